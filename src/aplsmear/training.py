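"""Monte-Carlo cross-validation training, ensembling and ROC evaluation.

Training repeatedly resamples the discovery cohort at the *patient* level
(75% train, remainder split in half into validation and test for the cell
classifier; 75/25 train/test for the MIL classifier), trains one model per
repetition, and pools per-cell/per-sample predictions only from repetitions
in which the patient was held out.  The trained repetitions double as an
ensemble: on an independent cohort every member scores every cell (or bag)
and the scores are averaged.

The promyelocyte fraction of a sample — the classical morphological
biomarker of APL — is computed alongside as the baseline comparator.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score

from .celltypes import IMMATURE_MYELOID
from .io import (DEFAULT_BLUR_SIGMA, DEFAULT_INPUT_SIZE, PatientSample, gaussian_blur,
                 preprocess_image)
from .models import MILClassifier, apl_probability
from .nn import Adam, ArchitectureConfig, CellNet

__all__ = [
    "MonteCarloConfig",
    "SplitAssignment",
    "EnsembleModel",
    "EvaluationReport",
    "UndefinedAUCError",
    "ClassMissingError",
    "prepare_patients",
    "mc_patient_split",
    "train_cell_classifier",
    "train_mil",
    "run_monte_carlo",
    "ensemble_predict",
    "promyelocyte_fraction",
    "roc_auc",
]


class UndefinedAUCError(ValueError):
    """ROC AUC requested with only one class present."""


class ClassMissingError(ValueError):
    """A training class has no images in the training split."""


@dataclass(frozen=True)
class MonteCarloConfig:
    """Settings for Monte-Carlo cross-validation training.

    ``n_reps`` repetitions of a patient-level 75/12.5/12.5 (cell mode) or
    75/25 (MIL mode) split; each repetition trains one model.  MIL training
    subsamples ``mil_subsample`` cells per bag per epoch and stops once the
    epoch training loss falls to ``mil_loss_threshold``; cell training
    early-stops on held-out validation loss.
    """

    n_reps: int = 100
    train_frac: float = 0.75
    mil_subsample: int = 25
    mil_loss_threshold: float = 0.2
    mil_max_epochs: int = 300
    max_epochs: int = 40
    patience: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 32
    image_size: int = DEFAULT_INPUT_SIZE
    blur_sigma: float | None = None
    use_outgroup: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if self.mil_subsample < 1:
            raise ValueError("mil_subsample must be >= 1")

    @property
    def sigma(self) -> float:
        if self.blur_sigma is not None:
            return self.blur_sigma
        return DEFAULT_BLUR_SIGMA * self.image_size / DEFAULT_INPUT_SIZE

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SplitAssignment:
    """Patient-level partition for one Monte-Carlo repetition."""

    rep_id: int
    train: frozenset
    validation: frozenset
    test: frozenset

    def __post_init__(self):
        overlap = (self.train & self.validation) | (self.train & self.test) | (self.validation & self.test)
        if overlap:
            raise ValueError(f"split sets overlap on patients {sorted(overlap)}")


@dataclass
class EnsembleModel:
    """Ordered collection of Monte-Carlo-trained models with their splits."""

    models: list
    splits: list
    mode: str                    # "cell" or "mil"
    cell_scope: str              # "blasts_only" or "all_cells"
    arch: ArchitectureConfig
    config: MonteCarloConfig

    def __len__(self) -> int:
        return len(self.models)

    def nets(self) -> list[CellNet]:
        return [m.net if isinstance(m, MILClassifier) else m for m in self.models]

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, net in enumerate(self.nets()):
            net.save(out_dir / f"model_{i:03d}.npz")
        meta = {
            "mode": self.mode,
            "cell_scope": self.cell_scope,
            "arch": self.arch.to_dict(),
            "config": self.config.to_dict(),
            "n_models": len(self.models),
            "splits": [
                {"rep_id": s.rep_id, "train": sorted(s.train),
                 "validation": sorted(s.validation), "test": sorted(s.test)}
                for s in self.splits
            ],
        }
        (out_dir / "ensemble.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, out_dir) -> "EnsembleModel":
        out_dir = Path(out_dir)
        meta = yaml.safe_load((out_dir / "ensemble.yaml").read_text())
        nets = [CellNet.load(out_dir / f"model_{i:03d}.npz") for i in range(meta["n_models"])]
        mode = meta["mode"]
        models = [MILClassifier(n) for n in nets] if mode == "mil" else nets
        splits = [SplitAssignment(rep_id=s["rep_id"], train=frozenset(s["train"]),
                                  validation=frozenset(s["validation"]), test=frozenset(s["test"]))
                  for s in meta["splits"]]
        cfg = meta["config"]
        cfg["blur_sigma"] = cfg.get("blur_sigma", None)
        return cls(models=models, splits=splits, mode=mode, cell_scope=meta["cell_scope"],
                   arch=ArchitectureConfig.from_dict(meta["arch"]),
                   config=MonteCarloConfig(**cfg))


@dataclass
class EvaluationReport:
    """Pooled per-cell and per-sample scores with their ROC AUCs."""

    per_cell: pd.DataFrame       # rep_id, patient_id, path, cell_type, label, score
    per_sample: pd.DataFrame     # patient_id, label, score, promyelocyte_fraction, n_cells
    auc_cell: float
    auc_sample: float
    baseline_auc_promyelocyte: float
    auc_by_cellcount_bin: pd.DataFrame
    mode: str = "cell"
    cell_scope: str = "all_cells"

    def summary(self) -> str:
        lines = [
            "Evaluation report",
            "=================",
            f"mode: {self.mode}    scope: {self.cell_scope}",
            f"cells scored:    {len(self.per_cell):>8d}",
            f"patients scored: {len(self.per_sample):>8d}",
            f"per-cell ROC AUC:               {self.auc_cell:.3f}",
            f"per-sample ROC AUC:             {self.auc_sample:.3f}",
            f"promyelocyte-fraction baseline: {self.baseline_auc_promyelocyte:.3f}",
            "",
            "AUC by per-patient cell count:",
        ]
        for row in self.auc_by_cellcount_bin.itertuples(index=False):
            auc = "   n/a" if np.isnan(row.auc) else f"{row.auc:.3f}"
            lines.append(f"  cells {row.bin:<12s} n={row.n_patients:<4d} AUC {auc}")
        return "\n".join(lines)

    def save(self, out_dir, stem: str = "report") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_cell.to_csv(out_dir / f"{stem}_cells.csv", index=False)
        self.per_sample.to_csv(out_dir / f"{stem}_samples.csv", index=False)
        payload = {
            "mode": self.mode,
            "cell_scope": self.cell_scope,
            "auc_cell": round(float(self.auc_cell), 6),
            "auc_sample": round(float(self.auc_sample), 6),
            "baseline_auc_promyelocyte": round(float(self.baseline_auc_promyelocyte), 6),
            "auc_by_cellcount_bin": self.auc_by_cellcount_bin.to_dict(orient="records"),
        }
        import json
        (out_dir / f"{stem}.json").write_text(json.dumps(payload, indent=2, allow_nan=True))
        try:
            plot_roc(self, out_dir / f"{stem}_roc.png")
        except UndefinedAUCError:
            pass


def plot_roc(report: "EvaluationReport", out_path) -> None:
    """Write per-cell and per-sample ROC curves for a report as one PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, df, auc in (("cell", report.per_cell, report.auc_cell),
                          ("sample", report.per_sample, report.auc_sample)):
        if len(df) and df["label"].nunique() == 2:
            fpr, tpr, _ = roc_curve(df["label"], df["score"])
            ax.plot(fpr, tpr, label=f"per-{name} AUC {auc:.3f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def prepare_patients(patients: list[PatientSample], size: int) -> dict:
    """Preprocess every cell once; returns pid -> dict(x, cell_types, paths, label)."""
    out = {}
    for s in patients:
        x = np.stack([preprocess_image(c, size) for c in s.cells]).astype(np.float32)
        out[s.patient_id] = {
            "x": x,
            "cell_types": [c.cell_type for c in s.cells],
            "paths": [c.path for c in s.cells],
            "label": s.label,
        }
    return out


def _scope_entry(entry: dict, scope: str):
    """Apply the cell-scope filter to one prepared patient; None if empty."""
    if scope == "all_cells":
        return entry
    if scope != "blasts_only":
        raise ValueError(f"unknown scope {scope!r}; expected 'blasts_only' or 'all_cells'")
    keep = [i for i, ct in enumerate(entry["cell_types"]) if ct in IMMATURE_MYELOID]
    if not keep:
        return None
    return {
        "x": entry["x"][keep],
        "cell_types": [entry["cell_types"][i] for i in keep],
        "paths": [entry["paths"][i] for i in keep],
        "label": entry["label"],
    }


def _scoped(dataset: dict, pids, scope: str) -> dict:
    out = {}
    for pid in sorted(pids):
        e = _scope_entry(dataset[pid], scope)
        if e is None:
            warnings.warn(f"patient {pid}: no cells in scope {scope}; excluded")
        else:
            out[pid] = e
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def mc_patient_split(patients, rep_id: int, config: MonteCarloConfig,
                     mode: str = "cell") -> SplitAssignment:
    """Stratified patient-level partition for one repetition.

    Cell mode reserves the held-out fraction half for validation and half
    for test; MIL mode puts it all in test.  Deterministic given
    ``(config.seed, rep_id)``.
    """
    if isinstance(patients, dict):
        by_label = {0: [], 1: []}
        for pid in sorted(patients):
            by_label[patients[pid]["label"]].append(pid)
    else:
        by_label = {0: [], 1: []}
        for s in sorted(patients, key=lambda s: s.patient_id):
            by_label[s.label].append(s.patient_id)
    n_total = len(by_label[0]) + len(by_label[1])
    if n_total < 4 or not by_label[0] or not by_label[1]:
        raise ValueError("need at least 4 patients with both classes present to split")
    rng = np.random.default_rng([int(config.seed) % (2**31), int(rep_id)])
    train, val, test = [], [], []
    for lab in (0, 1):
        pids = np.array(by_label[lab])
        rng.shuffle(pids)
        n_train = int(round(config.train_frac * len(pids)))
        n_train = min(max(n_train, 1), len(pids) - 1)   # both classes in train, >=1 held out
        held = pids[n_train:]
        train.extend(pids[:n_train])
        if mode == "cell":
            n_val = len(held) // 2
            val.extend(held[:n_val])
            test.extend(held[n_val:])
        else:
            test.extend(held)
    if not test:
        raise ValueError("held-out test set is empty; too few patients for this split")
    return SplitAssignment(rep_id=int(rep_id), train=frozenset(map(str, train)),
                           validation=frozenset(map(str, val)),
                           test=frozenset(map(str, test)))


# ---------------------------------------------------------------------------
# cell-classifier training
# ---------------------------------------------------------------------------

def _binary_val_loss(net: CellNet, x: np.ndarray, y: np.ndarray) -> float:
    """Cross-entropy of the renormalized binary APL score on held-out cells."""
    scores = []
    for i in range(0, len(x), 256):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores.append(apl_probability(net.predict_probs(x[i : i + 256])))
    p = np.clip(np.concatenate(scores), 1e-7, 1 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_cell_classifier(split: SplitAssignment, dataset: dict, scope: str,
                          config: MonteCarloConfig,
                          arch: ArchitectureConfig | None = None):
    """Train one single-cell classifier on one split.

    Training images are the train-split cells (in scope) plus, when the
    outgroup is enabled, one Gaussian-blurred copy of each — the outgroup
    is rebuilt per split from training images only.  Early stopping
    monitors the validation-split loss.  Returns ``(net, rows)`` where
    ``rows`` holds the out-of-fold binary APL score of every *test*-split
    cell.
    """
    arch = arch or ArchitectureConfig()
    train_set = _scoped(dataset, split.train, scope)
    labels_present = {e["label"] for e in train_set.values()}
    if labels_present != {0, 1}:
        raise ClassMissingError(
            f"training split must contain both classes, found labels {sorted(labels_present)}")
    xs = [train_set[pid]["x"] for pid in sorted(train_set)]
    ys = [np.full(len(x), train_set[pid]["label"]) for pid, x in zip(sorted(train_set), xs)]
    x_train = np.concatenate(xs)
    y_train = np.concatenate(ys).astype(np.int64)
    if config.use_outgroup and arch.n_classes == 3:
        x_blur = np.stack([gaussian_blur(im, config.sigma) for im in x_train])
        x_train = np.concatenate([x_train, x_blur])
        y_train = np.concatenate([y_train, np.full(len(x_blur), 2, dtype=np.int64)])

    val_set = _scoped(dataset, split.validation, scope)
    if val_set:
        x_val = np.concatenate([val_set[pid]["x"] for pid in sorted(val_set)])
        y_val = np.concatenate([np.full(len(val_set[pid]["x"]), val_set[pid]["label"])
                                for pid in sorted(val_set)])
    else:
        x_val = y_val = None

    rng = np.random.default_rng([int(config.seed) % (2**31), int(split.rep_id), 1])
    net = CellNet(arch, seed=int(rng.integers(2**31)))
    opt = Adam(net.params, lr=config.learning_rate)
    best_loss, best_params, bad_epochs = np.inf, None, 0
    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            _, grads = net.loss_and_grads(x_train[idx], y_train[idx])
            opt.step(net.params, grads)
        monitor = (_binary_val_loss(net, x_val, y_val) if x_val is not None
                   else net.cell_loss(x_train, y_train))
        if monitor < best_loss - 1e-5:
            best_loss, bad_epochs = monitor, 0
            best_params = {k: v.copy() for k, v in net.params.items()}
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    if best_params is not None:
        net.params = best_params

    rows = []
    test_set = _scoped(dataset, split.test, scope)
    for pid in sorted(test_set):
        e = test_set[pid]
        probs = np.concatenate([net.predict_probs(e["x"][i : i + 256])
                                for i in range(0, len(e["x"]), 256)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = apl_probability(probs)
        for path, ct, sc in zip(e["paths"], e["cell_types"], scores):
            rows.append({"rep_id": split.rep_id, "patient_id": pid, "path": path,
                         "cell_type": ct, "label": e["label"], "score": float(sc)})
    return net, rows


# ---------------------------------------------------------------------------
# MIL training
# ---------------------------------------------------------------------------

def train_mil(split: SplitAssignment, dataset: dict, scope: str,
              config: MonteCarloConfig, arch: ArchitectureConfig | None = None):
    """Train one MIL sample classifier on one split.

    Each epoch draws ``mil_subsample`` random cells per bag (all cells when
    the bag is smaller); blurred copies of the training bags form the
    outgroup bags.  Training stops once the epoch training loss reaches
    ``mil_loss_threshold`` (warning + stop at the epoch cap otherwise).
    Returns ``(MILClassifier, sample_rows, cell_rows)`` with out-of-fold
    bag and per-cell APL scores for the test-split patients.
    """
    arch = arch or ArchitectureConfig()
    train_set = _scoped(dataset, split.train, scope)
    labels_present = {e["label"] for e in train_set.values()}
    if labels_present != {0, 1}:
        raise ClassMissingError(
            f"training split must contain both classes, found labels {sorted(labels_present)}")
    bags = [(train_set[pid]["x"], train_set[pid]["label"]) for pid in sorted(train_set)]
    if config.use_outgroup and arch.n_classes == 3:
        bags += [(np.stack([gaussian_blur(im, config.sigma) for im in x]), 2) for x, _ in list(bags)]

    rng = np.random.default_rng([int(config.seed) % (2**31), int(split.rep_id), 2])
    net = CellNet(arch, seed=int(rng.integers(2**31)))
    opt = Adam(net.params, lr=config.learning_rate)
    converged = False
    for _epoch in range(config.mil_max_epochs):
        order = rng.permutation(len(bags))
        losses = []
        for bi in order:
            x, y = bags[bi]
            if len(x) > config.mil_subsample:
                idx = rng.choice(len(x), size=config.mil_subsample, replace=False)
                x = x[idx]
            loss, grads, _ = net.bag_loss_and_grads(x, y)
            opt.step(net.params, grads)
            losses.append(loss)
        if np.mean(losses) <= config.mil_loss_threshold:
            converged = True
            break
    if not converged:
        warnings.warn(f"MIL rep {split.rep_id}: training loss never reached "
                      f"{config.mil_loss_threshold} within {config.mil_max_epochs} epochs")

    clf = MILClassifier(net)
    sample_rows, cell_rows = [], []
    test_set = _scoped(dataset, split.test, scope)
    for pid in sorted(test_set):
        e = test_set[pid]
        pred = clf.predict_bag(e["x"])
        sample_rows.append({"rep_id": split.rep_id, "patient_id": pid,
                            "label": e["label"], "score": float(pred.p_apl_binary)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cell_scores = apl_probability(pred.per_cell_probs)
        for path, ct, sc in zip(e["paths"], e["cell_types"], cell_scores):
            cell_rows.append({"rep_id": split.rep_id, "patient_id": pid, "path": path,
                              "cell_type": ct, "label": e["label"], "score": float(sc)})
    return clf, sample_rows, cell_rows


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def roc_auc(labels, scores) -> float:
    """ROC AUC: probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError(f"labels and scores differ in length: {labels.shape} vs {scores.shape}")
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("ROC AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def promyelocyte_fraction(sample: PatientSample | dict) -> float:
    """Fraction of a patient's cells typed as promyelocytes (baseline biomarker)."""
    if isinstance(sample, PatientSample):
        types = [c.cell_type for c in sample.cells]
    else:
        types = sample["cell_types"]
    if len(types) == 0:
        raise ValueError("promyelocyte fraction undefined for an empty sample")
    return sum(t == "promyelocyte" for t in types) / len(types)


def _auc_or_nan(labels, scores) -> float:
    try:
        return roc_auc(labels, scores)
    except UndefinedAUCError:
        return float("nan")


def _cellcount_bins(per_sample: pd.DataFrame, n_bins: int = 4) -> pd.DataFrame:
    counts = per_sample["n_cells"]
    n_bins = min(n_bins, counts.nunique())
    rows = []
    if n_bins >= 2:
        binned = pd.qcut(counts, q=n_bins, duplicates="drop")
        for b, grp in per_sample.groupby(binned, observed=True):
            rows.append({"bin": str(b), "n_patients": len(grp),
                         "auc": _auc_or_nan(grp["label"], grp["score"])})
    else:
        rows.append({"bin": "all", "n_patients": len(per_sample),
                     "auc": _auc_or_nan(per_sample["label"], per_sample["score"])})
    return pd.DataFrame(rows, columns=["bin", "n_patients", "auc"])


def _build_report(per_cell: pd.DataFrame, per_sample_scores: pd.DataFrame | None,
                  dataset: dict, mode: str, scope: str) -> EvaluationReport:
    """Assemble an EvaluationReport from pooled predictions.

    For cell mode, the per-sample score is the mean of the patient's pooled
    per-cell predictions; for MIL mode it is the mean of the patient's
    pooled bag predictions.
    """
    if per_sample_scores is None:
        agg = per_cell.groupby("patient_id").agg(label=("label", "first"),
                                                 score=("score", "mean")).reset_index()
    else:
        agg = per_sample_scores.groupby("patient_id").agg(
            label=("label", "first"), score=("score", "mean")).reset_index()
    agg["promyelocyte_fraction"] = [promyelocyte_fraction(dataset[p]) for p in agg["patient_id"]]
    agg["n_cells"] = [len(dataset[p]["cell_types"]) for p in agg["patient_id"]]
    auc_cell = _auc_or_nan(per_cell["label"], per_cell["score"]) if len(per_cell) else float("nan")
    return EvaluationReport(
        per_cell=per_cell,
        per_sample=agg,
        auc_cell=auc_cell,
        auc_sample=_auc_or_nan(agg["label"], agg["score"]),
        baseline_auc_promyelocyte=_auc_or_nan(agg["label"], agg["promyelocyte_fraction"]),
        auc_by_cellcount_bin=_cellcount_bins(agg),
        mode=mode,
        cell_scope=scope,
    )


_CELL_COLS = ["rep_id", "patient_id", "path", "cell_type", "label", "score"]
_SAMPLE_COLS = ["rep_id", "patient_id", "label", "score"]


def run_monte_carlo(patients, mode: str, scope: str, config: MonteCarloConfig,
                    arch: ArchitectureConfig | None = None, progress: bool = False):
    """Full Monte-Carlo cross-validation run on a discovery cohort.

    Trains ``config.n_reps`` models on distinct random patient-level splits
    and pools strictly out-of-fold predictions into the discovery
    EvaluationReport.  Returns ``(EnsembleModel, EvaluationReport)``.
    """
    if mode not in ("cell", "mil"):
        raise ValueError(f"mode must be 'cell' or 'mil', got {mode!r}")
    arch = arch or ArchitectureConfig()
    dataset = patients if isinstance(patients, dict) else prepare_patients(patients, config.image_size)
    models, splits = [], []
    cell_rows, sample_rows = [], []
    for rep in range(config.n_reps):
        split = mc_patient_split(dataset, rep, config, mode=mode)
        if mode == "cell":
            net, rows = train_cell_classifier(split, dataset, scope, config, arch)
            models.append(net)
            cell_rows.extend(rows)
        else:
            clf, srows, crows = train_mil(split, dataset, scope, config, arch)
            models.append(clf)
            sample_rows.extend(srows)
            cell_rows.extend(crows)
        splits.append(split)
        if progress:
            print(f"[mc] rep {rep + 1}/{config.n_reps} done", flush=True)
    per_cell = pd.DataFrame(cell_rows, columns=_CELL_COLS)
    per_sample = pd.DataFrame(sample_rows, columns=_SAMPLE_COLS) if mode == "mil" else None
    ensemble = EnsembleModel(models=models, splits=splits, mode=mode,
                             cell_scope=scope, arch=arch, config=config)
    report = _build_report(per_cell, per_sample, dataset, mode, scope)
    return ensemble, report


def ensemble_predict(ensemble: EnsembleModel, patients) -> EvaluationReport:
    """Apply a complete ensemble to an independent cohort.

    Every member scores every in-scope cell (and, in MIL mode, every bag);
    scores are averaged over members with equal weight.
    """
    if not isinstance(patients, dict):
        patients = prepare_patients(patients, ensemble.config.image_size)
    if not patients:
        raise ValueError("cannot evaluate an ensemble on an empty cohort")
    scoped = _scoped(patients, patients.keys(), ensemble.cell_scope)
    cell_rows, sample_rows = [], []
    for pid in sorted(scoped):
        e = scoped[pid]
        cell_acc = np.zeros(len(e["x"]))
        bag_acc = 0.0
        for m in ensemble.models:
            net = m.net if isinstance(m, MILClassifier) else m
            probs = np.concatenate([net.predict_probs(e["x"][i : i + 256])
                                    for i in range(0, len(e["x"]), 256)])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cell_acc += apl_probability(probs)
                if ensemble.mode == "mil":
                    bag_acc += apl_probability(probs.mean(axis=0))
        cell_scores = cell_acc / len(ensemble.models)
        for path, ct, sc in zip(e["paths"], e["cell_types"], cell_scores):
            cell_rows.append({"rep_id": -1, "patient_id": pid, "path": path,
                              "cell_type": ct, "label": e["label"], "score": float(sc)})
        if ensemble.mode == "mil":
            sample_rows.append({"rep_id": -1, "patient_id": pid, "label": e["label"],
                                "score": float(bag_acc / len(ensemble.models))})
    per_cell = pd.DataFrame(cell_rows, columns=_CELL_COLS)
    per_sample = pd.DataFrame(sample_rows, columns=_SAMPLE_COLS) if ensemble.mode == "mil" else None
    return _build_report(per_cell, per_sample, patients, ensemble.mode, ensemble.cell_scope)
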