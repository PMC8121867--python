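"""High-level modelling interface: build a screening model from a cohort, fit, inspect.

`APLScreen` is constructed from a list of patient bags (or a manifest on
disk) and holds the architecture/training configuration; `fit()` runs the
Monte-Carlo cross-validation and returns `APLScreenResults`, which carries
the trained ensemble, the pooled out-of-fold discovery report, a
`summary()` table, `predict()` for independent cohorts, and the
interpretability entry points (attribution maps, latent embedding).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import interpret
from .io import load_dataset, preprocess_image
from .nn import ArchitectureConfig
from .training import (EnsembleModel, EvaluationReport, MonteCarloConfig, ensemble_predict,
                       prepare_patients, run_monte_carlo)

__all__ = ["APLScreen", "APLScreenResults"]


class APLScreen:
    """APL-vs-non-APL screening model for a peripheral-smear cohort.

    Parameters
    ----------
    patients : list of PatientSample
        The discovery cohort (bags of cell images with patient labels).
    mode : {"cell", "mil"}
        Single-cell classifier with post-hoc sample averaging, or the
        multiple-instance classifier with in-network bag averaging.
    scope : {"blasts_only", "all_cells"}
        Whether training/scoring is restricted to the immature myeloid
        compartment.
    """

    def __init__(self, patients, mode: str = "mil", scope: str = "all_cells",
                 arch: ArchitectureConfig | None = None,
                 mc: MonteCarloConfig | None = None):
        if mode not in ("cell", "mil"):
            raise ValueError(f"mode must be 'cell' or 'mil', got {mode!r}")
        if scope not in ("blasts_only", "all_cells"):
            raise ValueError(f"scope must be 'blasts_only' or 'all_cells', got {scope!r}")
        self.patients = list(patients)
        self.mode = mode
        self.scope = scope
        self.arch = arch or ArchitectureConfig()
        self.mc = mc or MonteCarloConfig()
        self._dataset = None

    @classmethod
    def from_manifest(cls, manifest_path, **kwargs) -> "APLScreen":
        """Build the model straight from a manifest CSV on disk."""
        return cls(load_dataset(manifest_path), **kwargs)

    @property
    def dataset(self) -> dict:
        if self._dataset is None:
            self._dataset = prepare_patients(self.patients, self.mc.image_size)
        return self._dataset

    def fit(self, progress: bool = False) -> "APLScreenResults":
        """Run the Monte-Carlo cross-validation and return the fitted results."""
        ensemble, report = run_monte_carlo(self.dataset, self.mode, self.scope,
                                           self.mc, self.arch, progress=progress)
        return APLScreenResults(self, ensemble, report)


class APLScreenResults:
    """Fitted ensemble plus pooled out-of-fold discovery evaluation."""

    def __init__(self, model: APLScreen, ensemble: EnsembleModel, report: EvaluationReport):
        self.model = model
        self.ensemble = ensemble
        self.report = report

    # estimates and diagnostics -------------------------------------------

    @property
    def auc_cell(self) -> float:
        return self.report.auc_cell

    @property
    def auc_sample(self) -> float:
        return self.report.auc_sample

    def summary(self) -> str:
        head = [
            "APL screening model — Monte-Carlo cross-validation",
            "---------------------------------------------------",
            f"patients: {len(self.model.patients)}    reps: {len(self.ensemble.models)}"
            f"    mode: {self.model.mode}    scope: {self.model.scope}",
            f"image size: {self.model.mc.image_size}px    outgroup blur sigma: "
            f"{self.model.mc.sigma:.1f}px",
            "",
        ]
        return "\n".join(head) + self.report.summary()

    # prediction on new cohorts -------------------------------------------

    def predict(self, patients) -> EvaluationReport:
        """Score an independent cohort with the full ensemble."""
        return ensemble_predict(self.ensemble, patients)

    # interpretability ------------------------------------------------------

    def attribute(self, image, n_models: int | None = None, seed: int = 0,
                  steps: int = 100):
        """Consensus integrated-gradients map for one preprocessed image."""
        image = preprocess_image(image, self.model.mc.image_size) \
            if np.asarray(image).shape[0] != self.model.mc.image_size else np.asarray(image)
        n = min(n_models or 25, len(self.ensemble.models))
        return interpret.consensus_attribution(self.ensemble, image, n_models=n,
                                               seed=seed, steps=steps)

    def latent_embedding(self, cells, labels=None, apl_probs=None, seed: int = 0):
        """Last-four-layer features for the given cells, embedded with PCA + UMAP."""
        feats = interpret.extract_latent_features(self.ensemble, cells)
        return feats, interpret.embed_latent(feats, labels=labels,
                                             apl_probs=apl_probs, seed=seed)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        self.ensemble.save(out_dir / "ensemble")
        self.report.save(out_dir, stem="discovery_report")
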