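"""Model surface: single-cell classifier, MIL sample classifier, score binarization.

Both classifiers share one backbone (see :mod:`aplsmear.nn`).  The
single-cell classifier maps one image to a softmax over
{non-APL, APL, blurred}.  The MIL sample classifier applies the identical
per-cell assignment and averages the softmax assignments over the bag
inside the network, so the bag probability is by construction the
arithmetic mean of the per-cell probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Adam, ArchitectureConfig, CellNet

__all__ = [
    "ArchitectureConfig",
    "SamplePrediction",
    "build_cell_classifier",
    "build_mil_classifier",
    "predict_cells",
    "apl_probability",
    "MILClassifier",
]


@dataclass
class SamplePrediction:
    """Bag-level output of the MIL classifier for one patient."""

    bag_probs: np.ndarray           # (n_classes,)
    per_cell_probs: np.ndarray      # (n_cells, n_classes)
    p_apl_binary: float


def build_cell_classifier(config: ArchitectureConfig | None = None, seed: int = 0) -> CellNet:
    """Seeded single-cell classifier; same (config, seed) gives identical weights."""
    return CellNet(config or ArchitectureConfig(), seed)


def predict_cells(model: CellNet, cells) -> np.ndarray:
    """Per-cell class probabilities, (n, n_classes); empty input gives empty output."""
    cells = list(cells)
    if len(cells) == 0:
        return np.zeros((0, model.config.n_classes))
    out = []
    for i in range(0, len(cells), 256):
        out.append(model.predict_probs(np.stack(cells[i : i + 256])))
    return np.concatenate(out, axis=0)


def apl_probability(probs: np.ndarray) -> np.ndarray | float:
    """Binary APL score: p_APL / (p_APL + p_non-APL).

    The blurred class is a training device, not a diagnosis, so the score
    renormalizes over the two real classes.  A degenerate all-blurred
    prediction (both real-class probabilities zero) scores 0.5 with a
    warning.  Accepts one triple or an (n, n_classes) array.
    """
    p = np.asarray(probs, dtype=np.float64)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    denom = p[:, 0] + p[:, 1]
    out = np.full(len(p), 0.5)
    ok = denom > 0
    out[ok] = p[ok, 1] / denom[ok]
    if not ok.all():
        warnings.warn("degenerate all-blurred prediction; APL probability set to 0.5")
    return float(out[0]) if single else out


class MILClassifier:
    """MIL sample classifier: per-cell assignment + in-network bag averaging."""

    def __init__(self, net: CellNet):
        self.net = net
        self.config = net.config

    def predict_bag(self, bag) -> SamplePrediction:
        bag = np.asarray(bag, dtype=np.float32)
        if len(bag) == 0:
            raise ValueError("MIL classifier requires a non-empty bag of cells")
        per_cell = []
        for i in range(0, len(bag), 256):
            per_cell.append(self.net.predict_probs(bag[i : i + 256]))
        per_cell = np.concatenate(per_cell, axis=0)
        bag_probs = per_cell.mean(axis=0)
        return SamplePrediction(
            bag_probs=bag_probs,
            per_cell_probs=per_cell,
            p_apl_binary=apl_probability(bag_probs),
        )


def build_mil_classifier(config: ArchitectureConfig | None = None, seed: int = 0) -> MILClassifier:
    """Seeded MIL sample classifier sharing the single-cell backbone."""
    return MILClassifier(CellNet(config or ArchitectureConfig(), seed))
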