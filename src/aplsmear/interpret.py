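"""Model interpretability: integrated gradients and latent-space embedding.

Integrated gradients attributes the class-contrast prediction
``dP = P(APL) - P(non-APL)`` to individual pixels by integrating the
gradient of dP along a straight path from a *blurred* version of the image
(the same blur that builds the training outgroup, so the baseline is a
stain-preserving but morphology-free image) to the original image.  The
path integral is approximated with a left-Riemann average over the
interpolation points, so the completeness identity

    sum(attributions) = dP(image) - dP(baseline)

holds up to O(1/steps).  Consensus maps average single-model maps over a
seeded random subset of ensemble members.

The latent-space view concatenates, per cell and per ensemble member, the
activations of the last four layers of the MIL network (three fully
connected layers plus the softmax output; 32+22+11+3 = 68 dimensions per
model), standardizes them, reduces with PCA keeping >= 99% of the
explained variance, and embeds in 2-D with UMAP; per-class Gaussian kernel
density grids summarize the class geography of the space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import gaussian_blur, DEFAULT_BLUR_SIGMA, DEFAULT_INPUT_SIZE
from .models import MILClassifier
from .training import EnsembleModel, EvaluationReport

__all__ = [
    "AttributionMap",
    "LatentFeatures",
    "EmbeddingResult",
    "integrated_gradients",
    "consensus_attribution",
    "rank_most_predictive_cells",
    "extract_latent_features",
    "embed_latent",
    "attribution_overlay",
]


@dataclass
class AttributionMap:
    """Per-pixel (channel-summed) attribution scores for one cell image."""

    values: np.ndarray           # (H, W)
    source: str                  # "single-model" or "consensus"
    n_models: int = 1

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribution map contains non-finite values")


@dataclass
class LatentFeatures:
    """Per-cell deep features: 68 dims per model, concatenated across members."""

    matrix: np.ndarray           # (n_cells, 68 * n_models)
    per_model_dim: int
    n_models: int


@dataclass
class EmbeddingResult:
    coords: np.ndarray           # (n_cells, 2)
    pca_dims_kept: int
    explained_variance_kept: float
    density_by_class: dict       # label -> (grid_x, grid_y, density)
    per_cell_apl_prob: np.ndarray


def _as_net(model):
    return model.net if isinstance(model, MILClassifier) else model


def integrated_gradients(model, image: np.ndarray, steps: int = 100,
                         sigma: float | None = None,
                         baseline: np.ndarray | None = None) -> AttributionMap:
    """Integrated-gradients map of dP = P(APL) - P(non-APL) for one image.

    ``steps`` scaled images are formed from the blurred baseline to the
    original; gradients of dP are averaged over them (left-Riemann) and
    multiplied by (image - baseline), then summed over channels.
    """
    if steps < 2:
        raise ValueError(f"steps must be >= 2, got {steps}")
    net = _as_net(model)
    image = np.asarray(image, dtype=np.float64)
    if baseline is None:
        if sigma is None:
            sigma = DEFAULT_BLUR_SIGMA * image.shape[0] / DEFAULT_INPUT_SIZE
        baseline = gaussian_blur(image, sigma)
    diff = image - baseline
    alphas = np.arange(steps) / steps
    grad_sum = np.zeros_like(image)
    batch = 25
    for i in range(0, steps, batch):
        chunk = alphas[i : i + batch]
        xs = baseline[None] + chunk[:, None, None, None] * diff[None]
        grad_sum += net.delta_grad(xs.astype(np.float32)).sum(axis=0)
    attr = diff * (grad_sum / steps)
    return AttributionMap(values=attr.sum(axis=2), source="single-model", n_models=1)


def consensus_attribution(ensemble: EnsembleModel, image: np.ndarray,
                          n_models: int = 25, seed: int = 0, steps: int = 100,
                          sigma: float | None = None) -> AttributionMap:
    """Mean attribution map over a seeded random subset of ensemble members."""
    if n_models > len(ensemble.models):
        raise ValueError(f"n_models={n_models} exceeds ensemble size {len(ensemble.models)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ensemble.models), size=n_models, replace=False)
    acc = None
    for i in chosen:
        m = integrated_gradients(ensemble.models[i], image, steps=steps, sigma=sigma)
        acc = m.values if acc is None else acc + m.values
    return AttributionMap(values=acc / n_models, source="consensus", n_models=n_models)


def rank_most_predictive_cells(report: EvaluationReport, k: int):
    """Top-k most APL-predictive and most non-APL-predictive cells.

    Returns ``(apl_cells, nonapl_cells)`` as DataFrames sorted by
    descending / ascending APL score, ties broken by (patient_id, path).
    """
    df = report.per_cell
    if k > len(df):
        warnings.warn(f"k={k} exceeds the {len(df)} scored cells; truncating")
        k = len(df)
    if k < 0:
        raise ValueError("k must be >= 0")
    cols = ["patient_id", "path", "cell_type", "label", "score"]
    apl = df.sort_values(["score", "patient_id", "path"],
                         ascending=[False, True, True]).head(k)[cols].reset_index(drop=True)
    non = df.sort_values(["score", "patient_id", "path"],
                         ascending=[True, True, True]).head(k)[cols].reset_index(drop=True)
    return apl, non


def extract_latent_features(ensemble: EnsembleModel, cells) -> LatentFeatures:
    """Last-four-layer activations per cell, concatenated across ensemble members.

    Per member: FC1, FC2, FC3 post-ReLU activations plus the softmax output
    (68 dimensions at the default architecture); members are concatenated
    in ensemble order, giving 68 x n_models columns.
    """
    if ensemble.mode != "mil":
        raise ValueError("latent features are extracted from a MIL-mode ensemble")
    cells = np.asarray(cells, dtype=np.float32)
    blocks = []
    for m in ensemble.models:
        net = _as_net(m)
        feats = []
        for i in range(0, len(cells), 256):
            _, hidden, _ = net.forward(cells[i : i + 256])
            feats.append(np.concatenate([h.astype(np.float64) for h in hidden], axis=1))
        blocks.append(np.concatenate(feats, axis=0))
    per_model_dim = blocks[0].shape[1]
    return LatentFeatures(matrix=np.concatenate(blocks, axis=1),
                          per_model_dim=per_model_dim, n_models=len(blocks))


def embed_latent(features: LatentFeatures | np.ndarray, labels=None, cell_types=None,
                 apl_probs=None, seed: int = 0, min_explained_variance: float = 0.99,
                 grid_size: int = 60) -> EmbeddingResult:
    """Standardize -> PCA (>= 99% explained variance) -> 2-D UMAP -> per-class KDE."""
    import umap

    x = features.matrix if isinstance(features, LatentFeatures) else np.asarray(features, dtype=np.float64)
    n = len(x)
    if n < 3:
        raise ValueError("embedding requires at least 3 cells")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd < 1e-12] = 1.0
    z = (x - mu) / sd
    n_comp = min(n - 1, z.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=int(seed))
    scores = pca.fit_transform(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(cum, min_explained_variance - 1e-12) + 1)
    keep = min(keep, n_comp)
    kept_var = float(cum[keep - 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_neighbors=min(15, n - 1), min_dist=0.1,
                            n_components=2, random_state=int(seed))
        coords = np.asarray(reducer.fit_transform(scores[:, :keep]), dtype=np.float64)
    density = {}
    if labels is not None:
        labels = np.asarray(labels)
        gx, gy = np.meshgrid(
            np.linspace(coords[:, 0].min(), coords[:, 0].max(), grid_size),
            np.linspace(coords[:, 1].min(), coords[:, 1].max(), grid_size),
        )
        for lab in np.unique(labels):
            pts = coords[labels == lab]
            if len(pts) >= 3 and not np.allclose(np.var(pts, axis=0), 0):
                try:
                    kde = stats.gaussian_kde(pts.T)
                    density[lab] = (gx, gy, kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape))
                except np.linalg.LinAlgError:
                    pass
    return EmbeddingResult(
        coords=coords,
        pca_dims_kept=keep,
        explained_variance_kept=kept_var,
        density_by_class=density,
        per_cell_apl_prob=(np.asarray(apl_probs, dtype=np.float64)
                           if apl_probs is not None else np.full(n, np.nan)),
    )


def attribution_overlay(image: np.ndarray, attr: AttributionMap, out_path,
                        alpha: float = 0.5) -> None:
    """Write a PNG of the attribution map overlaid on the original image.

    The map is normalized to [-1, 1] by its maximum absolute value and
    rendered with a diverging colormap at the given transparency.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = np.abs(attr.values).max() or 1.0
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.clip(image, 0, 1))
    ax.imshow(attr.values / vmax, cmap="bwr", vmin=-1, vmax=1, alpha=alpha)
    ax.set_axis_off()
    fig.savefig(out_path, bbox_inches="tight", dpi=120)
    plt.close(fig)
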