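"""Seeded generator of synthetic peripheral-smear cohorts.

The generator plants three controllable signals that mirror what a real
APL-versus-AML smear cohort carries:

* class-dependent immature-myeloid morphology — APL immature cells are
  rendered with condensed, centrally concentrated nuclear chromatin and a
  high granule density, non-APL immature cells with dispersed chromatin
  concentrated at the nuclear rim and few granules;
* class-dependent cell-type mixtures — APL patients carry an elevated
  promyelocyte fraction, non-APL patients more monocytoid cells;
* an era-dependent additive stain-color shift that can be correlated with
  the class label to any degree, emulating a collection-date batch effect
  in which one era contains only APL patients.

Everything is drawn from a single integer seed: an identical config yields
a byte-identical dataset on disk.  The renderer is deliberately simple —
layered 2-D primitives (elliptical nucleus with a radial chromatin density
gradient, cytoplasm disc, Gaussian-blob granules, pixel noise) — the
smallest model that makes chromatin centrality a single controllable
scalar.  It is not a photorealistic Wright-stain simulation.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .celltypes import CELL_TYPES, IMMATURE_MYELOID, CellTypeError

__all__ = [
    "MorphologyParams",
    "BatchEffect",
    "SyntheticCohortConfig",
    "generate_cell_image",
    "generate_cohort",
    "default_mixture",
    "default_morphology",
]

_BACKGROUND = np.array([236.0, 231.0, 238.0])   # pale field around the cell
_NUCLEUS_DARK = np.array([88.0, 52.0, 134.0])   # condensed chromatin purple
_NUCLEUS_LIGHT = np.array([170.0, 140.0, 200.0])
_GRANULE_COLOR = np.array([150.0, 60.0, 120.0])


@dataclass(frozen=True)
class MorphologyParams:
    """Rendering parameters for one cell class/type regime.

    chromatin_centrality in [0, 1]: 1 puts all chromatin density at the
    nucleus center (the APL regime), 0 at the nucleus rim (non-APL).
    granule_density is granules per 1000 px^2 of cytoplasm.
    """

    nucleus_radius_px: float
    chromatin_centrality: float
    granule_density: float
    cytoplasm_hue: float
    noise_sd: float

    def __post_init__(self):
        if not 0.0 <= self.chromatin_centrality <= 1.0:
            raise ValueError(f"chromatin_centrality must be in [0, 1], got {self.chromatin_centrality}")
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be > 0")
        if self.granule_density < 0:
            raise ValueError("granule_density must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class BatchEffect:
    """Additive stain-color shift tied to a collection era.

    ``class_correlation`` is the probability that an APL patient is
    assigned the confounded era; ``nonapl_confounded_prob`` the same for
    non-APL patients (0 by default, so class_correlation=1 reproduces a
    perfect class/era confound and class_correlation=0 removes the color
    shift from the cohort entirely).
    """

    era_id: str = "pre2018"
    color_shift_rgb: tuple[float, float, float] = (22.0, -10.0, -18.0)
    class_correlation: float = 0.0
    nonapl_confounded_prob: float = 0.0

    def __post_init__(self):
        if any(abs(c) > 64 for c in self.color_shift_rgb):
            raise ValueError("each color shift offset must satisfy |offset| <= 64 on the 0-255 scale")
        for p in (self.class_correlation, self.nonapl_confounded_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("era-assignment probabilities must be in [0, 1]")


def default_morphology(image_size_px: int = 128) -> dict[str, MorphologyParams]:
    """Per-class immature-myeloid morphology regimes, scaled to the image size.

    The two regimes differ only in chromatin centrality and granule
    density, never in color, so the planted class signal is morphological.
    """
    r = 0.18 * image_size_px
    return {
        "APL": MorphologyParams(nucleus_radius_px=r, chromatin_centrality=0.85,
                                granule_density=16.0, cytoplasm_hue=285.0, noise_sd=6.0),
        "non-APL": MorphologyParams(nucleus_radius_px=r, chromatin_centrality=0.15,
                                    granule_density=3.0, cytoplasm_hue=285.0, noise_sd=6.0),
    }


def default_mixture() -> dict[str, dict[str, float]]:
    """Per-class cell-type mixtures: promyelocyte-rich APL, monocytoid non-APL."""
    apl = {
        "promyelocyte": 0.40, "blast": 0.15, "myelocyte": 0.06, "metamyelocyte": 0.04,
        "promonocyte": 0.03, "segmented neutrophil": 0.08, "band neutrophil": 0.05,
        "lymphocyte": 0.10, "monocyte": 0.04, "eosinophil": 0.01, "basophil": 0.01,
        "erythroblast": 0.01, "platelet": 0.02,
    }
    nonapl = {
        "blast": 0.25, "promonocyte": 0.10, "monocyte": 0.18, "promyelocyte": 0.05,
        "myelocyte": 0.05, "metamyelocyte": 0.03, "segmented neutrophil": 0.10,
        "band neutrophil": 0.05, "lymphocyte": 0.12, "eosinophil": 0.01,
        "basophil": 0.01, "erythroblast": 0.03, "platelet": 0.02,
    }
    return {"APL": apl, "non-APL": nonapl}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_apl_patients: int = 10
    n_nonapl_patients: int = 10
    cells_per_patient: int = 200
    image_size_px: int = 128
    celltype_mixture_by_class: dict = field(default_factory=default_mixture)
    morphology_by_class: dict = None
    batch: BatchEffect = field(default_factory=BatchEffect)
    seed: int = 0
    cohort_name: str = "discovery"

    def __post_init__(self):
        if self.morphology_by_class is None:
            object.__setattr__(self, "morphology_by_class", default_morphology(self.image_size_px))
        if self.n_apl_patients < 0 or self.n_nonapl_patients < 0:
            raise ValueError("patient counts must be >= 0")
        if not 100 <= self.cells_per_patient <= 400:
            raise ValueError("cells_per_patient must be in [100, 400] (analyzer limit)")
        for label, mix in self.celltype_mixture_by_class.items():
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{label} cell-type mixture sums to {s}, expected 1")
            for ct in mix:
                if ct not in CELL_TYPES:
                    raise CellTypeError(ct)


# ---------------------------------------------------------------------------
# renderer
# ---------------------------------------------------------------------------

# relative (cell radius, nucleus scale) tweaks per cell type; immature
# myeloid types share the class morphology regime, mature types a fixed
# neutral regime so only immature cells carry the planted class signal.
_TYPE_GEOMETRY = {
    "lymphocyte": (0.30, 1.25),
    "platelet": (0.12, 0.0),
    "smudge": (0.34, 0.0),
    "artefact": (0.20, 0.0),
    "erythroblast": (0.26, 1.1),
}
_DEFAULT_GEOMETRY = (0.38, 1.0)
_LOBED_TYPES = {"segmented neutrophil": 3, "band neutrophil": 2}

_NEUTRAL = MorphologyParams(nucleus_radius_px=1.0, chromatin_centrality=0.5,
                            granule_density=2.0, cytoplasm_hue=285.0, noise_sd=6.0)


def generate_cell_image(class_label: str, cell_type: str, batch_shift_rgb,
                        params: MorphologyParams, rng: np.random.Generator,
                        image_size_px: int = 128) -> np.ndarray:
    """Render one synthetic white-blood-cell image.

    Returns an (H, W, 3) uint8 RGB array.  ``params`` applies to immature
    myeloid cell types; mature types are rendered from a neutral regime
    (same for both classes) so that the planted class signal lives in the
    immature compartment, with the noise level and hue taken from
    ``params``.  ``batch_shift_rgb`` is added to every pixel (the stain-age
    batch effect) before clipping to [0, 255].
    """
    if class_label not in ("APL", "non-APL"):
        raise ValueError(f"class_label must be 'APL' or 'non-APL', got {class_label!r}")
    if cell_type not in CELL_TYPES:
        raise CellTypeError(cell_type)
    n = int(image_size_px)
    if cell_type not in IMMATURE_MYELOID:
        params = replace(_NEUTRAL, nucleus_radius_px=0.14 * n,
                         cytoplasm_hue=params.cytoplasm_hue, noise_sd=params.noise_sd)

    # with no pixel noise and no granules the image is a deterministic
    # function of the geometry parameters: all stochastic jitter collapses
    # to its midpoint so different seeds render identical images
    det = params.noise_sd == 0 and params.granule_density == 0
    u = (lambda lo, hi: (lo + hi) / 2.0) if det else rng.uniform

    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    img = np.tile(_BACKGROUND, (n, n, 1))

    cell_rel, nuc_scale = _TYPE_GEOMETRY.get(cell_type, _DEFAULT_GEOMETRY)
    cx = n / 2 + u(-0.04, 0.04) * n
    cy = n / 2 + u(-0.04, 0.04) * n
    cell_r = cell_rel * n * u(0.92, 1.08)

    r_cell = np.hypot(xx - cx, yy - cy)
    cyto_mask = r_cell <= cell_r
    rgb = colorsys.hsv_to_rgb((params.cytoplasm_hue % 360.0) / 360.0, 0.22, 0.86)
    cyto_color = np.array(rgb) * 255.0
    img[cyto_mask] = cyto_color

    nuc_mask = np.zeros((n, n), dtype=bool)
    if nuc_scale > 0:
        nuc_r = params.nucleus_radius_px * nuc_scale
        lobes = _LOBED_TYPES.get(cell_type, 1)
        c = params.chromatin_centrality
        for lobe in range(lobes):
            if lobes == 1:
                ncx, ncy = cx + u(-0.05, 0.05) * n, cy + u(-0.05, 0.05) * n
                ax = nuc_r * u(0.9, 1.1)
                ay = nuc_r * u(0.9, 1.1)
            else:
                ang = 2 * np.pi * lobe / lobes + u(0, 2 * np.pi / lobes)
                ncx = cx + 0.45 * cell_r * np.cos(ang)
                ncy = cy + 0.45 * cell_r * np.sin(ang)
                ax = ay = nuc_r / np.sqrt(lobes) * u(0.9, 1.1)
            rho = np.sqrt(((xx - ncx) / ax) ** 2 + ((yy - ncy) / ay) ** 2)
            m = rho <= 1.0
            nuc_mask |= m
            # radial chromatin density: centrality c=1 -> dark center, c=0 -> dark rim
            w = c * (1.0 - rho[m]) + (1.0 - c) * rho[m]
            img[m] = _NUCLEUS_LIGHT + (_NUCLEUS_DARK - _NUCLEUS_LIGHT) * w[:, None]

    granule_area = cyto_mask & ~nuc_mask
    n_gran = rng.poisson(params.granule_density * granule_area.sum() / 1000.0) \
        if params.granule_density > 0 else 0
    for _ in range(n_gran):
        ang = rng.uniform(0, 2 * np.pi)
        rad = cell_r * np.sqrt(rng.uniform(0, 1))
        gx, gy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
        gr = rng.uniform(0.8, 1.8) * n / 128.0
        gm = (np.hypot(xx - gx, yy - gy) <= gr) & granule_area
        img[gm] = 0.4 * img[gm] + 0.6 * _GRANULE_COLOR

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = img + np.asarray(batch_shift_rgb, dtype=np.float64)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _assign_era(label: str, batch: BatchEffect, rng: np.random.Generator) -> str:
    p = batch.class_correlation if label == "APL" else batch.nonapl_confounded_prob
    return batch.era_id if rng.random() < p else "unconfounded"


def generate_cohort(config: SyntheticCohortConfig, out_dir) -> pd.DataFrame:
    """Write a synthetic cohort to ``out_dir`` and return its manifest.

    Layout: one PNG per cell under ``out_dir/<patient_id>/``, plus
    ``manifest.csv`` with columns patient_id, cohort, label, cell_type,
    path (relative to the manifest), era_id.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows = []
    labels = ["APL"] * config.n_apl_patients + ["non-APL"] * config.n_nonapl_patients
    width = max(3, len(str(max(len(labels), 1))))
    for idx, label in enumerate(labels):
        pid = f"P{idx:0{width}d}"
        era = _assign_era(label, config.batch, rng)
        shift = config.batch.color_shift_rgb if era == config.batch.era_id else (0.0, 0.0, 0.0)
        mix = config.celltype_mixture_by_class[label]
        types = list(mix)
        probs = np.array([mix[t] for t in types])
        probs = probs / probs.sum()
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        drawn = rng.choice(len(types), size=config.cells_per_patient, p=probs)
        for j, ti in enumerate(drawn):
            ct = types[ti]
            img = generate_cell_image(label, ct, shift, config.morphology_by_class[label],
                                      rng, config.image_size_px)
            rel = f"{pid}/cell_{j:04d}.png"
            Image.fromarray(img).save(out_dir / rel)
            rows.append((pid, config.cohort_name, label, ct, rel, era))
    manifest = pd.DataFrame(rows, columns=["patient_id", "cohort", "label",
                                           "cell_type", "path", "era_id"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
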