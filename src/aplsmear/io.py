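"""Dataset loading, preprocessing, blurred-outgroup construction and cell selection.

The on-disk format is a manifest CSV (patient_id, cohort, label, cell_type,
path, era_id) plus one RGB PNG/JPEG per segmented cell.  Images are resized
to a square model input (360x360 by default) by bilinear interpolation and
scaled to [0, 1].

The blurred outgroup is the batch-effect control: Gaussian-blurred copies
of the *training* images form a third class so that the classifier cannot
separate the two diagnostic classes on global color/stain statistics alone
— a blurred APL-stained image must be called "blurred", not "APL".
Outgroup images are always rebuilt from the training split of the current
resampling; held-out images never contribute members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .celltypes import CELL_TYPES, IMMATURE_MYELOID

__all__ = [
    "CellImage",
    "PatientSample",
    "NON_APL",
    "APL",
    "BLURRED",
    "DatasetIntegrityError",
    "load_dataset",
    "preprocess_image",
    "make_blur_outgroup",
    "gaussian_blur",
    "select_immature_myeloid",
    "DEFAULT_INPUT_SIZE",
    "DEFAULT_BLUR_SIGMA",
]

# the three training classes
NON_APL, APL, BLURRED = 0, 1, 2

DEFAULT_INPUT_SIZE = 360      # square model input, px
DEFAULT_BLUR_SIGMA = 11.0     # outgroup blur at 360 px; scale linearly for other sizes

_LABEL_CODES = {"non-APL": 0, "APL": 1, "0": 0, "1": 1}


class DatasetIntegrityError(ValueError):
    """Inconsistent manifest (e.g. one patient with two labels)."""


@dataclass
class CellImage:
    """One segmented white-blood-cell image with its metadata."""

    pixels: np.ndarray          # (H, W, 3) uint8
    patient_id: str
    cell_type: str
    era_id: str | None = None
    path: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or min(px.shape[:2]) < 1:
            raise ValueError(f"cell image must be (H, W, 3) RGB, got shape {px.shape}")
        self.pixels = px


@dataclass
class PatientSample:
    """A labeled bag of cell images from one patient (the MIL instance bag)."""

    patient_id: str
    label: int                  # non-APL=0, APL=1
    cohort: str
    cells: list[CellImage] = field(default_factory=list)

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 (non-APL) or 1 (APL), got {self.label}")
        if len(self.cells) < 1:
            raise ValueError(f"patient {self.patient_id} has no cells")
        for c in self.cells:
            if c.patient_id != self.patient_id:
                raise DatasetIntegrityError(
                    f"cell {c.path} carries patient_id {c.patient_id!r} inside sample {self.patient_id!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _code_label(raw, patient_id: str) -> int:
    key = str(raw)
    if key not in _LABEL_CODES:
        raise DatasetIntegrityError(f"patient {patient_id}: unrecognized label {raw!r}")
    return _LABEL_CODES[key]


def load_dataset(manifest_path) -> list[PatientSample]:
    """Load a manifest CSV and its images into per-patient bags.

    Patients are ordered by patient_id and cells by path, so loading is
    deterministic.  A patient listed with two different labels or cohorts
    raises :class:`DatasetIntegrityError`; a missing image file raises
    ``FileNotFoundError`` naming the path.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    required = {"patient_id", "cohort", "label", "cell_type", "path"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetIntegrityError(f"manifest missing columns: {sorted(missing)}")
    if len(df) == 0:
        return []
    root = manifest_path.parent
    samples: list[PatientSample] = []
    for pid, grp in df.sort_values(["patient_id", "path"]).groupby("patient_id", sort=True):
        labels = set(grp["label"])
        if len(labels) > 1:
            raise DatasetIntegrityError(f"patient {pid} has conflicting labels: {sorted(labels)}")
        cohorts = set(grp["cohort"])
        if len(cohorts) > 1:
            raise DatasetIntegrityError(f"patient {pid} has conflicting cohorts: {sorted(cohorts)}")
        cells = []
        for row in grp.itertuples(index=False):
            ct = row.cell_type
            if ct not in CELL_TYPES:
                warnings.warn(f"unknown cell type {ct!r} for {row.path}; mapping to 'unidentified'")
                ct = "unidentified"
            img_path = root / row.path
            if not img_path.exists():
                raise FileNotFoundError(f"image file not found: {img_path}")
            with Image.open(img_path) as im:
                pixels = np.asarray(im.convert("RGB"))
            era = getattr(row, "era_id", None) or None
            cells.append(CellImage(pixels=pixels, patient_id=pid, cell_type=ct,
                                   era_id=era, path=str(row.path)))
        samples.append(PatientSample(patient_id=pid, label=_code_label(grp["label"].iloc[0], pid),
                                     cohort=grp["cohort"].iloc[0], cells=cells))
    return samples


def _bilinear_resize(pixels: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resample to (size, size) with half-pixel-center alignment."""
    h, w = pixels.shape[:2]
    rows = (np.arange(size) + 0.5) * (h / size) - 0.5
    cols = (np.arange(size) + 0.5) * (w / size) - 0.5
    rows = np.clip(rows, 0, h - 1)
    cols = np.clip(cols, 0, w - 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])
    out = np.empty((size, size, 3), dtype=np.float64)
    for ch in range(3):
        out[:, :, ch] = ndimage.map_coordinates(
            pixels[:, :, ch].astype(np.float64), coords, order=1, mode="nearest"
        ).reshape(size, size)
    return out


def preprocess_image(image: CellImage | np.ndarray, size: int = DEFAULT_INPUT_SIZE) -> np.ndarray:
    """Resize one cell image to (size, size, 3) and scale intensities to [0, 1]."""
    pixels = image.pixels if isinstance(image, CellImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {pixels.shape}")
    if np.issubdtype(pixels.dtype, np.integer):
        pixels = pixels.astype(np.float64) / 255.0
    else:
        pixels = pixels.astype(np.float64)
    if pixels.shape[0] != size or pixels.shape[1] != size:
        pixels = _bilinear_resize(pixels, size)
    return np.clip(pixels, 0.0, 1.0)


def preprocess_sample(sample: PatientSample, size: int = DEFAULT_INPUT_SIZE) -> np.ndarray:
    """Stack of preprocessed tensors for one bag, (n_cells, size, size, 3) float32."""
    return np.stack([preprocess_image(c, size) for c in sample.cells]).astype(np.float32)


def gaussian_blur(tensor: np.ndarray, sigma: float) -> np.ndarray:
    """Channel-wise Gaussian blur (kernel truncated at 4 sigma)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return ndimage.gaussian_filter(
        tensor, sigma=(sigma, sigma, 0), mode="nearest", truncate=4.0
    )


def make_blur_outgroup(images, sigma: float | None = None, rng=None):
    """Blurred copies of ``images``, one per input, labeled BLURRED.

    The outgroup has exactly the size of its source set.  ``sigma``
    defaults to 11 px scaled to the image side (11 at 360).  Returns
    ``(blurred_images, labels)``.
    """
    images = list(images)
    if len(images) == 0:
        raise ValueError("cannot build a blur outgroup from an empty image set")
    if sigma is None:
        sigma = DEFAULT_BLUR_SIGMA * images[0].shape[0] / DEFAULT_INPUT_SIZE
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    blurred = [gaussian_blur(np.asarray(im, dtype=np.float32), sigma) for im in images]
    labels = np.full(len(blurred), BLURRED, dtype=np.int64)
    return blurred, labels


def select_immature_myeloid(sample: PatientSample) -> PatientSample | None:
    """Restrict a bag to the immature myeloid compartment.

    Keeps blasts, promonocytes, promyelocytes, myelocytes and
    metamyelocytes in their original order.  Returns ``None`` (with a
    warning) when no cell survives, so the caller can exclude the sample
    from blasts-only training.
    """
    kept = [c for c in sample.cells if c.cell_type in IMMATURE_MYELOID]
    if not kept:
        warnings.warn(f"patient {sample.patient_id}: no immature myeloid cells; "
                      "sample excluded from blasts-only scope")
        return None
    return PatientSample(patient_id=sample.patient_id, label=sample.label,
                         cohort=sample.cohort, cells=kept)
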