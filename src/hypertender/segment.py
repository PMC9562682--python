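"""Background/fat segmentation, ROI ring selection, unfolding, band trimming.

Segmentation uses the single band nearest 1210 nm with two published
thresholds: reflectance below 0.068 is background (low mask), above 0.19 is
fat (high mask), and everything between is lean meat.  Calibration-set samples
are further reduced to a region of interest: the 25% of lean pixels nearest
the lean-region centroid ("inner ring counting from the central point"),
which caps the pixel count fed to model calibration.  Prediction-set samples
keep their full lean mask.

Unfolding rearranges the 3-D cube into the pixels x wavelengths matrix that
chemometric models operate on, with (sample, row, col) bookkeeping so per-pixel
predictions can be refolded into maps.  The first 33 bands (noisy detector
edge below ~1000 nm) are trimmed before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil

import numpy as np

from .hypercube import Hypercube

__all__ = [
    "MaskSet",
    "SpectraMatrix",
    "SegmentationError",
    "segment_sample",
    "select_roi_ring",
    "unfold",
    "refold",
    "trim_bands",
    "stack_matrices",
]

DEFAULT_SEGMENT_BAND_NM = 1210.0
DEFAULT_LOW_THRESHOLD = 0.068
DEFAULT_HIGH_THRESHOLD = 0.19
DEFAULT_TRIM_LEADING = 33
DEFAULT_ROI_FRACTION = 0.25


class SegmentationError(ValueError):
    """Thresholding left no lean pixels."""


@dataclass
class MaskSet:
    """Background / fat / lean partition of a frame at one wavelength."""

    background_mask: np.ndarray
    fat_mask: np.ndarray
    lean_mask: np.ndarray
    threshold_low: float
    threshold_high: float
    band_nm: float

    def __post_init__(self) -> None:
        total = (self.background_mask.astype(int) + self.fat_mask.astype(int)
                 + self.lean_mask.astype(int))
        if not np.all(total == 1):
            raise ValueError("masks must partition the frame")


@dataclass
class SpectraMatrix:
    """Unfolded pixel spectra: ``n_pixels x n_bands`` with pixel bookkeeping.

    ``sample_ids``, ``pixel_rows`` and ``pixel_cols`` are parallel to the rows
    of ``X`` (canonical raster order within each sample); ``group_labels`` is
    the optional per-pixel tenderness group (1 | 2).
    """

    X: np.ndarray
    wavelengths: np.ndarray
    sample_ids: np.ndarray
    pixel_rows: np.ndarray
    pixel_cols: np.ndarray
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for name in ("sample_ids", "pixel_rows", "pixel_cols"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must equal the pixel count {n}")
        if self.group_labels is not None and len(self.group_labels) != n:
            raise ValueError("group_labels length must equal the pixel count")
        if self.X.shape[1] != len(self.wavelengths):
            raise ValueError("wavelength axis must match the column count")

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]

    @property
    def pixel_index(self) -> list[tuple[str, int, int]]:
        return list(zip(self.sample_ids.tolist(), self.pixel_rows.tolist(),
                        self.pixel_cols.tolist()))


def segment_sample(cube: Hypercube, band_nm: float = DEFAULT_SEGMENT_BAND_NM,
                   low: float = DEFAULT_LOW_THRESHOLD,
                   high: float = DEFAULT_HIGH_THRESHOLD) -> MaskSet:
    """Partition the frame into background / lean / fat at one band.

    At the band nearest ``band_nm``: reflectance below ``low`` is background,
    above ``high`` is fat, and values in ``[low, high]`` are lean.
    """
    if not cube.wavelengths[0] <= band_nm <= cube.wavelengths[-1]:
        raise ValueError(f"band {band_nm} nm outside wavelength range")
    image = cube.band_image(band_nm)
    background = image < low
    fat = image > high
    lean = ~background & ~fat
    if not lean.any():
        raise SegmentationError(
            f"no lean pixels between {low} and {high} at {band_nm} nm "
            f"for sample '{cube.sample_id}'")
    return MaskSet(background_mask=background, fat_mask=fat, lean_mask=lean,
                   threshold_low=low, threshold_high=high, band_nm=band_nm)


def select_roi_ring(lean_mask: np.ndarray,
                    fraction: float = DEFAULT_ROI_FRACTION) -> np.ndarray:
    """The ``ceil(fraction * n_lean)`` lean pixels nearest the lean centroid.

    The centroid is the arithmetic mean of the lean-pixel coordinates;
    distance ties are broken by raster order, making the selection
    deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"roi fraction must be in (0, 1], got {fraction}")
    lean_mask = np.asarray(lean_mask, dtype=bool)
    coords = np.argwhere(lean_mask)  # raster order
    if len(coords) == 0:
        raise ValueError("lean mask is empty")
    n_keep = ceil(fraction * len(coords))
    centroid = coords.mean(axis=0)
    dist2 = ((coords - centroid) ** 2).sum(axis=1)
    keep = np.argsort(dist2, kind="stable")[:n_keep]
    roi = np.zeros_like(lean_mask)
    roi[coords[keep, 0], coords[keep, 1]] = True
    return roi


def unfold(cube: Hypercube, roi: np.ndarray,
           group: int | None = None) -> SpectraMatrix:
    """One matrix row per ROI pixel, in raster (row-major) scan order."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("cannot unfold an empty ROI")
    coords = np.argwhere(roi)
    X = cube.values[roi]  # numpy boolean indexing is raster-ordered
    n = len(coords)
    labels = np.full(n, group, dtype=int) if group is not None else None
    return SpectraMatrix(X=X, wavelengths=cube.wavelengths.copy(),
                         sample_ids=np.asarray([cube.sample_id] * n),
                         pixel_rows=coords[:, 0], pixel_cols=coords[:, 1],
                         group_labels=labels)


def refold(values: np.ndarray, pixel_rows: np.ndarray, pixel_cols: np.ndarray,
           shape: tuple[int, int], fill=np.nan) -> np.ndarray:
    """Scatter per-pixel values back onto a 2-D frame; off-ROI pixels = fill."""
    out = np.full(shape, fill, dtype=float)
    out[pixel_rows, pixel_cols] = values
    return out


def trim_bands(obj: Hypercube | SpectraMatrix,
               n_leading: int = DEFAULT_TRIM_LEADING):
    """Drop the first ``n_leading`` bands (and wavelengths) from a cube/matrix."""
    n_bands = len(obj.wavelengths)
    if n_leading >= n_bands:
        raise ValueError(f"cannot trim {n_leading} of {n_bands} bands")
    if n_leading == 0:
        return obj
    wl = obj.wavelengths[n_leading:].copy()
    if isinstance(obj, Hypercube):
        return Hypercube(values=obj.values[:, :, n_leading:], wavelengths=wl,
                         sample_id=obj.sample_id)
    return replace(obj, X=obj.X[:, n_leading:], wavelengths=wl)


def stack_matrices(matrices: list[SpectraMatrix]) -> SpectraMatrix:
    """Concatenate per-sample matrices into one calibration/prediction block."""
    if not matrices:
        raise ValueError("nothing to stack")
    wl = matrices[0].wavelengths
    for m in matrices[1:]:
        if not np.array_equal(m.wavelengths, wl):
            raise ValueError("wavelength axes differ across matrices")
    labels = None
    if all(m.group_labels is not None for m in matrices):
        labels = np.concatenate([m.group_labels for m in matrices])
    return SpectraMatrix(
        X=np.vstack([m.X for m in matrices]),
        wavelengths=wl.copy(),
        sample_ids=np.concatenate([m.sample_ids for m in matrices]),
        pixel_rows=np.concatenate([m.pixel_rows for m in matrices]),
        pixel_cols=np.concatenate([m.pixel_cols for m in matrices]),
        group_labels=labels,
    )
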