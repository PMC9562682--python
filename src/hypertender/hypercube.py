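"""Hypercube container, ENVI band-sequential I/O, reflectance calibration and
artifact repair.

A hypercube is the raw object produced by a pushbroom NIR line-scan camera:
``rows x cols x bands`` with a strictly increasing wavelength axis.  Raw sensor
counts are converted to relative reflectance against a white (Spectralon tile)
and black (lens covered) reference::

    I_c = (I_raw - I_black) / (I_white - I_black)

Calibrated values are deliberately *not* clipped to [0, 1]: specular pixels may
exceed 1 and segmentation thresholds operate on the unclipped values.

Two sensor artifacts are handled after calibration:

* **dead pixels** — isolated spatial positions stuck at the black level across
  every band; they are located against the black reference and repaired by 2-D
  linear scattered interpolation over the surrounding live pixels (nearest
  neighbour at the frame edge where the convex hull does not cover them);
* **spikes** — single-band false intensity peaks; for each pixel spectrum any
  value outside mean +/- 6 standard deviations (n-1 denominator) is replaced
  by the mean of its two nearest non-spike spectral neighbours.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

__all__ = [
    "Hypercube",
    "ReferencePair",
    "CalibrationReferenceError",
    "read_cube",
    "write_cube",
    "calibrate_reflectance",
    "detect_dead_pixels",
    "repair_dead_pixels",
    "remove_spikes",
]


class CalibrationReferenceError(ValueError):
    """White reference does not strictly exceed the black reference."""


@dataclass
class Hypercube:
    """A ``rows x cols x bands`` reflectance (or raw-count) image.

    Parameters
    ----------
    values
        3-D float array, spatial rows x spatial columns x spectral bands.
    wavelengths
        Strictly increasing wavelength axis in nm, one entry per band.
    sample_id
        Identifier of the imaged sample.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("hypercube values must be 3-D (rows, cols, bands)")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} does not match "
                f"band count {self.values.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest to ``wavelength_nm`` (no interpolation)."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def band_image(self, wavelength_nm: float) -> np.ndarray:
        return self.values[:, :, self.band_index(wavelength_nm)]


@dataclass
class ReferencePair:
    """White / black reference frames for reflectance calibration.

    References may be supplied as full scans (``ref_rows x cols x bands``); the
    scan rows are averaged before use, which suppresses scan noise on the
    Spectralon tile.  After averaging the white level must strictly exceed the
    black level everywhere.
    """

    white: np.ndarray
    black: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.black = np.asarray(self.black, dtype=float)

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        """Row-averaged ``(white, black)`` frames of shape ``(cols, bands)``."""
        white = self.white.mean(axis=0) if self.white.ndim == 3 else self.white
        black = self.black.mean(axis=0) if self.black.ndim == 3 else self.black
        return white, black


# ---------------------------------------------------------------------------
# ENVI band-sequential I/O
# ---------------------------------------------------------------------------

_REQUIRED_HEADER_FIELDS = ("samples", "lines", "bands", "wavelength")


def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI ASCII header into a dict (values as strings or lists)."""
    # strip the leading magic word
    text = re.sub(r"^\s*ENVI\s*", "", text, count=1)
    fields: dict = {}
    # brace-delimited values may span lines
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(text):
        key = m.group(1).strip().lower()
        raw = m.group(2).strip()
        if raw.startswith("{"):
            items = [s.strip() for s in raw.strip("{}").replace("\n", " ").split(",")]
            fields[key] = [s for s in items if s]
        else:
            fields[key] = raw
    return fields


def read_cube(path: str | Path) -> Hypercube:
    """Read an ENVI band-sequential cube (``<path>.hdr`` + ``<path>.raw``)."""
    path = Path(path)
    hdr_path = path.with_suffix(".hdr")
    raw_path = path.with_suffix(".raw")
    if not hdr_path.exists():
        raise FileNotFoundError(f"ENVI header not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    for name in _REQUIRED_HEADER_FIELDS:
        if name not in fields:
            raise ValueError(f"ENVI header {hdr_path} is missing required field '{name}'")
    samples = int(fields["samples"])  # columns
    lines = int(fields["lines"])  # rows
    bands = int(fields["bands"])
    interleave = str(fields.get("interleave", "bsq")).lower()
    if interleave != "bsq":
        raise ValueError(f"only bsq interleave is supported, got '{interleave}'")
    dtype_code = int(fields.get("data type", 4))
    dtype = {4: np.float32, 5: np.float64, 1: np.uint8}.get(dtype_code)
    if dtype is None:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    payload = np.fromfile(raw_path, dtype=dtype)
    expected = samples * lines * bands
    if payload.size != expected:
        raise ValueError(
            f"payload size {payload.size} does not match header shape "
            f"{lines}x{samples}x{bands} (= {expected} values) in {raw_path}"
        )
    wavelengths = np.asarray([float(w) for w in fields["wavelength"]])
    # BSQ: band-major storage -> (bands, lines, samples)
    values = payload.reshape(bands, lines, samples).transpose(1, 2, 0)
    sample_id = str(fields.get("sample id", path.stem))
    return Hypercube(values=values, wavelengths=wavelengths, sample_id=sample_id)


def write_cube(cube: Hypercube, path: str | Path, dtype=np.float32) -> None:
    """Write a cube as ENVI BSQ: ``<path>.hdr`` (ASCII) + ``<path>.raw``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows, cols, bands = cube.shape
    dtype = np.dtype(dtype)
    code = {np.dtype(np.float32): 4, np.dtype(np.float64): 5, np.dtype(np.uint8): 1}[dtype]
    wl = ",\n  ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"sample id = {cube.sample_id}\n"
        "wavelength units = Nanometers\n"
        "wavelength = {\n  " + wl + "\n}\n"
    )
    path.with_suffix(".hdr").write_text(header)
    cube.values.transpose(2, 0, 1).astype(dtype).tofile(path.with_suffix(".raw"))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_reflectance(raw: Hypercube, refs: ReferencePair) -> Hypercube:
    """Normalise raw counts to relative reflectance between the references.

    Computes ``(I_raw - I_black) / (I_white - I_black)`` bandwise, broadcasting
    the row-averaged ``(cols, bands)`` reference frames over image rows.  The
    result is not clipped; values slightly outside [0, 1] are legitimate.
    """
    white, black = refs.averaged()
    span = white - black
    if np.any(span <= 0):
        bad = int(np.sum(span <= 0))
        raise CalibrationReferenceError(
            f"white reference does not exceed black at {bad} positions"
        )
    values = (raw.values - black[None, :, :]) / span[None, :, :]
    return Hypercube(values=values, wavelengths=raw.wavelengths.copy(),
                     sample_id=raw.sample_id)


# ---------------------------------------------------------------------------
# Dead pixels
# ---------------------------------------------------------------------------

def detect_dead_pixels(raw: Hypercube, refs: ReferencePair, k: float = 3.0) -> np.ndarray:
    """Flag pixels whose across-band mean raw response sits at the black level.

    A pixel is dead when its mean raw signal over all bands does not exceed the
    black reference's mean at that column by more than ``k`` black-frame
    standard deviations.  Operates on uncalibrated data.
    """
    _, black = refs.averaged()
    black_scan = refs.black if refs.black.ndim == 3 else refs.black[None, :, :]
    sigma = float(black_scan.std(ddof=1)) if black_scan.size > 1 else 0.0
    pixel_mean = raw.values.mean(axis=2)
    black_mean = black.mean(axis=1)  # per column
    return pixel_mean <= black_mean[None, :] + k * sigma


def repair_dead_pixels(cube: Hypercube, dead_mask: np.ndarray) -> Hypercube:
    """Replace dead pixels bandwise by 2-D interpolation over live pixels.

    Linear scattered interpolation on the live-pixel positions, evaluated at
    the dead positions; dead pixels outside the live convex hull fall back to
    the nearest live neighbour.  Live pixels are returned bit-identical.
    """
    dead_mask = np.asarray(dead_mask, dtype=bool)
    if dead_mask.shape != cube.shape[:2]:
        raise ValueError("dead_mask shape must match the spatial frame")
    if not dead_mask.any():
        return cube
    if dead_mask.all():
        raise ValueError("cannot repair: every pixel is flagged dead")
    live = ~dead_mask
    live_pts = np.argwhere(live).astype(float)
    dead_pts = np.argwhere(dead_mask).astype(float)
    live_vals = cube.values[live]  # (n_live, bands) — interpolated jointly
    interp = LinearNDInterpolator(live_pts, live_vals)
    filled = interp(dead_pts)
    outside = np.isnan(filled).any(axis=1)
    if outside.any():
        nearest = NearestNDInterpolator(live_pts, live_vals)
        filled[outside] = nearest(dead_pts[outside])
    values = cube.values.copy()
    values[dead_mask] = filled
    return replace(cube, values=values, wavelengths=cube.wavelengths.copy())


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def find_spikes(cube: Hypercube, n_sd: float = 6.0) -> np.ndarray:
    """Boolean ``rows x cols x bands`` mask of spectral spikes.

    Per pixel: mean and SD (n-1 denominator) over its spectrum, single pass;
    any band outside mean +/- ``n_sd`` SDs is a spike.  Constant spectra have
    zero SD and therefore no spikes.
    """
    if cube.n_bands < 3:
        raise ValueError("spike detection needs at least 3 bands")
    m = cube.values.mean(axis=2, keepdims=True)
    s = cube.values.std(axis=2, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        mask = np.abs(cube.values - m) > n_sd * s
    mask &= s > 0
    return mask


def remove_spikes(cube: Hypercube, n_sd: float = 6.0) -> Hypercube:
    """Replace spectral spikes by the mean of their two nearest clean neighbours.

    Interior spikes take the mean of the nearest non-spike band on each side;
    at the ends of the spectrum the two nearest valid same-side neighbours are
    averaged.  Detection is single-pass (statistics are not re-estimated after
    replacement); everything outside the flagged positions is untouched.
    """
    mask = find_spikes(cube, n_sd=n_sd)
    if not mask.any():
        return cube
    values = cube.values.copy()
    n_bands = cube.n_bands
    for r, c in zip(*np.nonzero(mask.any(axis=2))):
        spectrum = values[r, c]
        bad = np.nonzero(mask[r, c])[0]
        good = np.nonzero(~mask[r, c])[0]
        for b in bad:
            left = good[good < b]
            right = good[good > b]
            if left.size and right.size:
                neighbors = [spectrum[left[-1]], spectrum[right[0]]]
            elif right.size:
                neighbors = list(spectrum[right[:2]])
            else:
                neighbors = list(spectrum[left[-2:]])
            values[r, c, b] = float(np.mean(neighbors))
    return replace(cube, values=values, wavelengths=cube.wavelengths.copy())
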