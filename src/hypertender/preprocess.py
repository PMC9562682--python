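"""Spectral pre-processing: Savitzky-Golay smoothing/derivatives, SNV,
mean-centering, and ordered chains of those steps.

Row-wise transforms (SG, SNV) act on each pixel spectrum independently and can
never leak information between calibration and test blocks.  Mean-centering is
a *column* statistic: it is learned on the calibration block only and applied
unchanged to cross-validation held-out folds and the prediction set, i.e. it
is part of the fitted model.

Conventions
-----------
* SG derivatives are per-band-step (``delta = 1``), not per nm; classification
  is invariant to that monotone column rescale.
* SG edge handling fits the edge polynomial over the terminal half-windows
  (``mode='interp'``), so output length equals input length.
* SNV uses the n-1 denominator for the spectrum standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Step",
    "PreprocessSpec",
    "ZeroVarianceRowError",
    "sg_filter",
    "snv",
    "mean_center",
    "apply_center",
    "run_chain",
    "FIRST_DER_MC",
    "SMOOTH_2ND_DER_MC",
    "SMOOTH_SNV_MC",
]

DEFAULT_WINDOW = 15
DEFAULT_POLYORDER = 2


class ZeroVarianceRowError(ValueError):
    """SNV cannot scale constant spectra."""

    def __init__(self, rows: np.ndarray):
        self.rows = rows
        super().__init__(f"SNV: zero-variance spectra at pixel rows {rows.tolist()}")


@dataclass(frozen=True)
class Step:
    """One pre-processing step: smooth | derivative | snv | mean_center."""

    kind: str
    window: int = DEFAULT_WINDOW
    polyorder: int = DEFAULT_POLYORDER
    order: int = 1  # derivative order, used by kind='derivative'

    def __post_init__(self) -> None:
        if self.kind not in {"smooth", "derivative", "snv", "mean_center"}:
            raise ValueError(f"unknown step kind '{self.kind}'")
        if self.kind in {"smooth", "derivative"}:
            if self.window % 2 == 0 or self.window <= self.polyorder:
                raise ValueError("window must be odd and exceed polyorder")
        if self.kind == "derivative" and self.order not in (1, 2):
            raise ValueError("derivative order must be 1 or 2")

    @property
    def label(self) -> str:
        return {
            "smooth": "Smoothing",
            "derivative": f"{self.order}{'st' if self.order == 1 else 'nd'} der",
            "snv": "SNV",
            "mean_center": "MC",
        }[self.kind]


@dataclass(frozen=True)
class PreprocessSpec:
    """An ordered pre-processing chain.

    ``mean_center``, if present, must be the last step: it is the model-facing
    centering whose statistics are learned on calibration data only.
    """

    steps: tuple[Step, ...]
    name: str | None = None

    def __post_init__(self) -> None:
        kinds = [s.kind for s in self.steps]
        if "mean_center" in kinds and kinds.index("mean_center") != len(kinds) - 1:
            raise ValueError("mean_center must be the final step of a chain")

    @property
    def label(self) -> str:
        return self.name or " + ".join(s.label for s in self.steps)

    @property
    def rowwise_steps(self) -> tuple[Step, ...]:
        return tuple(s for s in self.steps if s.kind != "mean_center")

    @property
    def centers(self) -> bool:
        return any(s.kind == "mean_center" for s in self.steps)


#: the three chains compared in the published model table
FIRST_DER_MC = PreprocessSpec(
    (Step("derivative", order=1), Step("mean_center")), name="1st der + MC")
SMOOTH_2ND_DER_MC = PreprocessSpec(
    (Step("smooth"), Step("derivative", order=2), Step("mean_center")),
    name="Smoothing + 2nd der + MC")
SMOOTH_SNV_MC = PreprocessSpec(
    (Step("smooth"), Step("snv"), Step("mean_center")),
    name="Smoothing + SNV + MC")


def sg_filter(X: np.ndarray, window: int = DEFAULT_WINDOW,
              polyorder: int = DEFAULT_POLYORDER, deriv_order: int = 0) -> np.ndarray:
    """Row-wise Savitzky-Golay convolution (smoothing or differentiation)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    if X.shape[1] < window:
        raise ValueError(f"spectra of length {X.shape[1]} are shorter than the "
                         f"{window}-point window")
    return savgol_filter(X, window_length=window, polyorder=polyorder,
                         deriv=deriv_order, delta=1.0, axis=1, mode="interp")


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre each spectrum, scale to unit SD (n-1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.nonzero(sd.ravel() == 0)[0]
    if zero.size:
        raise ZeroVarianceRowError(zero)
    return (X - mean) / sd


def mean_center(X_cal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre calibration columns; return the centred block and column means."""
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    if X_cal.size == 0:
        raise ValueError("cannot centre an empty matrix")
    means = X_cal.mean(axis=0)
    return X_cal - means, means


def apply_center(X_new: np.ndarray, column_means: np.ndarray) -> np.ndarray:
    """Apply calibration column means to new data (CV folds, prediction set)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(column_means):
        raise ValueError(
            f"column count {X_new.shape[1]} does not match the "
            f"{len(column_means)} stored means")
    return X_new - np.asarray(column_means)


def apply_rowwise(spec: PreprocessSpec, X: np.ndarray) -> np.ndarray:
    """Apply the chain's row-wise steps (everything except mean-centering)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    for step in spec.rowwise_steps:
        if step.kind == "smooth":
            X = sg_filter(X, step.window, step.polyorder, deriv_order=0)
        elif step.kind == "derivative":
            X = sg_filter(X, step.window, step.polyorder, deriv_order=step.order)
        elif step.kind == "snv":
            X = snv(X)
    return X


def run_chain(spec: PreprocessSpec, X_cal: np.ndarray,
              X_test: np.ndarray | None = None):
    """Run a chain on a calibration block and optionally a test block.

    Row-wise steps are applied to each block independently; the centering
    statistic is learned on ``X_cal`` only and applied to both blocks.
    Returns ``(X_cal', X_test')`` (``X_test'`` is None when no test block is
    given).
    """
    X_cal = apply_rowwise(spec, X_cal)
    X_test = apply_rowwise(spec, X_test) if X_test is not None else None
    if spec.centers:
        X_cal, means = mean_center(X_cal)
        if X_test is not None:
            X_test = apply_center(X_test, means)
    return X_cal, X_test
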