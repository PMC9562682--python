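"""Split design, confusion summaries, sensitivity/specificity, %CC, model
comparison and pixel classification maps.

Conventions
-----------
* The confusion matrix is laid out predicted x real; ``column_percent``
  normalises each *real-group* column to 100, which is how published model
  tables in this field are printed.
* Positive class = group 1 (tender).  TP = true 1 predicted 1, FN = true 1
  predicted 2, TN = true 2 predicted 2, FP = true 2 predicted 1.  Then
  ``SEN = TP / (TP + FN)`` and ``SPE = TN / (TN + FP)``, so for the binary
  problem sensitivity of one group equals specificity of the other.
* The headline %CC is the macro average of the two diagonal column
  percentages (per-group correct rates), not pooled accuracy; the pooled
  pixel accuracy is reported alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plsda import CVSpec, PLSDAModel, cross_validate, fit, predict, select_n_lv
from .preprocess import PreprocessSpec
from .segment import refold

__all__ = [
    "ConfusionSummary",
    "ClassificationMap",
    "split_calibration",
    "confusion",
    "summary_from_column_percent",
    "compare_models",
    "classification_map",
]


@dataclass
class ConfusionSummary:
    """2x2 classification summary (predicted x real, positive = group 1)."""

    counts: np.ndarray | None
    column_percent: np.ndarray
    sensitivity: dict
    specificity: dict
    percent_cc_per_group: dict
    mean_percent_cc: float
    pooled_accuracy_percent: float | None = None

    @property
    def diagonal(self) -> tuple[float, float]:
        return float(self.column_percent[0, 0]), float(self.column_percent[1, 1])


def _summary_from_percent(column_percent: np.ndarray,
                          counts: np.ndarray | None = None,
                          pooled: float | None = None) -> ConfusionSummary:
    cp = np.asarray(column_percent, dtype=float)
    if cp.shape != (2, 2):
        raise ValueError("expected a 2x2 column-percent block")
    sums = cp.sum(axis=0)
    if not np.allclose(sums, 100.0, atol=0.05):
        raise ValueError(f"column-percent columns must sum to 100, got {sums}")
    d1, d2 = cp[0, 0], cp[1, 1]
    sen = {1: d1 / 100.0, 2: d2 / 100.0}
    spe = {1: d2 / 100.0, 2: d1 / 100.0}
    return ConfusionSummary(counts=counts, column_percent=cp,
                            sensitivity=sen, specificity=spe,
                            percent_cc_per_group={1: d1, 2: d2},
                            mean_percent_cc=(d1 + d2) / 2.0,
                            pooled_accuracy_percent=pooled)


def summary_from_column_percent(block: np.ndarray) -> ConfusionSummary:
    """Build a summary from a printed column-normalised confusion block.

    Lets a published 2x2 percentage table be pushed through the same
    sensitivity/specificity/%CC arithmetic as live predictions.
    """
    return _summary_from_percent(block)


def confusion(true_labels: np.ndarray, predicted_labels: np.ndarray) -> ConfusionSummary:
    """Tally a predicted x real confusion matrix and derive all statistics."""
    t = np.asarray(true_labels).astype(int)
    p = np.asarray(predicted_labels).astype(int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for arr, name in ((t, "true"), (p, "predicted")):
        bad = set(np.unique(arr)) - {1, 2}
        if bad:
            raise ValueError(f"{name} labels outside {{1, 2}}: {sorted(bad)}")
    if len(set(np.unique(t))) < 2:
        raise ValueError("both classes must be present in the true labels")
    counts = np.zeros((2, 2), dtype=int)  # predicted x real
    for pred in (1, 2):
        for real in (1, 2):
            counts[pred - 1, real - 1] = int(np.sum((p == pred) & (t == real)))
    column_percent = 100.0 * counts / counts.sum(axis=0, keepdims=True)
    pooled = 100.0 * np.trace(counts) / counts.sum()
    return _summary_from_percent(column_percent, counts=counts, pooled=pooled)


def split_calibration(groups: dict[str, int], fraction: float = 0.70,
                      seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified random calibration/test split with balanced calibration.

    Each group contributes the same number of calibration samples,
    ``ceil(fraction * n_max)`` where ``n_max`` is the larger group, capped so
    every group keeps at least one test sample.  For a 30 + 28 cohort at 0.70
    this gives 21 + 21 = 42 calibration and 16 test samples.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1): an empty calibration or "
                         "test set is not a usable split")
    by_group: dict[int, list[str]] = {}
    for sid, g in groups.items():
        by_group.setdefault(int(g), []).append(sid)
    if set(by_group) != {1, 2}:
        raise ValueError("both groups must be present")
    for g, ids in by_group.items():
        if len(ids) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    n_max = max(len(ids) for ids in by_group.values())
    n_cal_target = int(np.ceil(fraction * n_max))
    rng = np.random.default_rng(seed)
    cal, test = [], []
    for g in sorted(by_group):
        ids = sorted(by_group[g])
        n_cal = min(n_cal_target, len(ids) - 1)
        order = rng.permutation(len(ids))
        cal.extend(ids[i] for i in order[:n_cal])
        test.extend(ids[i] for i in order[n_cal:])
    return sorted(cal), sorted(test)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """One pre-processing chain's end-to-end result."""

    chain: PreprocessSpec
    n_lv: int
    explained_x_variance: float
    cv_summary: ConfusionSummary
    prediction_summary: ConfusionSummary
    model: PLSDAModel

    @property
    def label(self) -> str:
        return self.chain.label


def evaluate_chain(chain: PreprocessSpec, X_cal, y_cal, units_cal,
                   X_pred=None, y_pred=None, cv: CVSpec = CVSpec(),
                   wavelengths=None, n_lv: int | None = None) -> ModelReport:
    """Cross-validate one chain, pick the LV count, refit, and predict."""
    from .preprocess import run_chain

    summaries = cross_validate(X_cal, y_cal, units_cal, cv=cv, preprocess=chain)
    if n_lv is None:
        n_lv = select_n_lv(summaries)
    cv_summary = summaries[n_lv - 1]
    Xc, Xp = run_chain(chain, X_cal, X_pred)
    model = fit(Xc, y_cal, n_lv, wavelengths=wavelengths)
    if Xp is not None and y_pred is not None:
        _, labels = predict(model, Xp)
        pred_summary = confusion(y_pred, labels)
    else:
        pred_summary = cv_summary
    return ModelReport(chain=chain, n_lv=n_lv,
                       explained_x_variance=float(model.explained_x_variance[-1]),
                       cv_summary=cv_summary, prediction_summary=pred_summary,
                       model=model)


def compare_models(chains: list[PreprocessSpec], X_cal, y_cal, units_cal,
                   X_pred=None, y_pred=None, cv: CVSpec = CVSpec(),
                   wavelengths=None) -> list[ModelReport]:
    """Evaluate several chains and rank by mean CV %CC (ties: fewer LVs)."""
    if not chains:
        raise ValueError("no pre-processing chains given")
    reports = [evaluate_chain(c, X_cal, y_cal, units_cal, X_pred, y_pred,
                              cv=cv, wavelengths=wavelengths) for c in chains]
    reports.sort(key=lambda r: (-r.cv_summary.mean_percent_cc, r.n_lv))
    return reports


# ---------------------------------------------------------------------------
# Classification maps
# ---------------------------------------------------------------------------

#: map category codes and display colours (true/false positives/negatives)
MAP_CATEGORIES = {"TP": 1, "FN": 2, "TN": 3, "FP": 4}
MAP_COLORS = {0: (1.0, 1.0, 1.0), 1: (0.95, 0.87, 0.18), 2: (0.44, 0.16, 0.55),
              3: (0.95, 0.55, 0.15), 4: (0.18, 0.32, 0.81)}


@dataclass
class ClassificationMap:
    """Per-pixel TP/FN/TN/FP labelling of one prediction-set sample."""

    sample_id: str
    true_group: int
    categories: np.ndarray  # 2-D uint8, 0 = no data (background/fat)
    predicted: np.ndarray  # 2-D float, 1|2 on lean pixels, NaN elsewhere

    def fractions(self) -> dict[str, float]:
        lean = self.categories > 0
        n = int(lean.sum())
        return {name: float(np.sum(self.categories == code)) / n
                for name, code in MAP_CATEGORIES.items()}

    def to_rgb(self) -> np.ndarray:
        rgb = np.zeros(self.categories.shape + (3,))
        for code, color in MAP_COLORS.items():
            rgb[self.categories == code] = color
        return rgb


def classification_map(model: PLSDAModel, matrix, shape: tuple[int, int],
                       true_group: int) -> ClassificationMap:
    """Pixel-wise category map of one sample's full lean mask.

    ``matrix`` is the sample's pre-processed lean-pixel spectra matrix (one
    row per lean pixel).  Each lean pixel receives its predicted group and a
    TP/FN/TN/FP category against the sample's true group; background and fat
    are no-data.
    """
    if true_group not in (1, 2):
        raise ValueError("true_group must be 1 or 2")
    _, labels = predict(model, matrix.X)
    if true_group == 1:
        cats = np.where(labels == 1, MAP_CATEGORIES["TP"], MAP_CATEGORIES["FN"])
    else:
        cats = np.where(labels == 2, MAP_CATEGORIES["TN"], MAP_CATEGORIES["FP"])
    cat_map = refold(cats.astype(float), matrix.pixel_rows, matrix.pixel_cols,
                     shape, fill=0.0).astype(np.uint8)
    pred_map = refold(labels.astype(float), matrix.pixel_rows,
                      matrix.pixel_cols, shape)
    sid = str(matrix.sample_ids[0]) if len(matrix.sample_ids) else ""
    return ClassificationMap(sample_id=sid, true_group=true_group,
                             categories=cat_map, predicted=pred_map)
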