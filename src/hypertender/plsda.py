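"""Partial least squares discriminant analysis (PLS-DA) for pixel spectra.

The discriminant is a PLS2 regression of a two-column dummy class coding
(group 1 -> [1, 0], group 2 -> [0, 1]) on the spectra, fitted with the NIPALS
algorithm: latent variables (LVs) are extracted one at a time as the X
directions of maximal covariance with Y, with X (and Y) deflation after each
component.  For a two-class problem the centred Y block has rank one, so the
inner NIPALS loop converges in a single pass and the fit is fully
deterministic; the score vectors are mutually orthogonal by construction.

Class assignment is the argmax over the two predicted class scores, which for
the symmetric two-column coding equals a 0.5 threshold on either column.

Model selection uses Venetian-blinds cross-validation: blocking units (by
default whole samples, so pixels of one steak never straddle folds) are sorted
canonically and unit ``i`` goes to fold ``i mod n_splits``.  The LV count is
chosen by parsimony: the smallest count whose cross-validated mean correct
classification rate is within a tolerance (default 1 point) of the best.

Variable importance in projection (VIP) scores summarise how much each
wavelength contributes to the fitted LVs, weighted by the Y-variance each LV
explains; the mean squared VIP is identically 1, and wavelengths with
VIP > 1.0 are conventionally called influential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessSpec, run_chain

__all__ = [
    "PLSDAModel",
    "CVSpec",
    "fit",
    "predict",
    "cross_validate",
    "venetian_folds",
    "select_n_lv",
    "vip_scores",
    "vip_select",
]

MAX_LV_DEFAULT = 20
CLASS_CODES = {1: np.array([1.0, 0.0]), 2: np.array([0.0, 1.0])}


@dataclass
class PLSDAModel:
    """A fitted PLS-DA discriminant.

    ``W`` are the X-weights, ``P`` the X-loadings and ``Q`` the Y-loadings
    (bands x LV and classes x LV); ``B`` the regression coefficients
    (bands x classes) mapping centred spectra to class scores.  ``x_mean`` and
    ``y_mean`` are the centering vectors absorbed into prediction.
    """

    n_lv: int
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    B: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    explained_x_variance: np.ndarray  # cumulative, percent
    ssy_per_lv: np.ndarray = field(repr=False, default=None)
    wavelengths: np.ndarray | None = None

    @property
    def n_bands(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class CVSpec:
    """Venetian-blinds cross-validation settings."""

    n_splits: int = 10
    max_lv: int = MAX_LV_DEFAULT
    blocking_unit: str = "sample"  # or "pixel"

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if self.blocking_unit not in ("sample", "pixel"):
            raise ValueError("blocking_unit must be 'sample' or 'pixel'")


def _dummy_y(y_groups: np.ndarray) -> np.ndarray:
    y_groups = np.asarray(y_groups)
    if not set(np.unique(y_groups)) <= {1, 2}:
        raise ValueError("group labels must be 1 or 2")
    if len(np.unique(y_groups)) < 2:
        raise ValueError("both groups must be present to fit a discriminant")
    return np.stack([CLASS_CODES[int(g)] for g in y_groups])


def _nipals(Xc: np.ndarray, Yc: np.ndarray, n_lv: int,
            tol: float = 1e-12, max_iter: int = 500):
    """NIPALS PLS2 with X and Y deflation; returns W, P, Q, T."""
    n, p = Xc.shape
    m = Yc.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    T = np.zeros((n, n_lv))
    X, Y = Xc.copy(), Yc.copy()
    for a in range(n_lv):
        # deterministic start: the current dominant Y column
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if not np.any(u):
            raise ValueError(f"Y block exhausted after {a} latent variables")
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError(f"X block exhausted after {a} latent variables")
            w /= norm
            t = X @ w
            q = Y.T @ t / (t @ t)
            u = Y @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        tt = t @ t
        p_vec = X.T @ t / tt
        X = X - np.outer(t, p_vec)
        Y = Y - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q, t
    return W, P, Q, T


def fit(X_cal: np.ndarray, y_groups: np.ndarray, n_lv: int,
        wavelengths: np.ndarray | None = None) -> PLSDAModel:
    """Fit a PLS-DA model with ``n_lv`` latent variables.

    X and the dummy Y are centred internally (the centering vectors become
    part of the model).  ``n_lv`` must not exceed min(20-style cap handled by
    the caller, rank of the centred X).
    """
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    Y = _dummy_y(y_groups)
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    rank = np.linalg.matrix_rank(X_cal - X_cal.mean(axis=0)) if \
        min(X_cal.shape) <= 64 else min(X_cal.shape)
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds the rank {rank} of centred X")
    x_mean = X_cal.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X_cal - x_mean
    Yc = Y - y_mean
    W, P, Q, T = _nipals(Xc, Yc, n_lv)
    # B maps centred X to centred Y: B = W (P'W)^-1 Q'
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    total_x = np.sum(Xc ** 2)
    per_lv_x = (T ** 2).sum(axis=0) * (P ** 2).sum(axis=0)
    explained = 100.0 * np.cumsum(per_lv_x) / total_x if total_x > 0 else \
        np.zeros(n_lv)
    ssy = (T ** 2).sum(axis=0) * (Q ** 2).sum(axis=0)
    return PLSDAModel(n_lv=n_lv, W=W, P=P, Q=Q, B=B, x_mean=x_mean,
                      y_mean=y_mean, explained_x_variance=explained,
                      ssy_per_lv=ssy, wavelengths=wavelengths)


def predict(model: PLSDAModel, X_new: np.ndarray,
            n_lv: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Class scores and hard labels for new spectra.

    ``scores = (X_new - x_mean) @ B + y_mean``; the label is the class with
    the larger score.  ``n_lv`` may truncate the model to its leading LVs.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_bands:
        raise ValueError(f"band count {X_new.shape[1]} does not match the "
                         f"model's {model.n_bands}")
    if n_lv is None or n_lv == model.n_lv:
        B = model.B
    else:
        if not 1 <= n_lv <= model.n_lv:
            raise ValueError(f"n_lv must be in [1, {model.n_lv}]")
        W, P, Q = model.W[:, :n_lv], model.P[:, :n_lv], model.Q[:, :n_lv]
        B = W @ np.linalg.solve(P.T @ W, Q.T)
    scores = (X_new - model.x_mean) @ B + model.y_mean
    labels = np.where(scores[:, 0] >= scores[:, 1], 1, 2)
    return scores, labels


# ---------------------------------------------------------------------------
# Venetian-blinds cross-validation
# ---------------------------------------------------------------------------

def venetian_folds(units: np.ndarray, n_splits: int) -> list[np.ndarray]:
    """Fold membership masks: sorted unit ``i`` goes to fold ``i mod n_splits``.

    ``units`` is the per-row blocking unit (sample id, or row index for
    pixel-level blinds).  Units are sorted canonically so the assignment is
    reproducible without a seed.
    """
    units = np.asarray(units)
    unique = np.unique(units)  # canonical sort
    if len(unique) < n_splits:
        raise ValueError(f"{len(unique)} blocking units cannot fill "
                         f"{n_splits} splits")
    fold_of_unit = {u: i % n_splits for i, u in enumerate(unique)}
    fold_ids = np.asarray([fold_of_unit[u] for u in units])
    return [fold_ids == k for k in range(n_splits)]


def cross_validate(X_cal: np.ndarray, y_groups: np.ndarray, units: np.ndarray,
                   cv: CVSpec = CVSpec(),
                   preprocess: PreprocessSpec | None = None) -> list:
    """Per-LV aggregate confusion summaries under Venetian-blinds CV.

    For each fold, the pre-processing chain's learned statistics and the model
    are refit on the retained folds and the held-out rows are scored with
    1..max_lv latent variables; held-out predictions are pooled over folds
    into one confusion summary per LV count.
    """
    from .evaluate import confusion  # local import to avoid a cycle

    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y_groups = np.asarray(y_groups)
    if cv.blocking_unit == "pixel":
        units = np.arange(len(y_groups))
    folds = venetian_folds(units, cv.n_splits)
    max_lv = min(cv.max_lv, min(X_cal.shape) - 1)
    true_all: list[np.ndarray] = []
    pred_all: list[list[np.ndarray]] = [[] for _ in range(max_lv)]
    for held in folds:
        keep = ~held
        X_tr, X_ho = X_cal[keep], X_cal[held]
        if preprocess is not None:
            X_tr, X_ho = run_chain(preprocess, X_tr, X_ho)
        model = fit(X_tr, y_groups[keep], max_lv)
        true_all.append(y_groups[held])
        for a in range(1, max_lv + 1):
            _, labels = predict(model, X_ho, n_lv=a)
            pred_all[a - 1].append(labels)
    truth = np.concatenate(true_all)
    return [confusion(truth, np.concatenate(pred_all[a])) for a in range(max_lv)]


def select_n_lv(cv_summaries: list, tolerance_points: float = 1.0) -> int:
    """Parsimonious LV choice from per-LV CV summaries.

    Returns the smallest LV count whose mean CV correct-classification rate is
    within ``tolerance_points`` of the maximum over all candidates.
    """
    if not cv_summaries:
        raise ValueError("no CV summaries to select from")
    cc = np.asarray([s.mean_percent_cc for s in cv_summaries])
    best = cc.max()
    return int(np.nonzero(cc >= best - tolerance_points)[0][0]) + 1


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection per band.

    ``VIP_j = sqrt( p * sum_a[ SSY_a (w_ja / ||w_a||)^2 ] / sum_a SSY_a )``
    with ``SSY_a`` the Y-variance explained by LV ``a``.  The mean squared
    VIP equals 1 exactly.
    """
    W = model.W
    p = W.shape[0]
    w_norm2 = (W ** 2).sum(axis=0)
    ssy = model.ssy_per_lv
    contrib = (W ** 2 / w_norm2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


def vip_select(vip: np.ndarray, wavelengths: np.ndarray,
               threshold: float = 1.0) -> np.ndarray:
    """Wavelengths whose VIP exceeds the influence threshold (default 1.0)."""
    vip = np.asarray(vip)
    return np.asarray(wavelengths)[vip > threshold]
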