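"""Model evaluation: AUC, TSS, continuous Boyce index, null-model
significance testing, permutation variable importance, and marginal response
curves.

AUC is threshold-independent (rank probability that a presence outscores an
absence); TSS is sensitivity + specificity − 1 maximized over observed
thresholds; the continuous Boyce index rank-correlates the
predicted-to-expected presence ratio with suitability across overlapping
windows, the natural presence-only calibration check. Null-model testing
asks whether the observed AUC beats what models trained on random points
achieve by chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Metric needs both classes present."""


@dataclass
class EvalMetrics:
    """One evaluation: AUC ∈ [0,1], TSS ∈ [−1,1] with its operating
    threshold, and optionally the Boyce index ∈ [−1,1]."""

    auc: float
    tss: float
    tss_threshold: float
    boyce: float = float("nan")


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise UndefinedMetricError("need both classes (0 and 1) present")
    return labels


def auc(labels, scores) -> float:
    """Rank-based (Mann–Whitney, tie-corrected) area under the ROC curve."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def tss(labels, scores) -> tuple[float, float]:
    """Maximum true skill statistic over observed score thresholds.

    Returns ``(tss, threshold)`` where the threshold attains the maximum of
    sensitivity + specificity − 1 (Youden's J); presences are predicted where
    score ≥ threshold.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, float)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    # drop roc_curve's +inf sentinel: the search is over observed scores only,
    # so the returned threshold always attains the returned TSS
    fpr, tpr, thresholds = fpr[1:], tpr[1:], thresholds[1:]
    j = tpr - fpr
    best = int(np.argmax(j))
    return float(j[best]), float(thresholds[best])


def boyce_index(
    presence_scores,
    background_scores,
    n_bins: int = 101,
    window_width: float | None = None,
) -> float:
    """Continuous Boyce index over overlapping suitability windows.

    For each of ``n_bins`` windows (default width: 1/10 of the background
    score range) the predicted-to-expected ratio P/E compares the fraction of
    presence scores falling in the window with the fraction of background
    scores there; the index is the Spearman correlation between P/E and the
    window midpoint over windows with non-zero expected fraction.
    """
    pres = np.asarray(presence_scores, float)
    back = np.asarray(background_scores, float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("presence and background scores must be non-empty")
    lo, hi = float(back.min()), float(back.max())
    rng = hi - lo
    if rng == 0:
        warnings.warn("degenerate background: all scores identical")
        return float("nan")
    w = window_width if window_width is not None else 0.1 * rng
    mids = np.linspace(lo + w / 2, hi - w / 2, n_bins)
    pe, used_mids = [], []
    for m in mids:
        a, b = m - w / 2, m + w / 2
        e = np.mean((back >= a) & (back <= b))
        if e == 0:
            continue
        p = np.mean((pres >= a) & (pres <= b))
        pe.append(p / e)
        used_mids.append(m)
    if len(used_mids) < n_bins:
        logger.debug("boyce: %d of %d windows had background mass", len(used_mids), n_bins)
    if len(used_mids) < 3:
        warnings.warn("boyce: fewer than 3 usable windows; index unreliable")
        return float("nan")
    rho = spearmanr(pe, used_mids).statistic
    return float(rho)


def evaluate(labels, scores, background_scores=None) -> EvalMetrics:
    """AUC + TSS (+ Boyce when background scores are supplied)."""
    a = auc(labels, scores)
    t, thr = tss(labels, scores)
    b = float("nan")
    if background_scores is not None:
        pres = np.asarray(scores, float)[np.asarray(labels) == 1]
        b = boyce_index(pres, background_scores)
    return EvalMetrics(auc=a, tss=t, tss_threshold=thr, boyce=b)


@dataclass
class NullModelResult:
    """Observed AUC against the null distribution of random-point models."""

    observed_auc: float
    null_aucs: np.ndarray
    ci95_upper: float
    significant: bool


def random_points(stack, n: int, rng: np.random.Generator):
    """Uniform random presence points over the valid cells of a stack."""
    from .occurrences import OccurrenceSet

    valid = np.flatnonzero(stack.mask.ravel())
    if valid.size < n:
        raise ValueError("not enough valid cells")
    idx = rng.choice(valid, size=n, replace=False)
    row, col = np.unravel_index(idx, stack.grid.shape)
    x, y = stack.grid.xy(row, col)
    df = pd.DataFrame({"id": [f"null{i}" for i in range(n)], "x": x, "y": y, "source": "synthetic"})
    return OccurrenceSet(df, crs=stack.grid.crs)


def null_model_test(
    fit_eval,
    stack,
    n_presences: int,
    observed_auc: float,
    n_iter: int = 99,
    seed: int = 0,
) -> NullModelResult:
    """Raes & ter Steege-style null-model significance test.

    ``fit_eval(points, seed) -> auc`` must run the same fit/evaluate protocol
    as the observed model. The observed AUC is significant when it exceeds
    the 95th percentile (one-sided, type-7 interpolation) of ``n_iter`` null
    AUCs from models trained on uniformly random points.
    """
    if n_iter < 19:
        raise ValueError("n_iter must be >= 19 for a 95th percentile")
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_iter)
    for i in range(n_iter):
        pts = random_points(stack, n_presences, rng)
        try:
            nulls[i] = fit_eval(pts, int(rng.integers(2**31 - 1)))
        except Exception as exc:  # propagate with the iteration index
            raise RuntimeError(f"null-model iteration {i} failed: {exc}") from exc
    upper = float(np.quantile(nulls, 0.95))  # numpy default = type-7 linear
    return NullModelResult(
        observed_auc=float(observed_auc),
        null_aucs=nulls,
        ci95_upper=upper,
        significant=bool(observed_auc > upper),
    )


def variable_importance(
    predict,
    frame: pd.DataFrame,
    labels,
    variables: list[str] | None = None,
    metric: str = "AUC",
    n_perm: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance: mean drop in AUC (or TSS) when a variable's
    column is shuffled, floored at zero.

    ``predict(frame) -> scores`` is the fitted model's scoring function on a
    raw (unstandardized) predictor frame.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    variables = variables or list(frame.columns)

    def _score(fr):
        s = predict(fr)
        return auc(labels, s) if metric.upper() == "AUC" else tss(labels, s)[0]

    base = _score(frame)
    out = {}
    for var in variables:
        drops = []
        for _ in range(n_perm):
            shuffled = frame.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            drops.append(base - _score(shuffled))
        out[var] = max(0.0, float(np.mean(drops)))
    return out


def response_curve(
    predict,
    reference: pd.DataFrame,
    variable: str,
    n_points: int = 100,
    categorical: set[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal response: vary one predictor over its observed range while
    holding the others at their regional mean (mode for categorical layers).

    ``reference`` holds regional predictor values (e.g. all valid cells or a
    seeded subsample); returns ``(x_grid, predicted_suitability)``.
    """
    if variable not in reference.columns:
        raise KeyError(f"unknown variable {variable!r}")
    categorical = categorical or set()
    base = {}
    for col in reference.columns:
        if col in categorical:
            base[col] = reference[col].mode().iloc[0]
        else:
            base[col] = reference[col].mean()
    vals = reference[variable]
    if variable in categorical:
        xg = np.sort(vals.unique())
    else:
        xg = np.linspace(vals.min(), vals.max(), n_points)
    frame = pd.DataFrame({col: np.repeat(base[col], len(xg)) for col in reference.columns})
    frame[variable] = xg
    return xg, np.asarray(predict(frame), float)
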