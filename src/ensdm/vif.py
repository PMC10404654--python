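"""Variance-inflation-factor computation and stepwise collinearity elimination.

VIF_j = 1/(1 - R²_j), with R²_j from the OLS regression of predictor j on all
other predictors (plus intercept). Predictors are eliminated one at a time —
always the current worst — until every surviving VIF sits below the
threshold (10 by default, the conventional cut-off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data


class ConstantColumnError(ValueError):
    """A predictor is constant; its VIF is undefined."""


def compute_vif(design: np.ndarray | pd.DataFrame) -> np.ndarray:
    """VIF for each column of an (n, p) design of continuous predictors.

    Perfectly collinear columns get ``inf``. Requires n > p ≥ 2 and
    non-constant columns.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D")
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two predictors")
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    stds = X.std(axis=0)
    if np.any(stds == 0):
        bad = np.flatnonzero(stds == 0).tolist()
        raise ConstantColumnError(f"constant column(s) at index {bad}")

    vifs = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        Z = np.concatenate([ones, np.delete(X, j, axis=1)], axis=1)
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        # numerical guard: R² can exceed 1 by rounding when collinearity is exact
        if r2 >= 1.0 - 1e-12:
            vifs[j] = np.inf
        else:
            vifs[j] = 1.0 / (1.0 - r2)
    return vifs


@dataclass
class EliminationStep:
    dropped: str
    vif: float
    remaining: list[str] = field(default_factory=list)


def vif_eliminate(
    design: pd.DataFrame | np.ndarray,
    threshold: float = 10.0,
    names: list[str] | None = None,
) -> tuple[list[str], list[EliminationStep]]:
    """Iteratively drop the highest-VIF predictor until all VIFs < threshold.

    Ties on the maximum VIF are broken by column-name order (earliest name
    dropped) for determinism. Returns (survivors in input order, trace).
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    current = list(range(X.shape[1]))
    trace: list[EliminationStep] = []
    while len(current) >= 2:
        vifs = compute_vif(X[:, current])
        vmax = vifs.max()
        if vmax < threshold:
            break
        ties = np.flatnonzero(vifs == vmax)
        drop_local = min(ties, key=lambda i: names[current[i]])
        dropped = current.pop(drop_local)
        trace.append(
            EliminationStep(
                dropped=names[dropped],
                vif=float(vmax),
                remaining=[names[i] for i in current],
            )
        )
    return [names[i] for i in current], trace


def elimination_trace_frame(trace: list[EliminationStep]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "step": range(1, len(trace) + 1),
            "dropped": [s.dropped for s in trace],
            "vif": [s.vif for s in trace],
            "remaining": [";".join(s.remaining) for s in trace],
        }
    )


class VIFSelector(SelectorMixin, BaseEstimator):
    """Feature selector removing collinear predictors by stepwise VIF.

    scikit-learn transformer: ``fit`` learns which continuous columns survive
    the elimination loop, ``transform`` subsets them. Composes with
    ``sklearn.pipeline.Pipeline``.

    Parameters
    ----------
    threshold : float, default=10.0
        Elimination stops once every remaining VIF is below this value.

    Attributes
    ----------
    support_ : ndarray of bool, shape (n_features,)
        Mask of retained features.
    trace_ : list of EliminationStep
        Which feature was dropped at each step and at what VIF.
    vifs_ : ndarray
        Final VIFs of the surviving features.
    """

    def __init__(self, threshold: float = 10.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
        else:
            names = None
        X = validate_data(self, X, ensure_min_features=2)
        names = names or [f"x{j}" for j in range(X.shape[1])]
        survivors, trace = vif_eliminate(X, threshold=self.threshold, names=names)
        self.trace_ = trace
        self.support_ = np.isin(names, survivors)
        kept = X[:, self.support_]
        self.vifs_ = compute_vif(kept) if kept.shape[1] >= 2 else np.ones(kept.shape[1])
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
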