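"""Ensemble species distribution modelling.

The protocol: each learner family is fitted as 10 replicates; every
replicate takes a fresh 70/30 presence-level split and a fresh pseudo-absence
draw, runs 5-fold cross-validation inside the training portion, and is
scored on the held-out 30%. Families whose mean held-out AUC falls below 0.8
are excluded; the remaining replicate fits form a weighted-mean ensemble
with weights proportional to each fit's accuracy metric (TSS by default).

Presence–absence families (GLM, MARS, BRT, RF) train against equal numbers
of pseudo-absences drawn outside a 5 km buffer around presences; the
maximum-entropy-style family trains against a large unconstrained background
sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .grid import PredictorStack, Raster
from .learners import (
    BACKGROUND_FAMILIES,
    FAMILIES,
    LearnerSpec,
    make_learner,
)
from .metrics import EvalMetrics, auc as auc_metric, tss as tss_metric
from .occurrences import OccurrenceSet
from .predictors import Standardizer, extract_at_points

logger = logging.getLogger(__name__)

DEFAULT_N_BACKGROUND = 10_000


class EnsembleError(RuntimeError):
    """No learner family passed the inclusion rule."""


class StratificationError(RuntimeError):
    """A split or fold lost one of the classes."""


def generate_pseudo_absences(
    presences: OccurrenceSet,
    stack: PredictorStack,
    n: int | None = None,
    exclusion_km: float = 5.0,
    strategy: str = "equal_buffered",
    seed: int = 0,
    n_background: int = DEFAULT_N_BACKGROUND,
) -> OccurrenceSet:
    """Draw pseudo-absence / background points from the stack's valid cells.

    ``equal_buffered`` (presence–absence learners): ``n`` points (defaults to
    the presence count) uniformly from cells at least ``exclusion_km`` from
    every presence. ``background_large`` (MaxEnt-style): ``n_background``
    points from all valid cells, no buffer and no count constraint.
    """
    rng = np.random.default_rng(seed)
    grid = stack.grid
    xs, ys = grid.cell_centers()
    valid = stack.mask.ravel()

    if strategy == "equal_buffered":
        n = len(presences) if n is None else n
        tree = cKDTree(presences.xy)
        d, _ = tree.query(np.column_stack([xs.ravel(), ys.ravel()]), k=1)
        eligible = valid & (d >= exclusion_km)
        n_eligible = int(eligible.sum())
        if n_eligible < n:
            raise ValueError(
                f"pseudo-absence sampling needs {n} cells but only {n_eligible} lie "
                f"outside the {exclusion_km} km presence buffers (deficit {n - n_eligible})"
            )
        idx = rng.choice(np.flatnonzero(eligible), size=n, replace=False)
        prefix = "pa"
    elif strategy == "background_large":
        pool = np.flatnonzero(valid)
        take = min(n_background, pool.size)
        idx = rng.choice(pool, size=take, replace=False)
        prefix = "bg"
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    row, col = np.unravel_index(idx, grid.shape)
    px, py = grid.xy(row, col)
    df = pd.DataFrame(
        {"id": [f"{prefix}{i}" for i in range(len(idx))], "x": px, "y": py, "source": "synthetic"}
    )
    return OccurrenceSet(df, crs=grid.crs)


@dataclass
class FeatureBuilder:
    """Raw predictor frame → numeric design matrix.

    Continuous layers are z-scored with statistics frozen on the baseline
    stack; categorical layers are one-hot encoded against the category list
    observed at fit time, so scenario stacks project onto identical columns.
    """

    variables: list[str]
    standardizer: Standardizer
    categories: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_stack(cls, stack: PredictorStack, variables: list[str]) -> "FeatureBuilder":
        missing = [v for v in variables if v not in stack]
        if missing:
            raise KeyError(f"stack lacks layers {missing}")
        std = Standardizer.fit(stack, [v for v in variables if v not in stack.categorical])
        cats = {
            v: np.unique(stack[v][stack.mask])
            for v in variables
            if v in stack.categorical
        }
        return cls(variables=variables, standardizer=std, categories=cats)

    @property
    def columns(self) -> list[str]:
        cols = []
        for v in self.variables:
            if v in self.categories:
                cols.extend(f"{v}={int(c)}" for c in self.categories[v])
            else:
                cols.append(v)
        return cols

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        blocks = []
        for v in self.variables:
            vals = frame[v].to_numpy()
            if v in self.categories:
                blocks.append((vals[:, None] == self.categories[v][None, :]).astype(float))
            else:
                blocks.append(self.standardizer.transform_layer(v, vals.astype(float))[:, None])
        return np.concatenate(blocks, axis=1)


@dataclass
class ReplicateFit:
    """One fitted replicate: CV fold metrics plus held-out test metrics."""

    family: str
    replicate_index: int  # 1-based
    fold_metrics: list[EvalMetrics]
    test_metrics: EvalMetrics
    learner: object
    seed: int


def _eval(labels, scores) -> EvalMetrics:
    a = auc_metric(labels, scores)
    t, thr = tss_metric(labels, scores)
    return EvalMetrics(auc=a, tss=t, tss_threshold=thr)


def fit_replicates(
    X: np.ndarray,
    y: np.ndarray,
    spec: LearnerSpec,
    n_replicates: int = 10,
    n_folds: int = 5,
    train_fraction: float = 0.7,
    seed: int = 0,
    absence_pool: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> list[ReplicateFit]:
    """Fit one family's replicates on a labelled design.

    Per replicate: a fresh stratified split into ``train_fraction`` training
    and the rest test; ``n_folds``-fold CV inside the training portion; a
    final fit on the whole training portion scored on the held-out rows.
    When ``absence_pool`` is given, each replicate's 0-class rows are redrawn
    from it (fresh pseudo-absences), keeping the supplied absence count.
    When ``background`` is given (maximum-entropy-style families), its rows
    are appended as extra 0-class rows to every *training* fit while fold and
    held-out evaluations stay on the design rows, so families remain
    comparable under the same test protocol.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise StratificationError("design must contain both classes")
    pres = X[y == 1]
    n_abs = int((y == 0).sum())
    fits: list[ReplicateFit] = []
    for r in range(n_replicates):
        rep_seed = (seed + 104729 * (r + 1)) % (2**31 - 1)
        rng = np.random.default_rng(rep_seed)
        if absence_pool is not None:
            take = rng.choice(len(absence_pool), size=min(n_abs, len(absence_pool)), replace=False)
            absn = np.asarray(absence_pool, float)[take]
        else:
            absn = X[y == 0]
        Xr = np.vstack([pres, absn])
        yr = np.concatenate([np.ones(len(pres), int), np.zeros(len(absn), int)])
        try:
            Xtr, Xte, ytr, yte = train_test_split(
                Xr, yr, train_size=train_fraction, stratify=yr, random_state=rep_seed % (2**32 - 1)
            )
        except ValueError as exc:
            raise StratificationError(str(exc)) from exc
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            raise StratificationError("train/test split lost a class")

        def _augment(Xa_, ya_):
            if background is None:
                return Xa_, ya_
            return (
                np.vstack([Xa_, background]),
                np.concatenate([ya_, np.zeros(len(background), int)]),
            )

        fold_metrics = []
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed % (2**32 - 1))
        for tr_idx, va_idx in skf.split(Xtr, ytr):
            if len(np.unique(ytr[va_idx])) < 2:
                raise StratificationError("a CV fold lost a class")
            lrn = make_learner(spec, seed=rep_seed)
            lrn.fit(*_augment(Xtr[tr_idx], ytr[tr_idx]))
            fold_metrics.append(_eval(ytr[va_idx], lrn.predict_score(Xtr[va_idx])))

        final = make_learner(spec, seed=rep_seed)
        final.fit(*_augment(Xtr, ytr))
        test_metrics = _eval(yte, final.predict_score(Xte))
        fits.append(
            ReplicateFit(
                family=spec.family,
                replicate_index=r + 1,
                fold_metrics=fold_metrics,
                test_metrics=test_metrics,
                learner=final,
                seed=rep_seed,
            )
        )
    return fits


def build_ensemble(
    replicates: dict[str, list[ReplicateFit]],
    inclusion_auc: float = 0.8,
    weight_metric: str = "TSS",
) -> tuple[list[tuple[str, int, float]], list[str], list[str], pd.DataFrame]:
    """Accuracy-gated weighting of replicate fits.

    Families whose mean held-out AUC is below ``inclusion_auc`` are excluded
    wholesale. Weights are per replicate fit, proportional to its held-out
    ``weight_metric`` (TSS or AUC, clipped at 0) and normalized to sum to 1.

    Returns (weights as (family, replicate_index, weight), included families,
    excluded families, per-family metric summary).
    """
    weight_metric = weight_metric.upper()
    if weight_metric not in ("TSS", "AUC"):
        raise ValueError("weight_metric must be TSS or AUC")
    rows = []
    included, excluded = [], []
    for family, fits in replicates.items():
        mean_auc = float(np.mean([f.test_metrics.auc for f in fits]))
        mean_tss = float(np.mean([f.test_metrics.tss for f in fits]))
        cv_auc = float(np.mean([m.auc for f in fits for m in f.fold_metrics]))
        cv_tss = float(np.mean([m.tss for f in fits for m in f.fold_metrics]))
        ok = mean_auc >= inclusion_auc
        rows.append(
            {
                "family": family, "test_auc": mean_auc, "test_tss": mean_tss,
                "cv_auc": cv_auc, "cv_tss": cv_tss, "included": ok,
            }
        )
        (included if ok else excluded).append(family)
    if not included:
        raise EnsembleError(
            f"no family reached mean AUC {inclusion_auc}; "
            f"best = {max(r['test_auc'] for r in rows):.3f}"
        )
    raw = []
    for family in included:
        for f in replicates[family]:
            m = f.test_metrics.tss if weight_metric == "TSS" else f.test_metrics.auc
            raw.append((family, f.replicate_index, max(0.0, float(m))))
    total = sum(w for _, _, w in raw)
    if total == 0:
        w0 = 1.0 / len(raw)
        weights = [(fam, idx, w0) for fam, idx, _ in raw]
    else:
        weights = [(fam, idx, w / total) for fam, idx, w in raw]
    summary = pd.DataFrame(rows)
    return weights, included, excluded, summary


class EnsembleSDM(BaseEstimator):
    """Accuracy-gated weighted-mean ensemble over five learner families.

    scikit-learn style estimator. ``fit(X, y)`` takes a numeric design with
    presence labels (1) and pseudo-absence/background labels (0); each family
    is fitted as replicates with per-replicate resplits (see
    :func:`fit_replicates`). ``predict_proba`` / ``decision_function`` return
    the weighted-mean suitability of the included fits, a convex combination
    of member scores.

    Parameters
    ----------
    families : sequence of str
        Learner families, subset of ``("GLM", "MARS", "BRT", "RF", "MAXENT")``.
    n_replicates, n_folds, train_fraction :
        Replicate/CV protocol (defaults 10, 5, 0.7).
    inclusion_auc : float
        Families below this mean held-out AUC are dropped (default 0.8).
    weight_metric : {"TSS", "AUC"}
        Held-out metric that sets the member weights.
    learner_params : dict, optional
        Per-family hyperparameter overrides, e.g. ``{"RF": {"n_estimators": 100}}``.
    random_state : int

    Attributes
    ----------
    replicates_ : dict family -> list of ReplicateFit
    weights_ : list of (family, replicate_index, weight), summing to 1
    included_families_, excluded_families_ : list of str
    family_summary_ : DataFrame of per-family CV and held-out metrics
    """

    def __init__(
        self,
        families=FAMILIES,
        n_replicates: int = 10,
        n_folds: int = 5,
        train_fraction: float = 0.7,
        inclusion_auc: float = 0.8,
        weight_metric: str = "TSS",
        learner_params: dict | None = None,
        random_state: int = 0,
    ):
        self.families = families
        self.n_replicates = n_replicates
        self.n_folds = n_folds
        self.train_fraction = train_fraction
        self.inclusion_auc = inclusion_auc
        self.weight_metric = weight_metric
        self.learner_params = learner_params
        self.random_state = random_state

    def fit(self, X, y, absence_pool=None, background=None):
        """Fit all families.

        ``absence_pool`` — optional (m, p) matrix of eligible pseudo-absence
        feature rows; replicates redraw their 0-class rows from it.
        ``background`` — optional (m, p) matrix of background feature rows
        appended as training-only 0-class rows for background-sample
        families (MAXENT).
        """
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        params = self.learner_params or {}
        self.replicates_ = {}
        for k, family in enumerate(self.families):
            spec = LearnerSpec(family, params.get(family, {}))
            fam_seed = (self.random_state + 7919 * k) % (2**31 - 1)
            bg = background if family in BACKGROUND_FAMILIES else None
            self.replicates_[family] = fit_replicates(
                X, y, spec,
                n_replicates=self.n_replicates,
                n_folds=self.n_folds,
                train_fraction=self.train_fraction,
                seed=fam_seed,
                absence_pool=absence_pool,
                background=bg,
            )
        (
            self.weights_,
            self.included_families_,
            self.excluded_families_,
            self.family_summary_,
        ) = build_ensemble(
            self.replicates_, inclusion_auc=self.inclusion_auc, weight_metric=self.weight_metric
        )
        if self.excluded_families_:
            logger.info("excluded families (mean AUC < %.2f): %s",
                        self.inclusion_auc, self.excluded_families_)
        self._fit_index = {
            (fam, f.replicate_index): f for fam, fits in self.replicates_.items() for f in fits
        }
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def member_scores(self, X) -> np.ndarray:
        """(n_members, n_samples) scores of the included fits, weight order."""
        check_is_fitted(self, "weights_")
        X = np.asarray(X, float)
        return np.vstack(
            [self._fit_index[(fam, idx)].learner.predict_score(X) for fam, idx, _ in self.weights_]
        )

    def decision_function(self, X) -> np.ndarray:
        scores = self.member_scores(X)
        w = np.array([w for _, _, w in self.weights_])
        return w @ scores

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)


@dataclass
class SDMModel:
    """A fitted model bound to its variable set and feature encoding.

    Wraps the design-level :class:`EnsembleSDM` with the raster-facing
    plumbing: raw layer frames are encoded by the stored
    :class:`FeatureBuilder` (frozen standardization + one-hot categories), so
    the same model projects consistently onto baseline and scenario stacks.
    """

    name: str
    builder: FeatureBuilder
    ensemble: EnsembleSDM

    @property
    def variables(self) -> list[str]:
        return self.builder.variables

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        return self.ensemble.decision_function(self.builder.transform(frame))

    def predict_surface(self, stack: PredictorStack) -> Raster:
        """Weighted-mean suitability raster in [0, 1]; no-data propagated."""
        missing = [v for v in self.variables if v not in stack]
        if missing:
            raise KeyError(f"stack lacks layers {missing}")
        frame = pd.DataFrame({v: stack[v][stack.mask] for v in self.variables})
        scores = self.predict_frame(frame)
        out = np.full(stack.grid.shape, np.nan)
        out[stack.mask] = scores
        return Raster(out, stack.grid, stack.mask.copy(), f"suitability_{self.name}")


def predict_surface(model: SDMModel, stack: PredictorStack) -> Raster:
    """Module-level convenience wrapper over :meth:`SDMModel.predict_surface`."""
    return model.predict_surface(stack)


def fit_sdm(
    presences: OccurrenceSet,
    stack: PredictorStack,
    variables: list[str],
    name: str = "model",
    families=FAMILIES,
    n_replicates: int = 10,
    n_folds: int = 5,
    train_fraction: float = 0.7,
    inclusion_auc: float = 0.8,
    weight_metric: str = "TSS",
    exclusion_km: float = 5.0,
    n_background: int = DEFAULT_N_BACKGROUND,
    learner_params: dict | None = None,
    seed: int = 0,
) -> SDMModel:
    """Fit the full protocol from occurrences and a predictor stack.

    Builds the frozen feature encoding, draws buffered equal-count
    pseudo-absences (with a pool for per-replicate redraws) and a large
    background sample, fits every family, and gates/weights the ensemble.
    """
    builder = FeatureBuilder.from_stack(stack, variables)
    pres_frame = extract_at_points(stack, presences.xy[:, 0], presences.xy[:, 1], variables)
    Xp = builder.transform(pres_frame)

    pa = generate_pseudo_absences(
        presences, stack, exclusion_km=exclusion_km, strategy="equal_buffered", seed=seed
    )
    pa_frame = extract_at_points(stack, pa.xy[:, 0], pa.xy[:, 1], variables)
    Xa = builder.transform(pa_frame)

    # large eligible pool for fresh per-replicate pseudo-absence draws
    pool_pts = generate_pseudo_absences(
        presences, stack,
        n=min(max(4 * len(presences), 1000), _n_eligible(presences, stack, exclusion_km)),
        exclusion_km=exclusion_km, strategy="equal_buffered", seed=seed + 1,
    )
    pool_frame = extract_at_points(stack, pool_pts.xy[:, 0], pool_pts.xy[:, 1], variables)
    pool = builder.transform(pool_frame)

    bg = generate_pseudo_absences(
        presences, stack, strategy="background_large", n_background=n_background, seed=seed + 2
    )
    bg_frame = extract_at_points(stack, bg.xy[:, 0], bg.xy[:, 1], variables)
    Xbg = builder.transform(bg_frame)

    X = np.vstack([Xp, Xa])
    y = np.concatenate([np.ones(len(Xp), int), np.zeros(len(Xa), int)])
    ens = EnsembleSDM(
        families=families,
        n_replicates=n_replicates,
        n_folds=n_folds,
        train_fraction=train_fraction,
        inclusion_auc=inclusion_auc,
        weight_metric=weight_metric,
        learner_params=learner_params,
        random_state=seed,
    )
    ens.fit(X, y, absence_pool=pool, background=Xbg)
    return SDMModel(name=name, builder=builder, ensemble=ens)


def _n_eligible(presences: OccurrenceSet, stack: PredictorStack, exclusion_km: float) -> int:
    xs, ys = stack.grid.cell_centers()
    tree = cKDTree(presences.xy)
    d, _ = tree.query(np.column_stack([xs.ravel(), ys.ravel()]), k=1)
    return int((stack.mask.ravel() & (d >= exclusion_km)).sum())
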