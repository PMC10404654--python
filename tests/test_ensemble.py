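import numpy as np
import pandas as pd
import pytest

from ensdm.ensemble import (
    EnsembleError,
    EnsembleSDM,
    FeatureBuilder,
    ReplicateFit,
    StratificationError,
    build_ensemble,
    fit_replicates,
    fit_sdm,
    generate_pseudo_absences,
)
from ensdm.grid import GridSpec, PredictorStack, Raster
from ensdm.learners import FAMILIES, LearnerSpec, make_learner
from ensdm.metrics import EvalMetrics
from ensdm.occurrences import OccurrenceSet


def occ_at(xy):
    xy = np.asarray(xy, float)
    return OccurrenceSet(
        pd.DataFrame({"id": [f"p{i}" for i in range(len(xy))], "x": xy[:, 0], "y": xy[:, 1]})
    )


def _stack(n=30, seed=0):
    g = GridSpec(n_rows=n, n_cols=n)
    st = PredictorStack(grid=g)
    st.add("a", np.random.default_rng(seed).normal(size=g.shape))
    return st


class TestPseudoAbsences:
    def test_equal_count_and_buffer_respected(self):
        stack = _stack(40)
        pres = occ_at([[5.5, 5.5], [30.5, 30.5], [20.5, 10.5]])
        pa = generate_pseudo_absences(pres, stack, exclusion_km=5, seed=0)
        assert len(pa) == len(pres)
        # exhaustive pairwise check
        d = np.sqrt(((pa.xy[:, None] - pres.xy[None]) ** 2).sum(-1))
        assert (d >= 5.0).all()

    def test_buffer_covering_extent_errors(self):
        stack = _stack(10)
        pres = occ_at([[5.0, 5.0]])
        with pytest.raises(ValueError, match="deficit"):
            generate_pseudo_absences(pres, stack, exclusion_km=50, seed=0)

    def test_background_ignores_buffer_and_count(self):
        stack = _stack(20)
        pres = occ_at([[10.0, 10.0]])
        bg = generate_pseudo_absences(
            pres, stack, strategy="background_large", n_background=300, seed=1
        )
        assert len(bg) == 300

    def test_unknown_strategy(self):
        with pytest.raises(ValueError):
            generate_pseudo_absences(occ_at([[1, 1]]), _stack(), strategy="nope")


class TestLearners:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_fit_predict_contract(self, family, rng):
        X = rng.normal(size=(120, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=120) > 0).astype(int)
        lrn = make_learner(LearnerSpec(family), seed=0)
        s = lrn.fit(X, y).predict_score(X)
        assert s.shape == (120,)
        assert s.min() >= 0.0 and s.max() <= 1.0

    def test_glm_recovers_coefficient_sign(self, rng):
        X = rng.normal(size=(500, 2))
        p = 1 / (1 + np.exp(-(1.5 * X[:, 0] - 1.0 * X[:, 1])))
        y = (rng.uniform(size=500) < p).astype(int)
        glm = make_learner(LearnerSpec("GLM")).fit(X, y)
        assert glm.coef_[0] > 0 > glm.coef_[1]


class TestFitReplicates:
    def _design(self, rng, n=120, separable=False):
        X = rng.normal(size=(n, 2))
        if separable:
            y = (X[:, 0] > 0).astype(int)
        else:
            y = (X[:, 0] + rng.normal(size=n) > 0).astype(int)
        return X, y

    def test_separable_data_gives_perfect_glm_auc(self, rng):
        X, y = self._design(rng, separable=True)
        fits = fit_replicates(X, y, LearnerSpec("GLM"), n_replicates=2, seed=0)
        for f in fits:
            assert f.test_metrics.auc == 1.0

    def test_shuffled_labels_give_chance_auc(self, rng):
        X = rng.normal(size=(200, 2))
        y = rng.permutation(np.r_[np.ones(100, int), np.zeros(100, int)])
        fits = fit_replicates(X, y, LearnerSpec("GLM"), n_replicates=8, seed=1)
        mean_auc = np.mean([f.test_metrics.auc for f in fits])
        assert abs(mean_auc - 0.5) < 0.12

    def test_fold_count_and_structure(self, rng):
        X, y = self._design(rng)
        fits = fit_replicates(X, y, LearnerSpec("GLM"), n_replicates=3, n_folds=5, seed=2)
        assert len(fits) == 3
        for f in fits:
            assert len(f.fold_metrics) == 5
            assert np.isfinite(f.test_metrics.auc)

    def test_identical_seed_identical_metrics(self, rng):
        X, y = self._design(rng)
        a = fit_replicates(X, y, LearnerSpec("GLM"), n_replicates=2, seed=9)
        b = fit_replicates(X, y, LearnerSpec("GLM"), n_replicates=2, seed=9)
        assert [f.test_metrics.auc for f in a] == [f.test_metrics.auc for f in b]

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(50, 2))
        with pytest.raises(StratificationError):
            fit_replicates(X, np.ones(50, int), LearnerSpec("GLM"))

    def test_label_noise_degrades_auc(self, rng):
        X = rng.normal(size=(300, 2))
        y_clean = (X[:, 0] > 0).astype(int)
        aucs = []
        for noise in (0.0, 0.2, 0.4):
            y = y_clean.copy()
            flip = rng.uniform(size=len(y)) < noise
            y[flip] = 1 - y[flip]
            if y.min() == y.max():
                continue
            fits = fit_replicates(X, y, LearnerSpec("GLM"), n_replicates=4, seed=3)
            aucs.append(np.mean([f.test_metrics.auc for f in fits]))
        assert aucs[0] > aucs[1] > aucs[2]


def _fake_fit(family, idx, auc, tss):
    m = EvalMetrics(auc=auc, tss=tss, tss_threshold=0.5)
    return ReplicateFit(family, idx, [m], m, learner=None, seed=0)


class TestBuildEnsemble:
    def test_single_passing_family_takes_all_weight(self):
        reps = {
            "RF": [_fake_fit("RF", 1, 0.9, 0.7), _fake_fit("RF", 2, 0.88, 0.6)],
            "GLM": [_fake_fit("GLM", 1, 0.72, 0.39)],
        }
        weights, included, excluded, _ = build_ensemble(reps)
        assert included == ["RF"] and excluded == ["GLM"]
        assert sum(w for _, _, w in weights) == pytest.approx(1.0)
        assert all(fam == "RF" for fam, _, _ in weights)

    def test_low_auc_family_excluded(self):
        reps = {
            "GLM": [_fake_fit("GLM", 1, 0.72, 0.39)],
            "RF": [_fake_fit("RF", 1, 0.88, 0.66)],
        }
        _, included, excluded, summary = build_ensemble(reps, inclusion_auc=0.8)
        assert "GLM" in excluded
        row = summary[summary.family == "GLM"].iloc[0]
        assert not row["included"]

    def test_equal_metric_equal_weights(self):
        reps = {"RF": [_fake_fit("RF", 1, 0.9, 0.6), _fake_fit("RF", 2, 0.9, 0.6)]}
        weights, *_ = build_ensemble(reps)
        assert weights[0][2] == pytest.approx(weights[1][2]) == pytest.approx(0.5)

    def test_all_failing_raises(self):
        reps = {"GLM": [_fake_fit("GLM", 1, 0.6, 0.2)]}
        with pytest.raises(EnsembleError):
            build_ensemble(reps)

    def test_auc_weighting_switch(self):
        reps = {"RF": [_fake_fit("RF", 1, 0.95, 0.0), _fake_fit("RF", 2, 0.85, 0.0)]}
        weights, *_ = build_ensemble(reps, weight_metric="AUC")
        assert weights[0][2] > weights[1][2]


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(200, 3))
    y = (X[:, 0] - X[:, 1] + 0.5 * rng.normal(size=200) > 0).astype(int)
    ens = EnsembleSDM(
        families=("GLM", "RF"), n_replicates=2, inclusion_auc=0.0, random_state=0
    )
    return ens.fit(X, y), X


class TestEnsembleSDM:
    def test_convex_combination_invariant(self, fitted):
        ens, X = fitted
        member = ens.member_scores(X)
        combined = ens.decision_function(X)
        assert (combined <= member.max(0) + 1e-12).all()
        assert (combined >= member.min(0) - 1e-12).all()

    def test_weighted_mean_matches_loop_oracle(self, fitted):
        ens, X = fitted
        member = ens.member_scores(X[:50])
        expected = np.zeros(50)
        for (_, _, w), row in zip(ens.weights_, member):
            expected += w * row
        np.testing.assert_allclose(ens.decision_function(X[:50]), expected, atol=1e-12)

    def test_predict_proba_shape_and_classes(self, fitted):
        ens, X = fitted
        proba = ens.predict_proba(X[:10])
        assert proba.shape == (10, 2)
        np.testing.assert_allclose(proba.sum(1), 1.0)
        assert set(ens.predict(X)) <= {0, 1}

    def test_sklearn_params_roundtrip(self):
        ens = EnsembleSDM(n_replicates=4, weight_metric="AUC")
        params = ens.get_params()
        assert params["n_replicates"] == 4
        clone = EnsembleSDM(**params)
        assert clone.weight_metric == "AUC"


@pytest.fixture(scope="module")
def model():
    from ensdm.synth import LandscapeSpec, TruthModel, make_landscape, true_suitability, sample_occurrences

    spec = LandscapeSpec(seed=11, n_rows=60, n_cols=60, autocorrelation_range_cells=8.0)
    stack = make_landscape(spec)
    suit = true_suitability(stack, TruthModel())
    occ = sample_occurrences(suit, 150, seed=3)
    m = fit_sdm(
        occ, stack, ["bio18", "elevation", "human_footprint", "landcover"],
        families=("GLM",), n_replicates=2, inclusion_auc=0.0, exclusion_km=2, seed=4,
    )
    return m, stack


class TestSDMModelSurface:
    def test_surface_in_unit_interval_with_mask(self, model):
        m, stack = model
        surf = m.predict_surface(stack)
        v = surf.values[surf.mask]
        assert v.min() >= 0 and v.max() <= 1

    def test_missing_layer_raises(self, model):
        m, stack = model
        sub = stack.subset(["bio18", "elevation"])
        with pytest.raises(KeyError):
            m.predict_surface(sub)

    def test_constant_members_give_constant_surface(self):
        # all member fits predicting 0.7 -> ensemble exactly 0.7 (convexity)
        class Const:
            def predict_score(self, X):
                return np.full(len(X), 0.7)

        ens = EnsembleSDM(families=("GLM",), n_replicates=1)
        ens.weights_ = [("GLM", 1, 0.6), ("GLM", 2, 0.4)]
        ens._fit_index = {
            ("GLM", 1): type("F", (), {"learner": Const()})(),
            ("GLM", 2): type("F", (), {"learner": Const()})(),
        }
        out = ens.decision_function(np.zeros((5, 2)))
        np.testing.assert_allclose(out, 0.7)

    def test_feature_builder_consistent_between_stacks(self, model):
        m, stack = model
        fb = m.builder
        frame = pd.DataFrame({v: stack[v][stack.mask][:10] for v in m.variables})
        X1 = fb.transform(frame)
        assert X1.shape[1] == len(fb.columns)
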