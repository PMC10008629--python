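import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_score

from arcbio.occurrence_prep import PRESENCE, PSEUDO_ABSENCE
from arcbio.sdm_ensemble import (
    DEFAULT_ALGORITHMS,
    EnsemblePrediction,
    ModelEvaluation,
    NoAdmissibleMembersError,
    _make_estimator,
    committee_ensemble,
    constrain_to_regions,
    evaluate_model,
    evaluate_scores,
    fit_single_models,
    permutation_importance,
    predict_presence_probability,
    select_variables,
    tss_from_counts,
)


def make_train(n=300, separable=True, seed=0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    if separable:
        # wide-margin separation so every family (incl. k-NN) can be perfect
        x1 = np.where(x1 >= 0, x1 + 1.0, x1 - 1.0)
        y = x1 > 0
    else:
        y = rng.uniform(size=n) < 0.5
    return pd.DataFrame(
        {"x1": x1, "x2": x2, "label": np.where(y, PRESENCE, PSEUDO_ABSENCE)}
    )


class TestFitSingleModels:
    def test_separable_training_auc_one(self):
        train = make_train(separable=True)
        models = fit_single_models(train, ["x1", "x2"], seed=0)
        y = (train["label"] == PRESENCE).to_numpy()
        X = train[["x1", "x2"]].to_numpy()
        for name, model in models.items():
            auc = roc_auc_score(y, predict_presence_probability(model, X))
            assert auc == pytest.approx(1.0, abs=1e-6), name

    def test_null_data_cv_auc_half(self):
        # labels independent of covariates: mean CV AUC over 20 reps ~ 0.5
        aucs = []
        for rep in range(20):
            rng = np.random.default_rng(rep)
            X = rng.normal(size=(120, 2))
            y = rng.uniform(size=120) < 0.5
            est = _make_estimator("glm", seed=rep)
            aucs.append(cross_val_score(est, X, y, cv=3, scoring="roc_auc").mean())
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_determinism(self):
        train = make_train()
        X = train[["x1", "x2"]].to_numpy()
        for name in DEFAULT_ALGORITHMS:
            a = fit_single_models(train, ["x1", "x2"], [name], seed=3)[name]
            b = fit_single_models(train, ["x1", "x2"], [name], seed=3)[name]
            assert np.array_equal(
                predict_presence_probability(a, X), predict_presence_probability(b, X)
            ), name

    def test_single_class_error(self):
        train = make_train()
        train["label"] = PRESENCE
        with pytest.raises(ValueError, match="single class"):
            fit_single_models(train, ["x1", "x2"], seed=0)

    def test_needs_two_covariates(self):
        with pytest.raises(ValueError):
            fit_single_models(make_train(), ["x1"], seed=0)


class _StubModel:
    """predict_proba driven by a callable on the feature matrix."""

    classes_ = np.array([False, True])

    def __init__(self, fn):
        self.fn = fn

    def predict_proba(self, X):
        p = np.clip(self.fn(np.asarray(X)), 0.0, 1.0)
        return np.column_stack([1 - p, p])


class TestPermutationImportance:
    def test_ignored_variable_zero(self):
        data = make_train(200)
        model = _StubModel(lambda X: 1 / (1 + np.exp(-X[:, 0])))  # ignores x2
        imp = permutation_importance(model, data, ["x1", "x2"], n_perm=5, seed=0)
        assert imp.set_index("variable").loc["x2", "importance"] == 0.0

    def test_sole_variable_near_one(self):
        data = make_train(400)
        model = _StubModel(lambda X: (X[:, 0] - X[:, 0].min()) / np.ptp(X[:, 0]))
        imp = permutation_importance(model, data, ["x1", "x2"], n_perm=10, seed=0)
        assert imp.set_index("variable").loc["x1", "importance"] > 0.8

    def test_constant_predictions_zero(self):
        data = make_train(100)
        model = _StubModel(lambda X: np.full(X.shape[0], 0.3))
        imp = permutation_importance(model, data, ["x1", "x2"], n_perm=3, seed=0)
        assert (imp["importance"] == 0.0).all()

    def test_collinear_duplicate_drops_importance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        y = x > 0
        solo = pd.DataFrame({"x1": x, "x2": rng.normal(size=400),
                             "label": np.where(y, PRESENCE, PSEUDO_ABSENCE)})
        dup = solo.copy()
        dup["x1b"] = x + rng.normal(0, 1e-3, size=400)
        m_solo = fit_single_models(solo, ["x1", "x2"], ["rf"], seed=1)["rf"]
        m_dup = fit_single_models(dup, ["x1", "x1b", "x2"], ["rf"], seed=1)["rf"]
        i_solo = permutation_importance(m_solo, solo, ["x1", "x2"], n_perm=5, seed=2)
        i_dup = permutation_importance(m_dup, dup, ["x1", "x1b", "x2"], n_perm=5, seed=2)
        solo_imp = i_solo.set_index("variable").loc["x1", "importance"]
        dup_imp = i_dup.set_index("variable").loc["x1", "importance"]
        assert dup_imp < solo_imp


class TestSelectVariables:
    def test_above_mean_rule(self):
        imp = pd.DataFrame({"variable": ["v1", "v2", "v3", "v4"], "importance": [0.6, 0.3, 0.1, 0.0]})
        assert select_variables(imp) == ["v1", "v2"]

    def test_all_equal_keeps_first(self):
        imp = pd.DataFrame({"variable": ["v1", "v2", "v3"], "importance": [0.2, 0.2, 0.2]})
        assert select_variables(imp) == ["v1"]

    def test_single_variable_kept(self):
        imp = pd.DataFrame({"variable": ["v1"], "importance": [0.4]})
        assert select_variables(imp) == ["v1"]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_variables(pd.DataFrame({"variable": [], "importance": []}))


class TestEvaluateModel:
    def test_confusion_arithmetic(self):
        assert tss_from_counts(tp=45, fn=5, tn=40, fp=10) == pytest.approx(0.7)

    def test_perfect_classifier(self):
        y = np.array([True] * 30 + [False] * 30)
        scores = y.astype(float)
        ev = evaluate_scores(scores, y)
        assert ev.TSS == pytest.approx(1.0)
        assert ev.kappa == pytest.approx(1.0)
        assert ev.AUC == pytest.approx(1.0)

    def test_constant_score(self):
        y = np.array([True] * 10 + [False] * 10)
        ev = evaluate_scores(np.full(20, 0.4), y)
        assert ev.TSS == pytest.approx(0.0)
        assert ev.AUC == pytest.approx(0.5)

    def test_threshold_sweep_maximality(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(size=200) < 0.4
        scores = np.clip(y * 0.4 + rng.uniform(size=200) * 0.6, 0, 1)
        ev = evaluate_scores(scores, y)
        grid = np.linspace(0, 1, 101)
        for thr in grid:
            pred = scores >= thr
            tss = tss_from_counts(
                int((pred & y).sum()), int((~pred & y).sum()),
                int((~pred & ~y).sum()), int((pred & ~y).sum()),
            )
            assert tss <= ev.TSS + 1e-12
        assert ev.TSS == pytest.approx(ev.TSS)  # threshold reported is on the grid
        assert ev.binarization_threshold in grid

    def test_single_class_test_error(self):
        train = make_train()
        model = fit_single_models(train, ["x1", "x2"], ["glm"], seed=0)["glm"]
        bad = train.copy()
        bad["label"] = PRESENCE
        with pytest.raises(ValueError):
            evaluate_model(model, bad, ["x1", "x2"])

    def test_tss_identity(self):
        # TSS = sensitivity + specificity - 1 at the chosen threshold
        rng = np.random.default_rng(3)
        y = rng.uniform(size=100) < 0.5
        scores = np.where(y, rng.uniform(0.3, 1, 100), rng.uniform(0, 0.7, 100))
        ev = evaluate_scores(scores, y)
        pred = scores >= ev.binarization_threshold
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        assert ev.TSS == pytest.approx(sens + spec - 1, abs=1e-12)
        assert -1 <= ev.TSS <= 1 and -1 <= ev.kappa <= 1 and 0 <= ev.AUC <= 1


def _ev(name, tss):
    return ModelEvaluation(name, tss, 0.5, 0.9, 0.5)


class TestCommitteeEnsemble:
    def test_mean_and_half_rule(self):
        evals = {a: _ev(a, 0.9) for a in ("m1", "m2", "m3")}
        maps = {
            "m1": np.array([[1.0]]),
            "m2": np.array([[1.0]]),
            "m3": np.array([[0.0]]),
        }
        pred = committee_ensemble(evals, maps, tss_gate=0.7)
        assert pred.committee_score[0, 0] == pytest.approx(2 / 3)
        assert pred.binary_map[0, 0]

    def test_boundary_tie_is_presence(self):
        evals = {a: _ev(a, 0.9) for a in ("m1", "m2")}
        maps = {"m1": np.array([[1.0]]), "m2": np.array([[0.0]])}
        pred = committee_ensemble(evals, maps, tss_gate=0.7)
        assert pred.committee_score[0, 0] == pytest.approx(0.5)
        assert pred.binary_map[0, 0]

    def test_unanimous_absence(self):
        evals = {a: _ev(a, 0.9) for a in ("m1", "m2")}
        maps = {"m1": np.zeros((2, 2)), "m2": np.zeros((2, 2))}
        pred = committee_ensemble(evals, maps, tss_gate=0.7)
        assert not pred.binary_map.any()
        assert np.all(pred.committee_score == 0)

    def test_gate_filters_members(self):
        evals = {"good": _ev("good", 0.8), "bad": _ev("bad", 0.2)}
        maps = {"good": np.ones((1, 1)), "bad": np.zeros((1, 1))}
        pred = committee_ensemble(evals, maps, tss_gate=0.7)
        assert pred.members == ["good"]
        assert pred.committee_score[0, 0] == 1.0

    def test_no_members_error_reports_tss(self):
        evals = {"m1": _ev("m1", 0.1), "m2": _ev("m2", 0.3)}
        maps = {"m1": np.ones((1, 1)), "m2": np.ones((1, 1))}
        with pytest.raises(NoAdmissibleMembersError, match="m1"):
            committee_ensemble(evals, maps, tss_gate=0.7)

    def test_score_lattice(self):
        rng = np.random.default_rng(0)
        m = 4
        evals = {f"m{i}": _ev(f"m{i}", 0.9) for i in range(m)}
        maps = {f"m{i}": (rng.uniform(size=(5, 5)) < 0.5).astype(float) for i in range(m)}
        pred = committee_ensemble(evals, maps, tss_gate=0.7)
        lattice = np.arange(m + 1) / m
        assert np.all(np.isin(np.round(pred.committee_score, 12), np.round(lattice, 12)))


class TestConstrainToRegions:
    def _pred(self, grid):
        score = np.where(grid.ocean_mask, 1.0, np.nan)
        return EnsemblePrediction("sp", 2000, score, grid.ocean_mask.copy(), ["m1"])

    def test_all_regions_identity(self, small_grid):
        pred = self._pred(small_grid)
        out = constrain_to_regions(pred, small_grid.region_ids.tolist(), small_grid)
        assert np.array_equal(out.binary_map, pred.binary_map)

    def test_masking(self, small_grid):
        pred = self._pred(small_grid)
        out = constrain_to_regions(pred, [2], small_grid)
        outside = (small_grid.region_id != 2) & small_grid.ocean_mask
        assert not out.binary_map[outside].any()
        assert np.all(out.committee_score[outside] == 0.0)
        inside = small_grid.region_id == 2
        assert out.binary_map[inside].all()

    def test_idempotent(self, small_grid):
        pred = self._pred(small_grid)
        once = constrain_to_regions(pred, [1, 3], small_grid)
        twice = constrain_to_regions(once, [1, 3], small_grid)
        assert np.array_equal(once.binary_map, twice.binary_map)
        assert np.array_equal(once.committee_score, twice.committee_score, equal_nan=True)

    def test_empty_allowed_error(self, small_grid):
        with pytest.raises(ValueError):
            constrain_to_regions(self._pred(small_grid), [], small_grid)
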