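"""Multi-algorithm SDM fitting, importance-based variable selection, TSS/kappa/AUC
evaluation, and TSS-gated committee-mean ensembles constrained to allowed regions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from arcbio._stats import subseed_rng
from arcbio.occurrence_prep import PRESENCE
from arcbio.synthetic_data.environment import EnvStack
from arcbio.synthetic_data.grid import Grid

log = logging.getLogger(__name__)

DEFAULT_ALGORITHMS = ("glm", "gam", "rf", "gbm", "knn")
DEFAULT_TSS_GATE = 0.7
THRESHOLD_GRID = np.linspace(0.0, 1.0, 101)


class NoAdmissibleMembersError(RuntimeError):
    """No single-algorithm model passed the TSS gate."""


@dataclass(frozen=True)
class ModelEvaluation:
    algorithm: str
    TSS: float
    kappa: float
    AUC: float
    binarization_threshold: float


@dataclass
class EnsemblePrediction:
    species_id: str
    year: int
    committee_score: np.ndarray  # in {0, 1/m, ..., 1}; NaN outside domain
    binary_map: np.ndarray  # boolean
    members: list[str]


def _make_estimator(name: str, seed: int):
    rs = int(subseed_rng(seed, "estimator", name).integers(0, 2**31 - 1))
    if name == "glm":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000, random_state=rs))
    if name == "gam":
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(n_knots=6, degree=3),
            LogisticRegression(max_iter=1000, C=2.0, random_state=rs),
        )
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=150, min_samples_leaf=5, n_jobs=1, random_state=rs
        )
    if name == "gbm":
        return HistGradientBoostingClassifier(max_iter=150, random_state=rs)
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=25))
    raise ValueError(f"unknown algorithm {name!r}")


def _xy(train: pd.DataFrame, variables):
    X = train[list(variables)].to_numpy(dtype=float)
    y = (train["label"] == PRESENCE).to_numpy()
    return X, y


def fit_single_models(train: pd.DataFrame, variables, algorithms=DEFAULT_ALGORITHMS, seed: int = 0):
    """Fit one probability-of-presence classifier per algorithm family."""
    X, y = _xy(train, variables)
    if len(np.unique(y)) < 2:
        raise ValueError("training data has a single class")
    if len(variables) < 2:
        raise ValueError("need at least 2 covariates")
    models = {}
    for name in algorithms:
        est = _make_estimator(name, seed)
        est.fit(X, y)
        models[name] = est
    return models


def predict_presence_probability(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    return proba[:, classes.index(True)]


def permutation_importance(
    model, data: pd.DataFrame, variables, n_perm: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Importance of each variable as 1 - cor(pred, pred with that variable permuted),
    averaged over ``n_perm`` permutations and clipped to [0, 1].

    Constant predictions (undefined correlation) score 0.
    """
    variables = list(variables)
    X, _ = _xy(data, variables)
    base = predict_presence_probability(model, X)
    base_sd = base.std()
    rows = []
    rng = subseed_rng(seed, "permutation_importance")
    for j, var in enumerate(variables):
        scores = []
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm = predict_presence_probability(model, Xp)
            if base_sd == 0 or perm.std() == 0:
                scores.append(0.0)
            else:
                scores.append(1.0 - float(np.corrcoef(base, perm)[0, 1]))
        rows.append({"variable": var, "importance": float(np.clip(np.mean(scores), 0.0, 1.0))})
    return pd.DataFrame(rows)


def averaged_importance(
    models: dict, data: pd.DataFrame, variables, n_perm: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Per (algorithm, variable) importance plus the cross-algorithm mean."""
    parts = []
    for name, model in models.items():
        imp = permutation_importance(model, data, variables, n_perm=n_perm, seed=seed)
        imp.insert(0, "algorithm", name)
        parts.append(imp)
    table = pd.concat(parts, ignore_index=True)
    return table


def select_variables(importance: pd.DataFrame) -> list[str]:
    """Variables with mean importance above the grand mean; argmax if all tie.

    Accepts either the per-algorithm table from :func:`averaged_importance` or a
    two-column (variable, importance) frame. Declared variable order is kept.
    """
    if importance.empty:
        raise ValueError("empty importance table")
    order = importance["variable"].drop_duplicates().tolist()
    mean_imp = importance.groupby("variable", sort=False)["importance"].mean()
    mean_imp = mean_imp.reindex(order)
    grand = mean_imp.mean()
    selected = [v for v in order if mean_imp[v] > grand]
    if not selected:
        selected = [mean_imp.idxmax()]
    return selected


def tss_from_counts(tp: int, fn: int, tn: int, fp: int) -> float:
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return sens + spec - 1.0


def evaluate_model(model, test: pd.DataFrame, variables, thresholds=THRESHOLD_GRID) -> ModelEvaluation:
    """TSS-maximizing threshold sweep (smallest threshold on ties); kappa at that
    threshold; threshold-free AUC."""
    X, y = _xy(test, variables)
    if len(np.unique(y)) < 2:
        raise ValueError("test data has a single class")
    scores = predict_presence_probability(model, X)
    return evaluate_scores(scores, y, model_name=type(model).__name__, thresholds=thresholds)


def evaluate_scores(scores: np.ndarray, y: np.ndarray, model_name: str = "", thresholds=THRESHOLD_GRID) -> ModelEvaluation:
    y = np.asarray(y, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pos = y.sum()
    neg = y.size - pos
    # vectorized sweep: tp/fp counts at every threshold
    pred = scores[None, :] >= np.asarray(thresholds)[:, None]
    tp = (pred & y[None, :]).sum(axis=1)
    fp = (pred & ~y[None, :]).sum(axis=1)
    sens = tp / pos
    spec = (neg - fp) / neg
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (smallest) threshold on ties
    thr = float(thresholds[best])
    kappa = float(cohen_kappa_score(y, scores >= thr))
    if np.ptp(scores) == 0:
        auc = 0.5
    else:
        auc = float(roc_auc_score(y, scores))
    return ModelEvaluation(model_name, float(tss[best]), kappa, auc, thr)


def predict_raster(model, env: EnvStack, year: int, variables) -> np.ndarray:
    """Probability-of-presence raster for one year; NaN outside the ocean domain."""
    grid = env.grid
    layers = env.layers(year, variables)
    ocean = grid.ocean_mask
    X = np.column_stack([layers[v][ocean] for v in variables])
    out = np.full(grid.shape, np.nan)
    ok = np.all(np.isfinite(X), axis=1)
    if ok.any():
        probs = np.full(X.shape[0], np.nan)
        probs[ok] = predict_presence_probability(model, X[ok])
        out[ocean] = probs
    return out


def committee_ensemble(
    member_evals: dict[str, ModelEvaluation],
    member_binary_maps: dict[str, np.ndarray],
    tss_gate: float = DEFAULT_TSS_GATE,
    species_id: str = "",
    year: int = 0,
) -> EnsemblePrediction:
    """Committee mean of the binary maps of members whose TSS passes the gate;
    ensemble presence where the mean is >= 0.5."""
    members = [name for name, ev in member_evals.items() if ev.TSS >= tss_gate]
    if not members:
        report = {name: round(ev.TSS, 4) for name, ev in member_evals.items()}
        raise NoAdmissibleMembersError(
            f"{species_id} year {year}: no member passed TSS gate {tss_gate}; per-member TSS: {report}"
        )
    stack = np.stack([np.asarray(member_binary_maps[name], dtype=float) for name in members])
    score = stack.mean(axis=0)
    binary = np.where(np.isnan(score), False, score >= 0.5)
    return EnsemblePrediction(species_id, int(year), score, binary.astype(bool), members)


def constrain_to_regions(pred: EnsemblePrediction, allowed_regions, grid: Grid) -> EnsemblePrediction:
    """Zero score and presence outside the species' allowed marine areas."""
    allowed = set(int(r) for r in allowed_regions)
    if not allowed:
        raise ValueError("allowed_regions must be non-empty")
    if not allowed <= set(grid.region_ids.tolist()):
        raise ValueError("allowed_regions not a subset of grid regions")
    mask = np.isin(grid.region_id, list(allowed))
    score = pred.committee_score.copy()
    score[~mask & np.isfinite(score)] = 0.0
    binary = pred.binary_map & mask
    return replace(pred, committee_score=score, binary_map=binary)


@dataclass
class SpeciesSDM:
    """Fitted committee for one species: final models, averaged evaluations, members."""

    species_id: str
    variables: list[str]
    models: dict
    evaluations: dict[str, ModelEvaluation]
    tss_gate: float
    members: list[str]


def fit_species_sdm(
    species_id: str,
    train: pd.DataFrame,
    variables,
    algorithms=DEFAULT_ALGORITHMS,
    tss_gate: float = DEFAULT_TSS_GATE,
    n_splits: int = 3,
    test_size: float = 0.2,
    seed: int = 0,
) -> SpeciesSDM:
    """Stratified 80/20 evaluation repeated ``n_splits`` times (averaged), then a
    final refit on all rows for prediction."""
    variables = list(variables)
    X, y = _xy(train, variables)
    if len(np.unique(y)) < 2:
        raise ValueError("training data has a single class")
    rs = int(subseed_rng(seed, "split", species_id).integers(0, 2**31 - 1))
    splitter = StratifiedShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=rs)
    sums: dict[str, np.ndarray] = {a: np.zeros(4) for a in algorithms}
    for tr_idx, te_idx in splitter.split(X, y):
        models = fit_single_models(train.iloc[tr_idx], variables, algorithms, seed=seed)
        for name, model in models.items():
            ev = evaluate_model(model, train.iloc[te_idx], variables)
            sums[name] += (ev.TSS, ev.kappa, ev.AUC, ev.binarization_threshold)
    evaluations = {
        name: ModelEvaluation(name, *(sums[name] / n_splits)) for name in algorithms
    }
    final_models = fit_single_models(train, variables, algorithms, seed=seed)
    members = [a for a in algorithms if evaluations[a].TSS >= tss_gate]
    return SpeciesSDM(species_id, variables, final_models, evaluations, tss_gate, members)


def predict_species_year(
    sdm: SpeciesSDM, env: EnvStack, year: int, allowed_regions=None
) -> EnsemblePrediction:
    """Committee ensemble map for one species-year from the fitted SDM."""
    binary_maps = {}
    for name in sdm.models:
        prob = predict_raster(sdm.models[name], env, year, sdm.variables)
        thr = sdm.evaluations[name].binarization_threshold
        binary_maps[name] = np.where(np.isnan(prob), np.nan, prob >= thr)
    pred = committee_ensemble(sdm.evaluations, binary_maps, sdm.tss_gate, sdm.species_id, year)
    if allowed_regions is not None:
        pred = constrain_to_regions(pred, allowed_regions, env.grid)
    return pred
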