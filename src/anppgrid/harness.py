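"""Learner-agnostic model fitting, scoring and selection.

Covers the comparison of six learner families under the three CV strategies
(with repeated-measures ANOVA + Tukey HSD on the repeated scores), the
ntree/mtry grid search for the random forest, training of a model population
with per-model cross-validated scores, and unweighted ensemble averaging.

Scores are computed on *pooled* out-of-fold predictions: every row is
predicted exactly once by a model that never saw it, and R2/RMSE/MAE are
evaluated on that single vector, which is stable even for small folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import clone
from sklearn.ensemble import BaggingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import cv as cvs

logger = logging.getLogger(__name__)

FAMILIES = ("linear", "svr", "random_forest", "ann", "bagged_trees", "xgboost")


@dataclass(frozen=True)
class LearnerSpec:
    """One learner family plus its hyperparameters and seed."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}; choose from {FAMILIES}")
        if self.family == "random_forest":
            ntree = self.params.get("ntree", 500)
            mtry = self.params.get("mtry")
            if ntree < 1:
                raise ValueError("ntree must be >= 1")
            if mtry is not None and mtry < 1:
                raise ValueError("mtry must be >= 1")

    def with_seed(self, seed: int) -> "LearnerSpec":
        return replace(self, seed=seed)


def make_estimator(spec: LearnerSpec, n_predictors: int):
    """Instantiate the sklearn/xgboost estimator for a learner spec."""
    rs = spec.seed % (2**31)
    p = spec.params
    if spec.family == "linear":
        return LinearRegression()
    if spec.family == "svr":
        return make_pipeline(
            StandardScaler(),
            SVR(C=p.get("C", 100.0), epsilon=p.get("epsilon", 5.0), gamma="scale"),
        )
    if spec.family == "random_forest":
        mtry = p.get("mtry")
        if mtry is not None and mtry > n_predictors:
            raise ValueError(f"mtry={mtry} exceeds the {n_predictors} available predictors")
        return RandomForestRegressor(
            n_estimators=p.get("ntree", 500),
            max_features=mtry if mtry is not None else 1.0,
            random_state=rs,
            n_jobs=1,
        )
    if spec.family == "ann":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=p.get("hidden", (32,)),
                max_iter=p.get("max_iter", 400),
                random_state=rs,
            ),
        )
    if spec.family == "bagged_trees":
        return BaggingRegressor(
            estimator=DecisionTreeRegressor(random_state=rs),
            n_estimators=p.get("n_estimators", 100),
            random_state=rs,
            n_jobs=1,
        )
    if spec.family == "xgboost":
        return xgb.XGBRegressor(
            n_estimators=p.get("n_estimators", 200),
            max_depth=p.get("max_depth", 4),
            learning_rate=p.get("learning_rate", 0.1),
            random_state=rs,
            n_jobs=1,
            verbosity=0,
        )
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class ModelScore:
    """Pooled out-of-fold performance of one fitted configuration."""

    r2: float
    rmse: float
    mae: float
    strategy: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.mae < 0:
            raise ValueError("error metrics must be non-negative")


def score_predictions(obs: np.ndarray, pred: np.ndarray, strategy: str = "", seed: int = 0) -> ModelScore:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    return ModelScore(
        r2=float(r2_score(obs, pred)),
        rmse=float(np.sqrt(mean_squared_error(obs, pred))),
        mae=float(mean_absolute_error(obs, pred)),
        strategy=strategy,
        seed=seed,
    )


def cross_validate(
    learner: LearnerSpec,
    X: np.ndarray,
    y: np.ndarray,
    folds: cvs.FoldAssignment,
    return_predictions: bool = False,
):
    """Pooled out-of-fold score of one learner under one partition."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if folds.n != len(y):
        raise ValueError("fold assignment does not partition the table's rows")
    oof = np.full(len(y), np.nan)
    base = make_estimator(learner, X.shape[1])
    for f in range(1, folds.k + 1):
        test = folds.indices(f)
        if test.size < 2:
            raise ValueError(f"fold {f} has fewer than 2 rows; variance-based metrics undefined")
        train = np.flatnonzero(folds.folds != f)
        est = clone(base)
        est.fit(X[train], y[train])
        oof[test] = est.predict(X[test])
    score = score_predictions(y, oof, strategy=folds.strategy, seed=learner.seed)
    if return_predictions:
        return score, oof
    return score


def make_folds(
    strategy: str,
    n_rows: int,
    seed: int,
    k: int = cvs.DEFAULT_K,
    coords: tuple[np.ndarray, np.ndarray] | None = None,
    strat_features: np.ndarray | None = None,
    block_size: float | None = None,
    n_classes: int = cvs.DEFAULT_N_CLASSES,
) -> cvs.FoldAssignment:
    """Build a fold assignment for any of the three strategies."""
    if strategy == "random":
        return cvs.random_kfold(n_rows, k, seed)
    if strategy == "spatial_block":
        if coords is None:
            raise ValueError("spatial_block needs lon/lat coordinates")
        lon, lat = coords
        bs = block_size if block_size is not None else cvs.suggest_block_size(lon, lat, k)
        return cvs.spatial_block_cv(lon, lat, bs, k, seed)
    if strategy == "env_stratified":
        if strat_features is None:
            raise ValueError("env_stratified needs stratification features")
        return cvs.env_stratified_cv(strat_features, n_classes, k, seed)
    raise ValueError(f"unknown CV strategy {strategy!r}")


def compare_models(
    learners: dict[str, LearnerSpec],
    strategies: list[str],
    X: np.ndarray,
    y: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray] | None = None,
    strat_features: np.ndarray | None = None,
    k: int = cvs.DEFAULT_K,
    repeats: int = 10,
    base_seed: int = 0,
    block_size: float | None = None,
) -> pd.DataFrame:
    """Full factorial learner x strategy x repeat score table.

    All learners share the same folds within a (strategy, repeat) pair, so the
    repetition seed is a genuine repeated-measures unit.
    """
    if len(learners) < 2 and len(strategies) < 2:
        raise ValueError("need at least two learners or two strategies to compare")
    rows = []
    for rep in range(repeats):
        seed = base_seed + rep
        for strategy in strategies:
            folds = make_folds(
                strategy, len(y), seed, k=k, coords=coords,
                strat_features=strat_features, block_size=block_size,
            )
            for name, spec in learners.items():
                s = cross_validate(spec.with_seed(seed), X, y, folds)
                rows.append(
                    {"learner": name, "strategy": strategy, "repeat": rep,
                     "r2": s.r2, "rmse": s.rmse, "mae": s.mae}
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StatsReport:
    """Repeated-measures ANOVA plus Tukey HSD pairwise comparisons."""

    factor: str
    metric: str
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


def compare_stats(comparison: pd.DataFrame, factor: str = "learner", metric: str = "r2") -> StatsReport:
    """Repeated-measures ANOVA (repetition as subject) + Tukey HSD.

    Requires a balanced design: every factor level scored in every repeat.
    """
    counts = comparison.groupby([factor, "repeat"]).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: every group needs the same repeats")
    data = comparison.groupby([factor, "repeat"], as_index=False)[metric].mean()
    res = AnovaRM(data, depvar=metric, subject="repeat", within=[factor]).fit()
    row = res.anova_table.iloc[0]
    tk = pairwise_tukeyhsd(comparison[metric].values, comparison[factor].values)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[c.strip() for c in tk.summary().data[0]]
    )
    return StatsReport(
        factor=factor,
        metric=metric,
        anova_f=float(row["F Value"]),
        anova_p=float(row["Pr > F"]),
        tukey=tukey,
    )


DEFAULT_GRID = {"ntree": (200, 400, 600, 800, 1000), "mtry": (2, 4, 6, 8, 10)}


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    strat_features: np.ndarray,
    grid: dict | None = None,
    repeats: int = 10,
    k: int = cvs.DEFAULT_K,
    base_seed: int = 0,
    n_classes: int = cvs.DEFAULT_N_CLASSES,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Random-forest ntree/mtry grid search under environmentally-stratified CV.

    Returns the full tuning table (one row per combination x repetition, with
    a per-combination mean) and the selected (ntree, mtry): highest mean R2,
    ties broken by smaller ntree then smaller mtry.  Combinations whose mtry
    exceeds the predictor count are skipped with a warning.
    """
    grid = dict(DEFAULT_GRID) if grid is None else grid
    ntrees = tuple(grid["ntree"])
    mtrys = tuple(grid["mtry"])
    if not ntrees or not mtrys:
        raise ValueError("empty hyperparameter grid")
    n_pred = X.shape[1]
    rows = []
    for rep in range(repeats):
        seed = base_seed + rep
        folds = cvs.env_stratified_cv(strat_features, n_classes, k, seed)
        for ntree in ntrees:
            for mtry in mtrys:
                if mtry > n_pred:
                    logger.warning("skipping mtry=%d > %d predictors", mtry, n_pred)
                    continue
                spec = LearnerSpec("random_forest", {"ntree": ntree, "mtry": mtry}, seed=seed)
                s = cross_validate(spec, X, y, folds)
                rows.append({"ntree": ntree, "mtry": mtry, "repeat": rep, "r2": s.r2})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no feasible grid combination")
    means = (
        table.groupby(["ntree", "mtry"], as_index=False)["r2"]
        .mean()
        .rename(columns={"r2": "mean_r2"})
    )
    table = table.merge(means, on=["ntree", "mtry"])
    return table, select_best_combination(means)


def select_best_combination(means: pd.DataFrame) -> tuple[int, int]:
    """Highest mean R2; ties go to the smaller ntree, then the smaller mtry."""
    best = means.sort_values(
        ["mean_r2", "ntree", "mtry"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    return (int(best["ntree"]), int(best["mtry"]))


@dataclass
class FittedModel:
    """A fitted estimator plus the schema it expects and its CV score."""

    estimator: object
    feature_names: tuple[str, ...]
    spec: LearnerSpec
    score: ModelScore | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"schema mismatch: model expects {len(self.feature_names)} predictors "
                f"({self.feature_names}), got {X.shape[1]}"
            )
        return np.asarray(self.estimator.predict(X), dtype=float)


@dataclass
class ModelPopulation:
    """Repeatedly trained models with per-model CV scores."""

    models: list[FittedModel]
    best_index: int

    @property
    def best(self) -> FittedModel:
        return self.models[self.best_index]

    def r2_values(self) -> np.ndarray:
        return np.array([m.score.r2 for m in self.models])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": np.arange(len(self.models)),
                "r2": [m.score.r2 for m in self.models],
                "rmse": [m.score.rmse for m in self.models],
                "mae": [m.score.mae for m in self.models],
            }
        )


def train_population(
    X: np.ndarray,
    y: np.ndarray,
    feature_names,
    learner: LearnerSpec,
    strat_features: np.ndarray,
    n_models: int = 500,
    k: int = cvs.DEFAULT_K,
    base_seed: int = 0,
    n_classes: int = cvs.DEFAULT_N_CLASSES,
) -> ModelPopulation:
    """Train ``n_models`` copies (distinct seeds), each scored by
    environmentally-stratified CV; pick the best by R2 (tie: lowest RMSE)."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    models: list[FittedModel] = []
    for i in range(n_models):
        seed = base_seed + i
        spec = learner.with_seed(seed)
        folds = cvs.env_stratified_cv(strat_features, n_classes, k, seed)
        score = cross_validate(spec, X, y, folds)
        est = make_estimator(spec, X.shape[1])
        est.fit(X, y)
        models.append(FittedModel(est, tuple(feature_names), spec, score))
    order = sorted(
        range(n_models), key=lambda i: (-models[i].score.r2, models[i].score.rmse, i)
    )
    return ModelPopulation(models=models, best_index=order[0])


def ensemble_predict(models: list[FittedModel], X) -> np.ndarray:
    """Unweighted mean of member predictions (schemas must agree)."""
    if not models:
        raise ValueError("empty ensemble")
    schema = models[0].feature_names
    for m in models[1:]:
        if m.feature_names != schema:
            raise ValueError(f"schema mismatch: {m.feature_names} vs {schema}")
    preds = np.stack([m.predict(X) for m in models])
    return preds.mean(axis=0)
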