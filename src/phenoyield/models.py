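"""Ensemble yield regressors and the cross-validation protocol.

Two tree-ensemble learners predict plot yield (tons/ha) from selected
latent phenotypes: a random forest (default max depth 10, 400 trees) and
gradient boosting via XGBoost (default learning rate 0.06, max depth 3,
minimum child weight 5).  Validation follows the trial protocol:

* Monte-Carlo cross-validation (MCCV): many random 70/30 train/test
  partitions (or a per-iteration train fraction drawn from
  {0.5, 0.6, 0.7, 0.8, 0.9} in ``variable`` mode), scored with adjusted
  R2 = 1 - (1 - R2)(n - 1)/(n - p - 1) using each evaluation set's own n;
* 10-fold cross-validation as a second protocol;
* exhaustive grid search over a small hyperparameter grid, scored by
  k-fold mean test adjusted R2, ties broken toward the simpler model.

The MCCV iteration with the best test adjusted R2 (ties broken by train
adjusted R2, then by iteration id) supplies the fitted predictor used for
plot-level yield estimates downstream.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

__all__ = [
    "ModelSpec",
    "ModelScore",
    "CVResult",
    "adjusted_r2",
    "make_estimator",
    "grid_search",
    "mccv",
    "kfold",
    "predict_all",
]

logger = logging.getLogger(__name__)

ModelKind = Literal["random_forest", "gradient_boosting"]

_DEFAULTS: Mapping[ModelKind, dict] = {
    "random_forest": {"max_depth": 10, "n_estimators": 400},
    "gradient_boosting": {
        "learning_rate": 0.06,
        "max_depth": 3,
        "min_child_weight": 5,
        "n_estimators": 400,
    },
}

_GRIDS: Mapping[ModelKind, dict] = {
    "random_forest": {
        "max_depth": [5, 10, 15, None],
        "n_estimators": [100, 200, 400, 800],
    },
    "gradient_boosting": {
        "learning_rate": [0.03, 0.06, 0.1],
        "max_depth": [3, 5, 7],
        "min_child_weight": [1, 3, 5],
    },
}

VARIABLE_TRAIN_FRACTIONS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class ModelSpec:
    """One ensemble learner plus its hyperparameters and search grid."""

    kind: ModelKind
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _DEFAULTS:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def hyperparameters(self) -> dict:
        return {**_DEFAULTS[self.kind], **dict(self.params)}

    @property
    def grid(self) -> dict:
        return dict(_GRIDS[self.kind])

    def with_params(self, **params) -> "ModelSpec":
        return replace(self, params={**dict(self.params), **params})


def make_estimator(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn/XGBoost estimator for a spec."""
    hp = spec.hyperparameters
    if spec.kind == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    return XGBRegressor(
        random_state=seed,
        n_jobs=1,
        importance_type="gain",
        verbosity=0,
        **hp,
    )


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R2 with the evaluation set's own n and p predictors."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass(frozen=True)
class ModelScore:
    """Scores for one cross-validation iteration."""

    iteration: int
    n_train: int
    n_test: int
    p: int
    train_r2: float
    test_r2: float
    train_adj_r2: float
    test_adj_r2: float
    train_fraction: float


@dataclass
class CVResult:
    """Outcome of an MCCV run, including the best iteration's predictor."""

    scores: list[ModelScore]
    best_iteration: int
    model: object
    feature_columns: list[str]
    predictions: pd.DataFrame    # plot_id, measured, estimated, set_label

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.scores])

    @property
    def mean_train_adj_r2(self) -> float:
        return float(np.nanmean([s.train_adj_r2 for s in self.scores]))

    @property
    def mean_test_adj_r2(self) -> float:
        return float(np.nanmean([s.test_adj_r2 for s in self.scores]))


def _score_key(s: ModelScore) -> tuple:
    # maximise test adj R2, then train adj R2, then earliest iteration
    return (s.test_adj_r2, s.train_adj_r2, -s.iteration)


def mccv(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: Sequence[float],
    iterations: int = 1000,
    train_fraction: float | Literal["variable"] = 0.7,
    seed: int = 0,
) -> CVResult:
    """Monte-Carlo cross-validation with random train/test partitions.

    Each iteration draws a fresh random partition (fraction fixed, or drawn
    from {0.5..0.9} in ``variable`` mode), fits the learner on the training
    part and scores both parts with adjusted R2.  Iterations whose test set
    is too small for the adjusted-R2 denominator (n_test <= p + 1) are
    skipped with a log message.  The best iteration's fitted model and its
    all-plot predictions (train and test alike, with set labels) are kept.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    y = np.asarray(y, float)
    n, p = X.shape
    rng = np.random.default_rng(seed)

    scores: list[ModelScore] = []
    best: ModelScore | None = None
    best_artifacts = None
    for it in range(iterations):
        frac = (
            float(rng.choice(VARIABLE_TRAIN_FRACTIONS))
            if train_fraction == "variable"
            else float(train_fraction)
        )
        perm = rng.permutation(n)
        est_seed = int(rng.integers(0, 2**31 - 1))
        n_train = int(round(frac * n))
        tr, te = perm[:n_train], perm[n_train:]
        if len(te) <= p + 1 or len(tr) <= p + 1:
            logger.info("iteration %d skipped: partition too small for p=%d", it, p)
            continue
        model = make_estimator(spec, seed=est_seed)
        model.fit(X.iloc[tr], y[tr])
        r2_tr = r2_score(y[tr], model.predict(X.iloc[tr]))
        r2_te = r2_score(y[te], model.predict(X.iloc[te]))
        score = ModelScore(
            iteration=it,
            n_train=len(tr),
            n_test=len(te),
            p=p,
            train_r2=float(r2_tr),
            test_r2=float(r2_te),
            train_adj_r2=adjusted_r2(r2_tr, len(tr), p),
            test_adj_r2=adjusted_r2(r2_te, len(te), p),
            train_fraction=frac,
        )
        scores.append(score)
        if best is None or _score_key(score) > _score_key(best):
            best = score
            labels = np.empty(n, object)
            labels[tr] = "train"
            labels[te] = "test"
            best_artifacts = (model, labels)

    if best is None:
        raise ValueError("no MCCV iteration produced a valid partition")
    model, labels = best_artifacts
    predictions = pd.DataFrame(
        {
            "plot_id": X.index,
            "measured": y,
            "estimated": model.predict(X),
            "set_label": labels,
        }
    )
    return CVResult(
        scores=scores,
        best_iteration=best.iteration,
        model=model,
        feature_columns=list(X.columns),
        predictions=predictions,
    )


def kfold(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: Sequence[float],
    k: int = 10,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """K-fold cross-validation; returns (mean test adjusted R2, per-fold)."""
    y = np.asarray(y, float)
    n, p = X.shape
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    if n // k <= p + 1:
        raise ValueError(f"fold size {n // k} too small for p={p} predictors")
    fold_scores = []
    for i, (tr, te) in enumerate(KFold(n_splits=k, shuffle=True, random_state=seed).split(X)):
        model = make_estimator(spec, seed=seed + i)
        model.fit(X.iloc[tr], y[tr])
        r2_te = r2_score(y[te], model.predict(X.iloc[te]))
        fold_scores.append(adjusted_r2(r2_te, len(te), p))
    return float(np.nanmean(fold_scores)), fold_scores


def _complexity_key(kind: ModelKind, params: dict) -> tuple:
    # prefer fewer trees, then shallower trees (None = unlimited = deepest)
    depth = params.get("max_depth")
    depth = float("inf") if depth is None else depth
    return (params.get("n_estimators", 0), depth, params.get("learning_rate", 0))


def grid_search(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: Sequence[float],
    folds: int = 5,
    seed: int = 0,
    grid: Mapping[str, Sequence] | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search scored by k-fold mean test adjusted R2.

    Returns the best hyperparameter dict and the full results table.  Ties
    on the score break toward the simpler model (fewer trees, then
    shallower depth); the result is deterministic given the seed.
    """
    grid = dict(grid) if grid is not None else spec.grid
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be nonempty")
    keys = list(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        score, _ = kfold(spec.with_params(**params), X, y, k=folds, seed=seed)
        rows.append({**params, "mean_test_adj_r2": score})
    results = pd.DataFrame(rows)
    ranked = sorted(
        rows,
        key=lambda r: (
            -r["mean_test_adj_r2"],
            _complexity_key(spec.kind, r),
        ),
    )
    best = {k: ranked[0][k] for k in keys}
    return best, results


def predict_all(result: CVResult, X: pd.DataFrame) -> pd.Series:
    """Predict yield for every plot with the best-iteration model."""
    if list(X.columns) != result.feature_columns:
        raise ValueError("feature columns do not match the trained model")
    return pd.Series(result.model.predict(X), index=X.index, name="estimated_yield")
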