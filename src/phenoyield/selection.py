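"""Multicollinearity pruning and recursive feature elimination.

The candidate latent-phenotype pool is heavily collinear (many features
are deterministic functions of the same three curve parameters), so the
pipeline first removes features by variance inflation factor,
VIF_j = 1/(1 - R2_j) with R2_j the coefficient of determination of
feature j regressed on all the others: features are dropped one at a
time, highest VIF first, until every survivor has VIF <= 5.  Iterative
removal (rather than a single pass) avoids discarding an entire mutually
collinear group when dropping one member already resolves it.

Recursive feature elimination (RFE) then ranks the survivors with the
learner's own importances, eliminating one feature per step down to a
single feature; prefixes of that ranking give the selected subset at
every feature limit 1..30 in one pass.  Mean train/test adjusted R2 over
Monte-Carlo splits is recorded per limit, and the chosen limit is the
smallest one whose mean test adjusted R2 is within a small tolerance of
the peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import clone
from sklearn.feature_selection import RFE
from sklearn.metrics import r2_score
from sklearn.model_selection import ShuffleSplit
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .models import ModelSpec, adjusted_r2, make_estimator

__all__ = ["VIFReport", "RFESweep", "compute_vif", "vif_filter", "rfe_sweep"]


@dataclass
class VIFReport:
    """Outcome of iterative VIF pruning."""

    table: pd.DataFrame            # feature, vif (final or at removal), r2_aux, removed
    removed: list[str]             # in removal order
    threshold: float

    @property
    def survivors(self) -> list[str]:
        return self.table.loc[~self.table["removed"], "feature"].tolist()


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """VIF per column: 1/(1 - R2) of each feature on all others (+intercept)."""
    exog = sm.add_constant(np.asarray(X, float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vifs = [variance_inflation_factor(exog, i + 1) for i in range(X.shape[1])]
    return pd.Series(vifs, index=X.columns, name="vif")


def vif_filter(X: pd.DataFrame, threshold: float = 5.0) -> tuple[pd.DataFrame, VIFReport]:
    """Iteratively drop the highest-VIF feature until all VIF <= threshold.

    Constant columns (undefined VIF) are removed first with a warning.
    Every removal is recorded in order; ties on VIF break toward the
    earlier column, so the result is deterministic.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two features for VIF analysis")
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("feature table contains non-finite values")
    work = X.copy()
    rows: dict[str, dict] = {}
    removed: list[str] = []

    for col in list(work.columns):
        if work[col].nunique() <= 1:
            warnings.warn(f"constant feature {col!r} removed (VIF undefined)", stacklevel=2)
            rows[col] = {"feature": col, "vif": np.inf, "r2_aux": 1.0, "removed": True}
            removed.append(col)
            work = work.drop(columns=col)

    while work.shape[1] >= 2:
        vifs = compute_vif(work)
        vmax = vifs.replace(np.inf, np.finfo(float).max).max()
        if vifs.max() <= threshold:
            break
        worst = vifs.index[np.argmax(vifs.to_numpy())]
        rows[worst] = {
            "feature": worst,
            "vif": float(vifs[worst]),
            "r2_aux": 1.0 - 1.0 / vifs[worst] if np.isfinite(vifs[worst]) else 1.0,
            "removed": True,
        }
        removed.append(worst)
        work = work.drop(columns=worst)

    final = compute_vif(work) if work.shape[1] >= 2 else pd.Series(1.0, index=work.columns)
    for col in work.columns:
        v = float(final[col])
        rows[col] = {
            "feature": col,
            "vif": v,
            "r2_aux": 1.0 - 1.0 / v if np.isfinite(v) and v > 0 else np.nan,
            "removed": False,
        }
    table = pd.DataFrame([rows[c] for c in X.columns])
    return work, VIFReport(table=table, removed=removed, threshold=threshold)


@dataclass
class RFESweep:
    """Per-limit RFE results over Monte-Carlo splits."""

    limits: list[int]
    mean_train_adj_r2: list[float]
    mean_test_adj_r2: list[float]
    selected: dict[int, list[str]]     # limit -> feature names (full-data ranking)
    chosen_limit: int
    tolerance: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "limit": self.limits,
                "mean_train_adj_r2": self.mean_train_adj_r2,
                "mean_test_adj_r2": self.mean_test_adj_r2,
            }
        )

    @property
    def chosen_features(self) -> list[str]:
        return self.selected[self.chosen_limit]


def _elimination_ranking(estimator, X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Full RFE path: rank 1 = last surviving feature (step=1 down to 1)."""
    rfe = RFE(estimator, n_features_to_select=1, step=1)
    rfe.fit(X, y)
    return rfe.ranking_


def rfe_sweep(
    X: pd.DataFrame,
    y: Sequence[float],
    spec: ModelSpec,
    limits: Sequence[int] = range(1, 31),
    iterations: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
    tolerance: float = 0.005,
) -> RFESweep:
    """Sweep feature limits 1..30 with model-ranked recursive elimination.

    Per Monte-Carlo iteration a fresh train/test split is drawn, a full
    elimination ranking is computed on the training fold, and for each limit
    the estimator is refit on the top-``limit`` features and scored on both
    folds with adjusted R2 (each set's own n, p = limit).  The reported
    selected sets come from a ranking on the full data; the chosen limit is
    the smallest whose mean test adjusted R2 is within ``tolerance`` of the
    sweep's peak.  Limits beyond the feature count are capped.
    """
    y = np.asarray(y, float)
    n_feat = X.shape[1]
    limits = sorted({min(int(l), n_feat) for l in limits})
    splitter = ShuffleSplit(
        n_splits=iterations, train_size=train_fraction, random_state=seed
    )

    train_scores = {l: [] for l in limits}
    test_scores = {l: [] for l in limits}
    for it, (tr, te) in enumerate(splitter.split(X)):
        Xtr, Xte = X.iloc[tr], X.iloc[te]
        ytr, yte = y[tr], y[te]
        est = make_estimator(spec, seed=seed + 1000 + it)
        ranking = _elimination_ranking(clone(est), Xtr, ytr)
        for limit in limits:
            cols = X.columns[ranking <= limit]
            model = clone(est).fit(Xtr[cols], ytr)
            r2_tr = r2_score(ytr, model.predict(Xtr[cols]))
            r2_te = r2_score(yte, model.predict(Xte[cols]))
            train_scores[limit].append(adjusted_r2(r2_tr, len(tr), limit))
            test_scores[limit].append(adjusted_r2(r2_te, len(te), limit))

    full_ranking = _elimination_ranking(make_estimator(spec, seed=seed), X, y)
    selected = {l: X.columns[full_ranking <= l].tolist() for l in limits}

    mean_train = [float(np.nanmean(train_scores[l])) for l in limits]
    mean_test = [float(np.nanmean(test_scores[l])) for l in limits]
    peak = max(mean_test)
    chosen = next(l for l, s in zip(limits, mean_test) if s >= peak - tolerance)
    return RFESweep(
        limits=list(limits),
        mean_train_adj_r2=mean_train,
        mean_test_adj_r2=mean_test,
        selected=selected,
        chosen_limit=chosen,
        tolerance=tolerance,
    )
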