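"""Breeding-oriented evaluation of plot-level yield predictions.

Four evaluation surfaces:

* per-flight Pearson correlations between each directly extracted trait
  and final yield, one series per year — how early in the season the
  canopy signal appears;
* ordinary least-squares regression of estimated on measured yield,
  overall and within year (pooling years with very different means can
  anchor two clusters and inflate R2, so the per-year view is the honest
  one);
* repeatability R = sigma2_g / (sigma2_g + sigma2_e / r) from a one-way
  random-genotype ANOVA on plot values (method of moments:
  sigma2_e = MS_within, sigma2_g = (MS_between - MS_within)/r with r the
  mean number of replicates) — the entry-mean analogue of broad-sense
  heritability when genotypes are unrelated;
* selection-relevant classification: genotype means are binned into
  Excellent (top 10%), Good (11th-25th percentile), Mediocre (26th-50th)
  and Poor (bottom half), and a 4x4 confusion matrix of measured vs
  estimated bins counts agreement, with special attention to catastrophic
  errors (Excellent <-> Poor).

Each prediction method is binned by its own percentile ranks, so the
confusion matrix is a pure ranking-agreement measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BIN_LABELS",
    "RepeatabilityEstimate",
    "ConfusionMatrix",
    "perflight_correlations",
    "regress_estimated_vs_measured",
    "repeatability",
    "bin_sizes",
    "bin_genotypes",
    "confusion_matrix",
]

#: yield categories, best first
BIN_LABELS = ("Excellent", "Good", "Mediocre", "Poor")

#: cumulative upper-percentile boundaries of the first three bins
_CUM_FRACTIONS = (0.10, 0.25, 0.50)


def perflight_correlations(
    traits: pd.DataFrame, yields: pd.DataFrame, trait_cols: Sequence[str] = ("CC", "CH", "CH90", "CV", "CV90", "ExG")
) -> pd.DataFrame:
    """Pearson r between each trait and yield, per flight date per year.

    Requires at least 3 plots on a date; a zero-variance trait on a date
    gives an undefined correlation, reported as NaN.
    """
    merged = traits.merge(yields[["plot_id", "yield"]], on="plot_id", how="inner")
    rows = []
    for (year, dap), g in merged.groupby(["year", "dap"]):
        for trait in trait_cols:
            sub = g[[trait, "yield"]].dropna()
            r = np.nan
            if len(sub) >= 3 and sub[trait].std() > 0 and sub["yield"].std() > 0:
                r = float(stats.pearsonr(sub[trait], sub["yield"])[0])
            rows.append({"year": year, "dap": dap, "trait": trait, "r": r, "n": len(sub)})
    return pd.DataFrame(rows)


def regress_estimated_vs_measured(
    predictions: pd.DataFrame,
    grouping: Literal["overall", "per-year"] = "overall",
    yields: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS of estimated on measured yield, overall or within year.

    ``predictions`` needs ``plot_id, measured, estimated``; for per-year
    grouping a ``year`` column must be present or joinable via ``yields``.
    Returns one row per group with slope, intercept, R2 and n.
    """
    df = predictions.copy()
    if grouping == "per-year" and "year" not in df.columns:
        if yields is None:
            raise ValueError("per-year grouping needs a 'year' column or a yields table")
        df = df.merge(yields[["plot_id", "year"]], on="plot_id", how="left")
    groups = [("overall", df)] if grouping == "overall" else list(df.groupby("year"))
    rows = []
    for label, g in groups:
        if len(g) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 points")
        if g["measured"].std() == 0:
            raise ValueError(f"constant measured yield in group {label!r}")
        fit = stats.linregress(g["measured"], g["estimated"])
        rows.append(
            {
                "group": label,
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r2": float(fit.rvalue**2),
                "n": len(g),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RepeatabilityEstimate:
    """Variance components and entry-mean repeatability."""

    sigma2_g: float
    sigma2_e: float
    r_reps: float
    repeatability: float
    truncated: bool = False   # True when a negative genotype variance was clipped to 0


def repeatability(
    values: Sequence[float], genotypes: Sequence[str]
) -> RepeatabilityEstimate:
    """Entry-mean repeatability from a one-way random-genotype ANOVA.

    Method-of-moments estimates: sigma2_e = MS_within,
    sigma2_g = (MS_between - MS_within) / r with r the mean replicate count;
    R = sigma2_g / (sigma2_g + sigma2_e / r).  Negative genotype-variance
    estimates are truncated to zero and flagged.
    """
    df = pd.DataFrame({"value": np.asarray(values, float), "genotype": list(genotypes)}).dropna()
    counts = df.groupby("genotype")["value"].count()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 genotypes with >= 2 replicates")
    g = counts.size
    n = len(df)
    r_bar = n / g
    grand = df["value"].mean()
    means = df.groupby("genotype")["value"].transform("mean")
    ss_within = float(((df["value"] - means) ** 2).sum())
    group_means = df.groupby("genotype")["value"].agg(["mean", "count"])
    ss_between = float((group_means["count"] * (group_means["mean"] - grand) ** 2).sum())
    ms_within = ss_within / (n - g)
    ms_between = ss_between / (g - 1)
    sigma2_g = (ms_between - ms_within) / r_bar
    truncated = sigma2_g < 0
    sigma2_g = max(sigma2_g, 0.0)
    denom = sigma2_g + ms_within / r_bar
    rep = sigma2_g / denom if denom > 0 else 0.0
    return RepeatabilityEstimate(
        sigma2_g=sigma2_g,
        sigma2_e=ms_within,
        r_reps=r_bar,
        repeatability=float(rep),
        truncated=truncated,
    )


def bin_sizes(n_genotypes: int) -> dict[str, int]:
    """Bin sizes from the percentile boundaries, exact for any genotype count.

    Cumulative boundaries at 10/25/50% are converted to counts with
    round-half-up, so the four bins always partition the genotype set.
    """
    if n_genotypes < 4:
        raise ValueError("need at least 4 genotypes to form the four bins")
    cum = [int(math.floor(f * n_genotypes + 0.5)) for f in _CUM_FRACTIONS]
    sizes = {
        "Excellent": cum[0],
        "Good": cum[1] - cum[0],
        "Mediocre": cum[2] - cum[1],
        "Poor": n_genotypes - cum[2],
    }
    return sizes


def bin_genotypes(genotype_means: pd.Series) -> pd.Series:
    """Assign each genotype mean to a yield bin by percentile rank.

    Genotypes are ranked best-first; ties break by stable genotype-id
    order.  Returns a Series of bin labels indexed like the input.
    """
    means = genotype_means.dropna()
    sizes = bin_sizes(len(means))
    order = means.sort_values(ascending=False, kind="stable").index
    labels = {}
    pos = 0
    for label in BIN_LABELS:
        for geno in order[pos : pos + sizes[label]]:
            labels[geno] = label
        pos += sizes[label]
    return pd.Series([labels[g] for g in genotype_means.index], index=genotype_means.index, name="bin")


@dataclass
class ConfusionMatrix:
    """4x4 yield-bin agreement: rows = measured bin, columns = estimated."""

    counts: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts.to_numpy()))

    @property
    def catastrophic(self) -> int:
        """Excellent <-> Poor misclassifications, the worst selection errors."""
        return int(
            self.counts.loc["Excellent", "Poor"] + self.counts.loc["Poor", "Excellent"]
        )


def confusion_matrix(measured_bins: pd.Series, estimated_bins: pd.Series) -> ConfusionMatrix:
    """Count measured-vs-estimated bin assignments over the same genotypes."""
    if set(measured_bins.index) != set(estimated_bins.index):
        raise ValueError("measured and estimated bins cover different genotype sets")
    est = estimated_bins.reindex(measured_bins.index)
    counts = pd.DataFrame(0, index=list(BIN_LABELS), columns=list(BIN_LABELS))
    for m, e in zip(measured_bins, est):
        counts.loc[m, e] += 1
    counts.index.name = "measured"
    counts.columns.name = "estimated"
    return ConfusionMatrix(counts=counts)
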