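"""Sigmoidal growth-curve models for plot-level trait time series.

Two families are supported, each parameterised in its conventional form:

* logistic ``N(t) = K / (1 + ((K - N0)/N0) e^{-r t})`` with carrying
  capacity ``K``, value ``N0`` at t = 0 and intrinsic rate ``r``;
* Gompertz ``N(t) = A exp(-b e^{-c t})`` with upper asymptote ``A``,
  displacement ``b`` and rate ``c`` (so ``N(0) = A e^{-b}``).

Both are strictly increasing for valid parameters and have a single
inflection point; their analytic first derivatives are the growth-rate
curves from which latent phenotypes are extracted downstream.  Time is
measured in days after planting (DAP, planting day = 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LogisticParams",
    "GompertzParams",
    "SigmoidFit",
    "TRAIT_COLUMNS",
    "evaluate_curve",
    "growth_rate",
    "fit_sigmoid",
    "fit_trait_table",
    "impute_missing",
]

Family = Literal["logistic", "gompertz"]

#: trait columns fitted by default, in canonical order
TRAIT_COLUMNS = ("CC", "CH", "CH90", "CV", "CV90", "ExG")


@dataclass(frozen=True)
class LogisticParams:
    """Logistic parameters: asymptote K, initial value N0 = N(0), rate r."""

    asymptote: float
    initial: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.asymptote > 0 and 0 < self.initial < self.asymptote and self.rate > 0):
            raise ValueError(
                f"invalid logistic parameters K={self.asymptote}, "
                f"N0={self.initial}, r={self.rate}"
            )

    def value(self, t):
        a = (self.asymptote - self.initial) / self.initial
        return self.asymptote / (1.0 + a * np.exp(-self.rate * np.asarray(t, float)))

    def derivative(self, t):
        n = self.value(t)
        return self.rate * n * (1.0 - n / self.asymptote)

    @property
    def inflection_time(self) -> float:
        return math.log((self.asymptote - self.initial) / self.initial) / self.rate

    @property
    def inflection_value(self) -> float:
        return self.asymptote / 2.0

    @property
    def peak_rate(self) -> float:
        return self.rate * self.asymptote / 4.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.asymptote, self.initial, self.rate)


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz parameters: upper asymptote A, displacement b, rate c."""

    asymptote: float
    displacement: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.asymptote > 0 and self.displacement > 0 and self.rate > 0):
            raise ValueError(
                f"invalid Gompertz parameters A={self.asymptote}, "
                f"b={self.displacement}, c={self.rate}"
            )

    def value(self, t):
        t = np.asarray(t, float)
        return self.asymptote * np.exp(-self.displacement * np.exp(-self.rate * t))

    def derivative(self, t):
        t = np.asarray(t, float)
        u = self.displacement * np.exp(-self.rate * t)
        return self.asymptote * self.rate * u * np.exp(-u)

    @property
    def inflection_time(self) -> float:
        return math.log(self.displacement) / self.rate

    @property
    def inflection_value(self) -> float:
        return self.asymptote / math.e

    @property
    def peak_rate(self) -> float:
        return self.asymptote * self.rate / math.e

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.asymptote, self.displacement, self.rate)


Params = LogisticParams | GompertzParams


def evaluate_curve(params: Params, t):
    """Curve value N(t) for either family (vectorised over *t*)."""
    return params.value(t)


def growth_rate(params: Params, t):
    """Analytic first derivative N'(t) — the growth-rate curve."""
    return params.derivative(t)


@dataclass
class SigmoidFit:
    """A fitted sigmoid for one plot x trait series.

    ``window`` is (first observed DAP, last observed DAP); ``r2_fit`` is
    1 - RSS/TSS of the fit itself (not a cross-validated quantity).
    """

    family: Family
    params: Params
    rss: float
    r2_fit: float
    converged: bool
    window: tuple[float, float]
    n_obs: int = 0

    def value(self, t):
        return self.params.value(t)

    def rate(self, t):
        return self.params.derivative(t)

    def to_dict(self) -> dict:
        keys = {
            "logistic": ("asymptote", "initial", "rate"),
            "gompertz": ("asymptote", "displacement", "rate"),
        }[self.family]
        return {
            "family": self.family,
            "params": dict(zip(keys, self.params.as_tuple())),
            "rss": self.rss,
            "r2_fit": self.r2_fit,
            "converged": self.converged,
            "window": list(self.window),
            "n_obs": self.n_obs,
        }


def _logistic_theta(t, theta):
    # theta = (K, A, r) with A = (K - N0)/N0 > 0
    k, a, r = theta
    return k / (1.0 + a * np.exp(-r * t))


def _gompertz_theta(t, theta):
    a, b, c = theta
    return a * np.exp(-b * np.exp(-c * t))


def _initial_rate_guess(t: np.ndarray, v: np.ndarray) -> float:
    """Log-slope of the middle third of the series, clipped to the rate bounds."""
    n = len(t)
    lo, hi = n // 3, max(n // 3 + 2, 2 * n // 3)
    tm, vm = t[lo:hi], np.clip(v[lo:hi], 1e-9, None)
    if len(tm) < 2 or tm[-1] == tm[0]:
        return 0.08
    slope = (np.log(vm[-1]) - np.log(vm[0])) / (tm[-1] - tm[0])
    return float(np.clip(abs(slope) if slope != 0 else 0.08, 2e-4, 0.9))


def fit_sigmoid(
    dap: Sequence[float],
    values: Sequence[float],
    family: Family,
    asymptote_cap: float | None = None,
    n_restarts: int = 4,
    restart_seed: int = 0,
) -> SigmoidFit:
    """Fit one sigmoid family to a (DAP, value) series by bounded least squares.

    A deterministic multi-start is used: a data-driven initial guess (asymptote
    at 1.05x the observed maximum, rate from the log-slope of the middle third
    of the series, displacement matched to the first observation) plus
    ``n_restarts`` log-normally jittered copies drawn from a fixed seed.  The
    restart with the lowest residual sum of squares wins.  Non-convergence is
    reported via ``converged=False`` with best-effort parameters retained.

    ``asymptote_cap`` bounds the fitted asymptote (e.g. 1.0 for canopy cover,
    which is a fraction of plot area).
    """
    t = np.asarray(dap, float)
    v = np.asarray(values, float)
    ok = np.isfinite(t) & np.isfinite(v)
    t, v = t[ok], v[ok]
    if len(t) < 4:
        raise ValueError("need at least 4 observations to fit a 3-parameter sigmoid")
    if np.any(v < 0):
        raise ValueError("trait values must be non-negative")
    order = np.argsort(t)
    t, v = t[order], v[order]
    window = (float(t[0]), float(t[-1]))
    vmax = float(v.max())
    if vmax <= 0:
        raise ValueError("series is identically zero; nothing to fit")

    cap = 2.0 * vmax
    if asymptote_cap is not None:
        cap = min(cap, float(asymptote_cap))
    lo = np.array([1e-8, 1e-3, 1e-4])
    hi = np.array([cap, 1e3, 1.0])

    a0 = min(1.05 * vmax, cap * (1 - 1e-9))
    r0 = _initial_rate_guess(t, v)
    v0 = max(float(v[0]), 1e-6)
    if family == "logistic":
        model = _logistic_theta
        # A = (K - N0)/N0 from the first observation back-projected to t=0
        n0_guess = min(v0, 0.9 * a0)
        a_disp = max((a0 - n0_guess) / n0_guess * math.exp(-r0 * t[0]), 1e-3)
        theta0 = np.array([a0, min(a_disp, 1e3), r0])
    elif family == "gompertz":
        model = _gompertz_theta
        b0 = -math.log(min(v0 / a0, 1 - 1e-9)) * math.exp(r0 * t[0])
        theta0 = np.array([a0, float(np.clip(b0, 1e-3, 1e3)), r0])
    else:
        raise ValueError(f"unknown family {family!r}")

    rng = np.random.default_rng(restart_seed)
    starts = [theta0]
    for _ in range(n_restarts):
        jitter = np.exp(rng.normal(0.0, 0.3, size=3))
        starts.append(np.clip(theta0 * jitter, lo * 1.01, hi * 0.99))

    best = None
    for start in starts:
        try:
            res = least_squares(
                lambda th: model(t, th) - v,
                np.clip(start, lo + 1e-12, hi - 1e-12),
                bounds=(lo, hi),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=5000,
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)

    converged = best is not None and best[1].success
    if best is None:  # pragma: no cover
        theta, rss = theta0, float(np.sum((model(t, theta0) - v) ** 2))
    else:
        rss, res = best
        theta = res.x

    if family == "logistic":
        k, a, r = theta
        params = LogisticParams(asymptote=float(k), initial=float(k / (1.0 + a)), rate=float(r))
    else:
        params = GompertzParams(*(float(x) for x in theta))

    tss = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return SigmoidFit(
        family=family,
        params=params,
        rss=rss,
        r2_fit=r2,
        converged=bool(converged),
        window=window,
        n_obs=len(t),
    )


def impute_missing(
    traits: pd.DataFrame,
    trait_cols: Iterable[str] = TRAIT_COLUMNS,
    schedule: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Fill missing plot x date trait observations with per-date means.

    Every plot observed in a year is expected on every flight date of that
    year; rows absent from the table (occluded plots) are inserted and each
    missing trait value is replaced by the mean of that trait over the plots
    observed on the same date in the same year.  Imputed rows/cells carry
    ``imputed=True``.  ``schedule`` optionally fixes the flight dates per
    year; by default the dates observed in the data are used.

    Raises ``ValueError`` if some date has no observation at all for a trait
    (there is then no mean to impute from).
    """
    trait_cols = list(trait_cols)
    df = traits.copy()
    if "imputed" not in df.columns:
        df["imputed"] = False

    out = []
    for year, g in df.groupby("year", sort=False):
        daps = sorted(schedule[year]) if schedule is not None else sorted(g["dap"].unique())
        plots = g[["plot_id", "genotype", "rep"]].drop_duplicates("plot_id") if "rep" in g else (
            g[["plot_id", "genotype"]].drop_duplicates("plot_id")
        )
        grid = plots.merge(pd.DataFrame({"dap": daps}), how="cross")
        grid["year"] = year
        merged = grid.merge(g, on=[c for c in grid.columns if c in g.columns], how="left")
        merged["imputed"] = merged["imputed"].astype("boolean").fillna(False).astype(bool)
        for col in trait_cols:
            means = merged.groupby("dap")[col].transform("mean")
            missing = merged[col].isna()
            if missing.any():
                if means[missing].isna().any():
                    bad = merged.loc[missing & means.isna(), "dap"].unique()
                    raise ValueError(
                        f"trait {col!r} has no observation on date(s) {bad.tolist()} "
                        f"in year {year}; cannot impute"
                    )
                merged.loc[missing, col] = means[missing]
                merged.loc[missing, "imputed"] = True
        out.append(merged)
    result = pd.concat(out, ignore_index=True)
    n_filled = int(result["imputed"].sum()) - int(df["imputed"].sum())
    if n_filled:
        warnings.warn(f"imputed {n_filled} plot x date records", stacklevel=2)
    return result


def fit_trait_table(
    traits: pd.DataFrame,
    families: Sequence[Family] = ("gompertz", "logistic"),
    trait_cols: Iterable[str] = TRAIT_COLUMNS,
    n_restarts: int = 4,
) -> dict[tuple[str, str, str], SigmoidFit]:
    """Fit every (plot, trait, family) series in a tidy trait table.

    Returns a dict keyed by ``(plot_id, trait, family)``.  Canopy-cover fits
    are capped at asymptote 1.0 (cover is a fraction of plot area).
    """
    fits: dict[tuple[str, str, str], SigmoidFit] = {}
    for plot_id, g in traits.groupby("plot_id", sort=False):
        g = g.sort_values("dap")
        for trait in trait_cols:
            series = g[["dap", trait]].dropna()
            for family in families:
                cap = 1.0 if trait == "CC" else None
                try:
                    fit = fit_sigmoid(
                        series["dap"].to_numpy(),
                        series[trait].to_numpy(),
                        family,
                        asymptote_cap=cap,
                        n_restarts=n_restarts,
                    )
                except ValueError:
                    continue
                fits[(str(plot_id), trait, family)] = fit
    return fits
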