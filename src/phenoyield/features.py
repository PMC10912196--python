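"""Latent phenotypes extracted from fitted growth curves and their derivatives.

Fourteen features summarise each fitted sigmoid and its growth-rate curve
(the analytic first derivative), indexed f1..f14:

f1  value of the curve at the inflection point        (trait units)
f2  DAP at 50% of the inflection-point value          (days)
f3  DAP at 80% of the inflection-point value          (days)
f4  DAP at the inflection point                       (days)
f5  maximum value attained over the observed window   (trait units)
f6  DAP at maximum growth rate                        (days)
f7  maximum growth rate                               (units/day)
f8  DAP at the first half-maximum growth rate         (days)
f9  DAP at the last half-maximum growth rate          (days)
f10 days between the half-maximum growth rates        (days)
f11 area under the growth-rate curve over the window  (trait units)
f12 mean growth rate over the window                  (units/day)
f13 rate of growth-rate increase (half-max to peak)   (units/day^2)
f14 rate of growth-rate decrease (peak to half-max)   (units/day^2)

For a sigmoid, f4 = f6 (the rate peaks at the inflection) and, by the
fundamental theorem of calculus, f11 equals the net trait gain
N(window end) - N(window start).  f13 and f14 are the slopes of the chords
joining the half-maximum-rate crossings to the rate peak, signed so that
the rising limb is positive and the falling limb negative.

Crossing times (f2, f3, f8, f9) are located by root bracketing and Brent's
method on the analytic curves, so both families share one code path; the
logistic and Gompertz closed forms (Lambert-W for the rate half-maxima)
serve as independent oracles in the test suite.  Crossings falling outside
the observed window are clipped to the window bound and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .growth import SigmoidFit

__all__ = ["FEATURE_NAMES", "FEATURE_DESCRIPTIONS", "LatentFeatureSet", "extract_features", "feature_pool"]

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = tuple(f"f{i}" for i in range(1, 15))

FEATURE_DESCRIPTIONS: Mapping[str, str] = {
    "f1": "value at inflection point",
    "f2": "DAP at 50% of inflection value",
    "f3": "DAP at 80% of inflection value",
    "f4": "DAP at inflection point",
    "f5": "maximum value over observed window",
    "f6": "DAP at maximum growth rate",
    "f7": "maximum growth rate",
    "f8": "DAP at first half-maximum growth rate",
    "f9": "DAP at last half-maximum growth rate",
    "f10": "days between half-maximum growth rates",
    "f11": "area under growth-rate curve",
    "f12": "mean growth rate",
    "f13": "rate of growth-rate increase",
    "f14": "rate of growth-rate decrease",
}

_XTOL = 1e-10  # days; bisection tolerance on crossing times


@dataclass
class LatentFeatureSet:
    """The 14 latent phenotypes for one fitted (plot, trait, family) curve."""

    values: dict[str, float]
    clipped: tuple[str, ...] = ()

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[name] for name in FEATURE_NAMES])


def _solve_increasing(func, target: float, t_ref: float, direction: int) -> float:
    """Root of ``func(t) - target`` on the side ``direction`` (+1/-1) of t_ref.

    ``func`` must approach a value below ``target`` as t moves away from
    ``t_ref`` in ``direction`` and exceed it at ``t_ref``.  The bracket is
    expanded geometrically until the sign change is enclosed.
    """
    span = 1.0
    t_far = t_ref - direction * span
    for _ in range(200):
        if func(t_far) - target < 0:
            break
        span *= 2.0
        t_far = t_ref - direction * span
    else:  # pragma: no cover - pathological parameters
        raise RuntimeError("failed to bracket crossing")
    a, b = sorted((t_far, t_ref))
    return float(brentq(lambda t: func(t) - target, a, b, xtol=_XTOL))


def extract_features(fit: SigmoidFit) -> LatentFeatureSet:
    """Extract the 14 latent phenotypes from a converged sigmoid fit."""
    if not fit.converged:
        raise ValueError("latent features require a converged fit")
    p = fit.params
    a, b = fit.window
    t_inf = p.inflection_time
    f1 = p.inflection_value
    f7 = p.peak_rate

    # value crossings at 50% / 80% of the inflection value (rising limb only)
    f2 = _solve_increasing(lambda t: float(p.value(t)), 0.5 * f1, t_inf, +1)
    f3 = _solve_increasing(lambda t: float(p.value(t)), 0.8 * f1, t_inf, +1)

    # rate half-maximum crossings either side of the peak
    half = 0.5 * f7
    f8 = _solve_increasing(lambda t: float(p.derivative(t)), half, t_inf, +1)
    f9 = _solve_increasing(lambda t: float(p.derivative(t)), half, t_inf, -1)

    # slopes of the rate-curve chords use the analytic (unclipped) crossing
    # times, which straddle the inflection strictly, so they stay finite even
    # when a crossing falls outside the observed season
    f13 = f7 / (2.0 * (t_inf - f8))
    f14 = -f7 / (2.0 * (f9 - t_inf))

    clipped = []
    vals = {"f2": f2, "f3": f3, "f8": f8, "f9": f9}
    for name, t in vals.items():
        if t < a or t > b:
            vals[name] = float(np.clip(t, a, b))
            clipped.append(name)
    f2, f3, f8, f9 = vals["f2"], vals["f3"], vals["f8"], vals["f9"]

    f5 = float(p.value(b))  # curves are increasing: window end is the max
    f11 = float(p.value(b) - p.value(a))
    f12 = f11 / (b - a)

    values = {
        "f1": float(f1),
        "f2": f2,
        "f3": f3,
        "f4": float(t_inf),
        "f5": f5,
        "f6": float(t_inf),
        "f7": float(f7),
        "f8": f8,
        "f9": f9,
        "f10": f9 - f8,
        "f11": f11,
        "f12": f12,
        "f13": f13,
        "f14": f14,
    }
    return LatentFeatureSet(values=values, clipped=tuple(clipped))


def feature_pool(
    fits: Mapping[tuple[str, str, str], SigmoidFit],
    traits: Sequence[str] | None = None,
    families: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the wide candidate-feature table from a collection of fits.

    ``fits`` maps ``(plot_id, trait, family)`` to a :class:`SigmoidFit`.
    Columns are named ``{trait}_{family}_{feature}`` (e.g. ``CC_gompertz_f9``);
    one row per plot.  Plots missing a converged fit for any requested
    trait x family combination are dropped with a logged reason, so the
    resulting matrix is complete.
    """
    all_traits = sorted({k[1] for k in fits}) if traits is None else list(traits)
    all_families = sorted({k[2] for k in fits}) if families is None else list(families)
    plots = sorted({k[0] for k in fits})

    rows: dict[str, dict[str, float]] = {}
    for plot_id in plots:
        row: dict[str, float] = {}
        reason = None
        for trait in all_traits:
            for family in all_families:
                fit = fits.get((plot_id, trait, family))
                if fit is None or not fit.converged:
                    reason = f"no converged {family} fit for trait {trait}"
                    break
                feats = extract_features(fit)
                for name in FEATURE_NAMES:
                    row[f"{trait}_{family}_{name}"] = feats[name]
            if reason:
                break
        if reason:
            logger.info("dropping plot %s from feature pool: %s", plot_id, reason)
        else:
            rows[plot_id] = row

    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "plot_id"
    cols = [
        f"{trait}_{family}_{name}"
        for trait in all_traits
        for family in all_families
        for name in FEATURE_NAMES
    ]
    return df.reindex(columns=cols)
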