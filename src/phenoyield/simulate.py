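"""Synthetic field-trial generator for the growth-curve yield pipeline.

Emulates a multi-year peanut breeding trial phenotyped by repeated UAV
flights: ~73 genotypes x 3 replicates in a randomized complete block
design per year (~219 plots/year), 12-18 flight dates spanning roughly
10-130 days after planting (DAP), sigmoidal trait trajectories (canopy
cover CC, canopy height CH and its 90th percentile CH90, canopy volume
CV = CC x CH and CV90, normalized excess-green ExG), occasional plots
missing at random on a date, and plot yield (tons/ha) generated as a
linear function of latent growth features of the plot's own true curves
plus a genotype effect and Gaussian residual.

Genotype-level Gompertz parameters are drawn log-normally around
trait-specific medians so trajectories have realistic shape variation;
plot-level log-normal parameter noise and additive measurement noise sit
on top.  A small tile renderer produces paired RGB/DEM plot images with
known canopy cover and height for exercising the image-trait extractor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .features import FEATURE_NAMES, extract_features
from .growth import GompertzParams, SigmoidFit

__all__ = [
    "TrialDesign",
    "GenotypeTruth",
    "YieldModelTruth",
    "sample_genotype_truth",
    "simulate_trial",
    "calibrate_residual_sd",
    "render_plot_tile",
    "write_tile_dataset",
    "DEFAULT_DAP_SCHEDULES",
]

#: default flight schedules: 12 flights in the first year, 18 in the second
DEFAULT_DAP_SCHEDULES: Mapping[str, tuple[int, ...]] = {
    "2021": tuple(range(14, 130, 10)),          # 12 dates, 14..124 DAP
    "2022": tuple(range(10, 130, 7)),           # 18 dates, 10..129 DAP
}

#: sigmoid base traits that get their own Gompertz truth; CV/CV90 are products
BASE_TRAITS = ("CC", "CH", "CH90", "ExG")

#: per-trait median (asymptote, displacement, rate) of the genotype population
DEFAULT_TRAIT_MEDIANS: Mapping[str, tuple[float, float, float]] = {
    "CC": (0.90, 8.0, 0.080),
    "CH": (0.40, 8.0, 0.070),
    "CH90": (0.50, 8.0, 0.070),
    "ExG": (0.85, 6.0, 0.090),
}

#: additive measurement noise SD per trait (trait units)
DEFAULT_MEASUREMENT_NOISE: Mapping[str, float] = {
    "CC": 0.02,
    "CH": 0.02,
    "CH90": 0.025,
    "ExG": 0.02,
}


@dataclass(frozen=True)
class TrialDesign:
    """Layout of one multi-year RCBD trial with repeated UAV flights."""

    n_genotypes: int = 73
    n_reps: int = 3
    dap_schedules: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DAP_SCHEDULES)
    )
    missing_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_genotypes < 1 or self.n_reps < 1:
            raise ValueError("need at least one genotype and one replicate")
        if not (0 <= self.missing_rate < 0.2):
            raise ValueError("missing_rate must lie in [0, 0.2)")
        if not self.dap_schedules:
            raise ValueError("at least one year with a flight schedule is required")
        for year, daps in self.dap_schedules.items():
            if len(daps) == 0:
                raise ValueError(f"empty DAP schedule for year {year}")
            arr = np.asarray(daps)
            if not np.all(np.diff(arr) > 0):
                raise ValueError(f"DAP schedule for {year} must be strictly increasing")
            if arr.min() < 7 or arr.max() > 130:
                raise ValueError(f"DAP schedule for {year} must lie within [7, 130]")

    @property
    def years(self) -> tuple[str, ...]:
        return tuple(self.dap_schedules)

    @property
    def plots_per_year(self) -> int:
        return self.n_genotypes * self.n_reps


@dataclass
class GenotypeTruth:
    """Generating parameters: per-genotype Gompertz truth and noise scales.

    ``params[trait]`` is a DataFrame indexed by genotype with columns
    ``asymptote``, ``displacement``, ``rate``.  ``plot_noise_sd`` is the
    log-normal sigma applied per plot to every curve parameter;
    ``measurement_noise[trait]`` the additive observation SD.
    """

    params: Mapping[str, pd.DataFrame]
    genotype_yield_effect: pd.Series
    plot_noise_sd: float = 0.05
    measurement_noise: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEASUREMENT_NOISE)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for trait, df in self.params.items():
            if (df[["asymptote", "displacement", "rate"]] <= 0).any().any():
                raise ValueError(f"non-positive Gompertz parameter for trait {trait}")
        if "CC" in self.params and (self.params["CC"]["asymptote"] > 1).any():
            raise ValueError("canopy-cover asymptote exceeds 1 (cover is a fraction)")

    @property
    def genotypes(self) -> list[str]:
        return list(next(iter(self.params.values())).index)


@dataclass
class YieldModelTruth:
    """Known linear map from latent growth features to expected yield.

    ``features`` lists the driving features as ``(trait, feature)`` pairs
    with feature codes f1..f14 (computed from each plot's true Gompertz
    curve); yield = intercept + features . coefs + genotype effect +
    N(0, residual_sd), all in tons/ha.
    """

    features: tuple[tuple[str, str], ...] = (
        ("CC", "f9"),
        ("CC", "f7"),
        ("CC", "f11"),
        ("CH90", "f4"),
        ("ExG", "f1"),
    )
    coefs: tuple[float, ...] = (-0.045, 30.0, 2.5, -0.030, 3.0)
    intercept: float = 5.5
    residual_sd: float = 0.30

    def __post_init__(self) -> None:
        if len(self.features) != len(self.coefs):
            raise ValueError("features and coefs must align")
        if sum(c != 0 for c in self.coefs) < 3:
            raise ValueError("need at least 3 nonzero coefficients")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")

    @property
    def column_names(self) -> list[str]:
        # matches the pool naming scheme for Gompertz-derived features
        return [f"{trait}_gompertz_{feat}" for trait, feat in self.features]


def sample_genotype_truth(
    design: TrialDesign,
    seed: int,
    trait_medians: Mapping[str, tuple[float, float, float]] = DEFAULT_TRAIT_MEDIANS,
    genotype_sigma: tuple[float, float, float] = (0.08, 0.25, 0.12),
    yield_effect_sd: float = 0.35,
    plot_noise_sd: float = 0.05,
    measurement_noise: Mapping[str, float] | None = None,
) -> GenotypeTruth:
    """Draw a genotype population log-normally around trait medians.

    ``genotype_sigma`` gives the log-scale SD for (asymptote, displacement,
    rate).  Canopy-cover asymptotes are clipped to 0.99 so cover stays a
    valid fraction.
    """
    rng = np.random.default_rng(seed)
    genotypes = [f"G{i:03d}" for i in range(1, design.n_genotypes + 1)]
    params: dict[str, pd.DataFrame] = {}
    for trait, (med_a, med_b, med_c) in trait_medians.items():
        draws = np.exp(rng.normal(0.0, genotype_sigma, size=(design.n_genotypes, 3)))
        df = pd.DataFrame(
            {
                "asymptote": med_a * draws[:, 0],
                "displacement": med_b * draws[:, 1],
                "rate": med_c * draws[:, 2],
            },
            index=pd.Index(genotypes, name="genotype"),
        )
        if trait == "CC":
            df["asymptote"] = df["asymptote"].clip(upper=0.99)
        params[trait] = df
    effects = pd.Series(
        rng.normal(0.0, yield_effect_sd, size=design.n_genotypes),
        index=pd.Index(genotypes, name="genotype"),
        name="yield_effect",
    )
    return GenotypeTruth(
        params=params,
        genotype_yield_effect=effects,
        plot_noise_sd=plot_noise_sd,
        measurement_noise=dict(measurement_noise or DEFAULT_MEASUREMENT_NOISE),
    )


def _plot_curve(truth: GenotypeTruth, plot_draw: np.ndarray, geno_row: pd.Series, trait: str) -> GompertzParams:
    a = float(geno_row["asymptote"] * plot_draw[0])
    b = float(geno_row["displacement"] * plot_draw[1])
    c = float(geno_row["rate"] * plot_draw[2])
    if trait == "CC":
        a = min(a, 0.995)
    return GompertzParams(asymptote=a, displacement=b, rate=c)


def _true_features(curve: GompertzParams, window: tuple[float, float]) -> dict[str, float]:
    fit = SigmoidFit(
        family="gompertz", params=curve, rss=0.0, r2_fit=1.0, converged=True, window=window
    )
    return extract_features(fit).values


def simulate_trial(
    design: TrialDesign,
    truth: GenotypeTruth,
    yield_truth: YieldModelTruth,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one trial: trait table, yield table and the truth record.

    Returns ``(traits, yields, truth_record)``:

    * ``traits``: one row per surviving plot x flight date with columns
      ``year, plot_id, genotype, rep, dap, CC, CH, CH90, CV, CV90, ExG``
      (CV = CC x CH and CV90 = CC x CH90 hold exactly, noise included);
    * ``yields``: one row per plot with the measured yield in tons/ha;
    * ``truth_record``: generating parameters — per-plot curve parameters,
      the true latent-feature matrix used for yield, coefficients, genotype
      effects and the seed — for parameter-recovery tests.

    All randomness derives from ``seed``; the same seed reproduces the
    tables bit for bit.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    trait_rows: list[dict] = []
    yield_rows: list[dict] = []
    plot_param_rows: list[dict] = []
    feat_rows: list[dict] = []

    for year in design.years:
        daps = np.asarray(design.dap_schedules[year], float)
        window = (float(daps[0]), float(daps[-1]))
        for rep in range(1, design.n_reps + 1):
            for geno in truth.genotypes:
                plot_id = f"{year}-R{rep}-{geno}"
                curves: dict[str, GompertzParams] = {}
                for trait in BASE_TRAITS:
                    draw = (
                        np.exp(rng.normal(0.0, truth.plot_noise_sd, size=3))
                        if truth.plot_noise_sd > 0
                        else np.ones(3)
                    )
                    curve = _plot_curve(truth, draw, truth.params[trait].loc[geno], trait)
                    curves[trait] = curve
                    plot_param_rows.append(
                        {
                            "year": year,
                            "plot_id": plot_id,
                            "genotype": geno,
                            "trait": trait,
                            "asymptote": curve.asymptote,
                            "displacement": curve.displacement,
                            "rate": curve.rate,
                        }
                    )

                # observations
                base = {t: curves[t].value(daps) for t in BASE_TRAITS}
                obs: dict[str, np.ndarray] = {}
                for trait in BASE_TRAITS:
                    sd = truth.measurement_noise.get(trait, 0.0)
                    noise = rng.normal(0.0, sd, size=len(daps)) if sd > 0 else 0.0
                    vals = base[trait] + noise
                    if trait in ("CC", "ExG"):
                        vals = np.clip(vals, 0.0, 1.0)
                    else:
                        vals = np.clip(vals, 0.0, None)
                    obs[trait] = vals
                keep = (
                    rng.random(len(daps)) >= design.missing_rate
                    if design.missing_rate > 0
                    else np.ones(len(daps), bool)
                )
                for j, dap in enumerate(daps):
                    if not keep[j]:
                        continue
                    cc, ch, ch90, exg = (obs[t][j] for t in BASE_TRAITS)
                    trait_rows.append(
                        {
                            "year": year,
                            "plot_id": plot_id,
                            "genotype": geno,
                            "rep": rep,
                            "dap": int(dap),
                            "CC": cc,
                            "CH": ch,
                            "CH90": ch90,
                            "CV": cc * ch,
                            "CV90": cc * ch90,
                            "ExG": exg,
                        }
                    )

                # yield from latent features of the plot's true curves
                feats: dict[str, float] = {"year": year, "plot_id": plot_id, "genotype": geno}
                for trait in BASE_TRAITS:
                    tf = _true_features(curves[trait], window)
                    for name in FEATURE_NAMES:
                        feats[f"{trait}_gompertz_{name}"] = tf[name]
                feat_rows.append(feats)
                lp = sum(
                    coef * feats[col]
                    for coef, col in zip(yield_truth.coefs, yield_truth.column_names)
                )
                resid = rng.normal(0.0, yield_truth.residual_sd) if yield_truth.residual_sd > 0 else 0.0
                y = yield_truth.intercept + lp + truth.genotype_yield_effect[geno] + resid
                yield_rows.append(
                    {
                        "year": year,
                        "plot_id": plot_id,
                        "genotype": geno,
                        "rep": rep,
                        "yield": float(y),
                        "linear_predictor": float(lp),
                    }
                )

    traits = pd.DataFrame(trait_rows)
    yields = pd.DataFrame(yield_rows)
    truth_record = {
        "seed": seed,
        "design": design,
        "genotype_params": truth.params,
        "genotype_effects": truth.genotype_yield_effect,
        "plot_params": pd.DataFrame(plot_param_rows),
        "true_features": pd.DataFrame(feat_rows).set_index("plot_id"),
        "yield_features": list(yield_truth.column_names),
        "yield_coefs": list(yield_truth.coefs),
        "intercept": yield_truth.intercept,
        "residual_sd": yield_truth.residual_sd,
    }
    return traits, yields, truth_record


def calibrate_residual_sd(
    true_features: pd.DataFrame, yield_truth: YieldModelTruth, target_r2: float
) -> YieldModelTruth:
    """Return a copy of ``yield_truth`` whose residual SD yields ``target_r2``.

    The true R-squared of the feature signal is var(Xb)/(var(Xb)+sd^2);
    the residual SD is solved from the realized variance of the linear
    predictor over the simulated plots.  Genotype effects are not part of
    the feature signal, so for an exactly defined target they should be
    generated with zero SD.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    lp = true_features[yield_truth.column_names].to_numpy() @ np.asarray(yield_truth.coefs)
    var_lp = float(np.var(lp))
    sd = math.sqrt(var_lp * (1.0 - target_r2) / target_r2)
    return replace(yield_truth, residual_sd=sd)


# ---------------------------------------------------------------------------
# tile rendering


def render_plot_tile(
    cc_target: float,
    height_target: float,
    image_size: tuple[int, int] = (100, 100),
    seed: int = 0,
    ground_elevation: float = 0.10,
    canopy_rgb: tuple[int, int, int] = (60, 140, 60),
    soil_rgb: tuple[int, int, int] = (150, 110, 70),
) -> tuple[np.ndarray, np.ndarray]:
    """Render one plot tile pair with known cover and height.

    Exactly ``round(cc_target * n_pixels)`` pixels take the canopy color
    (hue inside the segmentation band) over a uniform soil background (hue
    below the lower bound); the DEM is ``ground_elevation`` everywhere and
    ``ground_elevation + height_target`` on canopy pixels.  Returns
    ``(rgb uint8 HxWx3, dem float32 HxW)``.
    """
    if not 0.0 <= cc_target <= 1.0:
        raise ValueError("cc_target must lie in [0, 1]")
    if height_target < 0:
        raise ValueError("height_target must be non-negative")
    h, w = image_size
    n_pix = h * w
    n_canopy = int(round(cc_target * n_pix))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_pix, size=n_canopy, replace=False)
    mask = np.zeros(n_pix, bool)
    mask[idx] = True
    mask = mask.reshape(h, w)

    rgb = np.empty((h, w, 3), np.uint8)
    rgb[...] = np.array(soil_rgb, np.uint8)
    rgb[mask] = np.array(canopy_rgb, np.uint8)
    dem = np.full((h, w), ground_elevation, np.float32)
    dem[mask] += np.float32(height_target)
    return rgb, dem


def write_tile_dataset(
    records: pd.DataFrame,
    outdir: str | Path,
    image_size: tuple[int, int] = (100, 100),
    seed: int = 0,
) -> pd.DataFrame:
    """Render and write tile pairs for a set of trait records.

    ``records`` needs columns ``plot_id, genotype, year, dap, CC, CH``; one
    RGB PNG and one 32-bit DEM TIFF are written per row and a manifest
    DataFrame (also saved as ``manifest.csv``) is returned, suitable for
    :func:`phenoyield.traits.extract_trait_table`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    n = len(records)
    for i, rec in records.reset_index(drop=True).iterrows():
        # vary canopy saturation (hue fixed at 60) so greenness differs per tile
        c = 40 + int(round(40 * i / max(n - 1, 1)))
        rgb, dem = render_plot_tile(
            float(rec["CC"]),
            float(rec["CH"]),
            image_size=image_size,
            seed=seed + i,
            canopy_rgb=(c, 140, c),
        )
        stem = f"{rec['plot_id']}_d{int(rec['dap']):03d}"
        rgb_path = outdir / f"{stem}.png"
        dem_path = outdir / f"{stem}.tif"
        iio.imwrite(rgb_path, rgb)
        tifffile.imwrite(dem_path, dem)
        rows.append(
            {
                "plot_id": rec["plot_id"],
                "genotype": rec["genotype"],
                "year": rec["year"],
                "dap": int(rec["dap"]),
                "rgb_path": str(rgb_path),
                "dem_path": str(dem_path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
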