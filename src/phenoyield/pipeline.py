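"""End-to-end orchestration: simulate -> impute -> fit -> features ->
select -> cross-validate -> evaluate.

`run_pipeline` wires the stage modules together with one seed and returns
every intermediate product in a dict, so examples, tests and the
reproduction script all exercise the same code path.  Problem sizes
(iteration counts, families, traits) are parameters; the defaults are
desk-scale rather than the full protocol.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .growth import fit_trait_table, impute_missing
from .features import feature_pool
from .models import ModelSpec, kfold, mccv
from .selection import rfe_sweep, vif_filter
from .simulate import (
    GenotypeTruth,
    TrialDesign,
    YieldModelTruth,
    sample_genotype_truth,
    simulate_trial,
)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def run_pipeline(
    design: TrialDesign | None = None,
    seed: int = 0,
    truth: GenotypeTruth | None = None,
    yield_truth: YieldModelTruth | None = None,
    families: Sequence[str] = ("gompertz", "logistic"),
    trait_cols: Sequence[str] = ("CC", "CH", "CH90", "CV", "CV90", "ExG"),
    model_specs: Mapping[str, ModelSpec] | None = None,
    mccv_iterations: int = 200,
    train_fraction: float | str = 0.7,
    kfold_splits: int = 10,
    rfe_limits: Sequence[int] = range(1, 31),
    rfe_iterations: int = 5,
    run_rfe: bool = True,
    fit_restarts: int = 2,
) -> dict:
    """Run the whole pipeline on a synthetic trial and evaluate it.

    Returns a dict with the trait/yield tables, fits, candidate and pruned
    feature matrices, the VIF report, per-model RFE sweeps and CV results,
    regression/repeatability/confusion evaluations, and the truth record.
    """
    design = design or TrialDesign()
    truth = truth or sample_genotype_truth(design, seed=seed)
    yield_truth = yield_truth or YieldModelTruth()
    specs = model_specs or {
        "rf": ModelSpec("random_forest"),
        "xgb": ModelSpec("gradient_boosting"),
    }

    traits, yields, truth_record = simulate_trial(design, truth, yield_truth, seed=seed)
    traits = impute_missing(traits, trait_cols=trait_cols, schedule=design.dap_schedules)
    logger.info("simulated %d trait rows, %d plots", len(traits), len(yields))

    fits = fit_trait_table(traits, families=families, trait_cols=trait_cols, n_restarts=fit_restarts)
    pool = feature_pool(fits, traits=trait_cols, families=families)
    yields = yields.set_index("plot_id").loc[pool.index].reset_index()
    y = yields.set_index("plot_id")["yield"]

    pruned, vif_report = vif_filter(pool, threshold=5.0)
    logger.info("VIF pruning: %d -> %d features", pool.shape[1], pruned.shape[1])

    out: dict = {
        "design": design,
        "traits": traits,
        "yields": yields,
        "fits": fits,
        "pool": pool,
        "pruned": pruned,
        "vif_report": vif_report,
        "truth_record": truth_record,
        "models": {},
    }

    for name, spec in specs.items():
        entry: dict = {"spec": spec}
        X = pruned
        if run_rfe:
            sweep = rfe_sweep(
                pruned, y, spec, limits=rfe_limits, iterations=rfe_iterations, seed=seed
            )
            entry["rfe"] = sweep
            X = pruned[sweep.chosen_features]
        cv = mccv(
            spec, X, y, iterations=mccv_iterations, train_fraction=train_fraction, seed=seed
        )
        entry["cv"] = cv
        entry["kfold_test_adj_r2"] = kfold(spec, X, y, k=kfold_splits, seed=seed)[0]

        preds = cv.predictions.merge(yields[["plot_id", "year", "genotype"]], on="plot_id")
        entry["regression_overall"] = evaluation.regress_estimated_vs_measured(preds, "overall")
        entry["regression_per_year"] = evaluation.regress_estimated_vs_measured(preds, "per-year")

        rep_rows = []
        for year, g in preds.groupby("year"):
            rep_meas = evaluation.repeatability(g["measured"], g["genotype"])
            rep_est = evaluation.repeatability(g["estimated"], g["genotype"])
            rep_rows.append(
                {
                    "year": year,
                    "measured_R": rep_meas.repeatability,
                    "estimated_R": rep_est.repeatability,
                }
            )
        entry["repeatability"] = pd.DataFrame(rep_rows)

        measured_means = preds.groupby("genotype")["measured"].mean()
        estimated_means = preds.groupby("genotype")["estimated"].mean()
        mbins = evaluation.bin_genotypes(measured_means)
        ebins = evaluation.bin_genotypes(estimated_means)
        entry["confusion"] = evaluation.confusion_matrix(mbins, ebins)
        out["models"][name] = entry

    out["correlations"] = evaluation.perflight_correlations(traits, yields)
    return out
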