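"""Feature selection and cross-validated yield prediction on a small trial.

Runs VIF pruning, a short RFE sweep and Monte-Carlo cross-validation for
both ensemble learners on a reduced synthetic trial (~1 minute).
"""

import warnings

warnings.filterwarnings("ignore")

from phenoyield import (
    ModelSpec,
    TrialDesign,
    YieldModelTruth,
    feature_pool,
    fit_trait_table,
    mccv,
    rfe_sweep,
    sample_genotype_truth,
    simulate_trial,
    vif_filter,
)

design = TrialDesign(n_genotypes=73, n_reps=3,
                     dap_schedules={"2021": tuple(range(14, 130, 10))},
                     missing_rate=0.0)
truth = sample_genotype_truth(design, seed=1)
traits, yields, _ = simulate_trial(design, truth, YieldModelTruth(), seed=1)

fits = fit_trait_table(traits, families=("gompertz",), trait_cols=("CC", "CH90", "CV", "ExG"))
pool = feature_pool(fits, traits=("CC", "CH90", "CV", "ExG"), families=("gompertz",))
y = yields.set_index("plot_id").loc[pool.index, "yield"]
print(f"candidate features: {pool.shape[1]} (4 traits x 14 features)")

pruned, report = vif_filter(pool, threshold=5.0)
print(f"after VIF > 5 pruning: {pruned.shape[1]} features survive")

spec = ModelSpec("random_forest", {"n_estimators": 150})
sweep = rfe_sweep(pruned, y, spec, limits=range(1, 11), iterations=3, seed=1)
print(f"RFE chose {sweep.chosen_limit} features: {sweep.chosen_features}")

for name, kind in [("random forest", "random_forest"), ("XGBoost", "gradient_boosting")]:
    cv = mccv(ModelSpec(kind), pruned[sweep.chosen_features], y, iterations=50, seed=1)
    print(f"{name:14s} MCCV mean adj R2: train {cv.mean_train_adj_r2:.3f}, "
          f"test {cv.mean_test_adj_r2:.3f} (best iteration {cv.best_iteration})")
print("\nTest scores are what matter for unseen plots; the train/test gap")
print("shows how much the ensembles overfit at this trial size.")
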