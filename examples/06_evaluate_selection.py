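"""Breeding-oriented evaluation: regression, repeatability, confusion bins.

Uses the end-to-end pipeline on a reduced trial and prints the surfaces a
breeder would inspect before trusting model-driven selection (~2 minutes).
"""

import warnings

warnings.filterwarnings("ignore")

from phenoyield import ModelSpec, TrialDesign
from phenoyield.pipeline import run_pipeline

result = run_pipeline(
    design=TrialDesign(n_genotypes=30, n_reps=3, missing_rate=0.0),
    seed=5,
    families=("gompertz",),
    trait_cols=("CC", "CH90", "ExG"),
    model_specs={"rf": ModelSpec("random_forest", {"n_estimators": 150})},
    mccv_iterations=50,
    rfe_limits=range(1, 9),
    rfe_iterations=2,
)

entry = result["models"]["rf"]
print("regression of estimated on measured yield:")
print(entry["regression_overall"].round(3).to_string(index=False))
print(entry["regression_per_year"].round(3).to_string(index=False))
print("\nrepeatability (entry-mean R) per year:")
print(entry["repeatability"].round(3).to_string(index=False))
print("\nconfusion matrix of genotype yield bins (rows measured, cols estimated):")
print(entry["confusion"].counts.to_string())
print(f"\ncorrect: {entry['confusion'].n_correct}/{entry['confusion'].total}, "
      f"catastrophic Excellent<->Poor errors: {entry['confusion'].catastrophic}")
print("\nPooling years can inflate the overall R2 relative to within-year fits;")
print("catastrophic errors are the misclassifications a breeder cannot accept.")
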