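"""Simulate a two-year UAV-phenotyped breeding trial with known truth.

73 genotypes x 3 replicates per year, 12 flights in the first season and
18 in the second, sigmoidal trait trajectories and yields driven by known
latent growth features.
"""

from phenoyield import TrialDesign, YieldModelTruth, sample_genotype_truth, simulate_trial

design = TrialDesign()  # defaults: 73 x 3, years 2021/2022, 1% missing dates
truth = sample_genotype_truth(design, seed=42)
traits, yields, record = simulate_trial(design, truth, YieldModelTruth(), seed=42)

print(f"trait rows: {len(traits)} (plots x surviving flight dates)")
print(f"plots:      {len(yields)} ({design.plots_per_year} per year)")
print("\nfirst plot, first flights:")
print(traits.head(3)[["plot_id", "dap", "CC", "CH", "CV", "ExG"]].to_string(index=False))
print("\nyield summary (tons/ha):")
print(yields["yield"].describe()[["mean", "std", "min", "max"]].round(2).to_string())
# The truth record keeps every generating parameter, so downstream stages
# can be scored against the exact curves and coefficients that made the data.
print(f"\ntruth record keys: {sorted(record)}")
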