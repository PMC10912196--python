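"""The 14 latent phenotypes of a fitted growth curve."""

from phenoyield import GompertzParams, SigmoidFit, extract_features
from phenoyield.features import FEATURE_DESCRIPTIONS

fit = SigmoidFit(
    family="gompertz",
    params=GompertzParams(asymptote=0.9, displacement=8.0, rate=0.08),
    rss=0.0, r2_fit=1.0, converged=True, window=(14.0, 124.0),
)
features = extract_features(fit)

print("latent phenotypes for a Gompertz canopy-cover curve (A=0.9, b=8, c=0.08):\n")
for name, value in features.values.items():
    print(f"  {name:>4s}  {value:10.4f}   {FEATURE_DESCRIPTIONS[name]}")
print("\nDAP-type features are in days; value-type in trait units; rates in")
print("units/day (f13/f14 in units/day^2). f4 = f6 because a sigmoid grows")
print("fastest at its inflection, and f10 = f9 - f8 by definition.")
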