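# phenoyield

Growth-curve phenomics for field-plot breeding trials: from plot-level
UAV imagery (or trait time series) to latent growth phenotypes, ensemble
yield prediction, and breeding-oriented evaluation.

## The problem

Peanut yield forms underground, so it cannot be sensed directly from the
air. What *can* be measured, repeatedly and cheaply, is the above-ground
canopy: repeated UAV flights over a trial give each plot a time series of
canopy cover (CC), canopy height (CH, CH90), canopy volume
(CV = CC x CH) and excess-green index (ExG) versus days after planting
(DAP). This package implements the full analysis that turns those series
into plot-level yield predictions a breeding program can act on, plus a
synthetic-trial generator with known ground truth so every stage is
testable without field data.

## The method

1. **Image traits** (`phenoyield.traits`) — CLAHE illumination
   normalisation on the HSV value channel, canopy/soil segmentation by an
   HSV band threshold ((20, 0, 0)..(170, 255, 255), hue on the 0..180
   scale), then CC, ground-normalised CH/CH90, CV, CV90 and chromatic
   ExG = 2g − r − b per plot per flight.
2. **Growth curves** (`phenoyield.growth`) — per plot x trait, bounded
   nonlinear least squares fits of the logistic
   N(t) = K / (1 + ((K−N0)/N0) e^(−rt)) and Gompertz
   N(t) = A·exp(−b·e^(−ct)) families; rare missing dates imputed with
   per-date means; growth-rate curves are the analytic derivatives.
3. **Latent phenotypes** (`phenoyield.features`) — 14 descriptors of each
   fitted curve and its rate curve (inflection value and timing, maximum
   rate, half-maximum rate crossings, area under the rate curve, chord
   slopes, ...), pooled into a plots x features matrix named
   `{trait}_{family}_{f1..f14}`.
4. **Selection** (`phenoyield.selection`) — iterative variance-inflation
   pruning (VIF = 1/(1−R²) > 5 removed), then recursive feature
   elimination swept over feature limits 1..30, choosing the smallest
   limit at the peak mean test adjusted R².
5. **Prediction** (`phenoyield.models`) — random forest (depth 10, 400
   trees) and XGBoost (lr 0.06, depth 3, min child weight 5), validated by
   Monte-Carlo cross-validation (70/30 or variable splits), 10-fold CV and
   grid search; scores are adjusted R² = 1 − (1−R²)(n−1)/(n−p−1).
6. **Evaluation** (`phenoyield.evaluation`) — per-flight Pearson
   correlation series, estimated-vs-measured regressions (overall and per
   year), entry-mean repeatability R = σ²_g/(σ²_g + σ²_e/r) from a one-way
   random-genotype ANOVA, and 4x4 confusion matrices over genotype yield
   bins (Excellent = top 10%, Good = 11–25th pct, Mediocre = 26–50th,
   Poor = bottom half).

## Worked example

Latent phenotypes of a canopy-cover Gompertz curve (asymptote 0.9,
displacement 8, rate 0.08/day) over a 14–124 DAP season
(`python examples/04_latent_features.py`):

```
  f1      0.3311   value at inflection point
  f4     25.9930   DAP at inflection point
  f7      0.0265   maximum growth rate
  f8     14.0000   DAP at first half-maximum growth rate
  f9     44.2578   DAP at last half-maximum growth rate
 f10     30.2578   days between half-maximum growth rates
 f11      0.8335   area under growth-rate curve
```

This crop reaches its fastest canopy expansion at DAP 26 (gaining 2.65%
cover per day), sustains at least half that pace for 30 days, and accrues
0.83 cover in total over the season. `f10` and `f9` are vigor-duration
phenotypes that tend to track final yield.

The other scripts in `examples/` walk through simulation, tile
extraction, curve fitting, feature selection with cross-validated
prediction, and the breeding evaluation surfaces, each printing the
numbers it computes and what they mean.

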