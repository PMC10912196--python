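# Methods

## Growth models

Each plot x trait series versus days after planting (DAP, planting = day
0) is fitted with two three-parameter sigmoids:

* logistic `N(t) = K / (1 + A e^{-rt})`, `A = (K - N0)/N0`, reported as
  (asymptote K, initial value N0 = N(0), rate r /day);
* Gompertz `N(t) = A exp(-b e^{-ct})`, reported as (asymptote A,
  displacement b, rate c /day). Note `N(0) = A e^{-b}`, so the asymptote
  is the *upper* plateau, not the initial value.

Both are strictly increasing with a single inflection (logistic at
`t* = ln(A)/r`, value K/2; Gompertz at `t* = ln(b)/c`, value A/e); the
growth-rate curve is the analytic first derivative, never a numeric one.

**Fitting.** Bounded trust-region least squares (`scipy.optimize.
least_squares`, tolerances 1e-14). Initialisation: asymptote at 1.05x the
observed maximum, rate from the log-slope of the middle third of the
series, displacement matched to the first observation; four further
starts jitter these log-normally from a fixed seed, and the lowest-RSS
start wins. Bounds: asymptote in (0, 2x max observed] (capped at 1.0 for
canopy cover, which is a fraction), rates in (1e-4, 1], displacement in
(1e-3, 1e3]. Non-convergence is carried as `converged=False` and such
fits are excluded from the feature pool. Non-monotone late-season series
(e.g. ExG decline) are fitted as-is — the sigmoid is the model of record
— and `r2_fit` is carried so users can filter poor fits.

**Imputation.** A plot missing on a flight date receives the mean of the
observed plots for that trait on that date (same year), flagged
`imputed`. A date with no observations at all is an error.

## The 14 latent phenotypes

For each converged fit, with observed window [a, b]: f1 value at
inflection; f2/f3 DAP where the curve reaches 50%/80% of the inflection
*value* (the reading that keeps both features distinct and computable
from the curve alone); f4 = f6 inflection DAP; f5 value at the window end
(the asymptote may be unreachable within a season, so the window-limited
value is what the crop attained; switchable); f7 peak growth rate; f8/f9
first/last DAP at half-maximum growth rate; f10 = f9 - f8; f11 area under
the rate curve over [a, b], which equals N(b) - N(a) exactly; f12 =
f11/(b - a); f13/f14 chord slopes of the rate curve from the half-maximum
crossings to the peak (rising positive, falling negative).

Crossings are found by bracketing plus Brent's method on the analytic
curves (tolerance 1e-10 days) so both families share one code path; the
Lambert-W and grid-scan closed forms serve as independent oracles in the
tests. Crossings outside [a, b] are clipped to the window bound and
flagged; f13/f14 use the *unclipped* crossing times, which strictly
straddle the inflection, so the slopes stay finite even when an
early-rising trait (ExG) has its inflection before the first flight.

## Feature selection

VIF_j = 1/(1 - R²_j), with R²_j from regressing feature j on all others
plus an intercept (via statsmodels). Features are removed one at a time,
highest VIF first, until all survivors are <= 5; iterative removal avoids
discarding an entire mutually collinear group when one removal already
resolves it. Constant columns are removed first (undefined VIF).
Surviving correlated features are not pruned further.

RFE uses the learner's own importances (impurity for the forest, gain for
boosting). One elimination path (step 1, down to a single feature) is
computed per training split; prefixes of that ranking give the selected
set at every limit 1..30, which is equivalent to a separate step-1 RFE
per limit but ~30x cheaper (the equivalence is asserted against sklearn's
RFE in the tests). The chosen limit is the smallest whose mean test
adjusted R² is within 0.005 of the sweep's peak.

## Models and validation

Random forest: max depth 10, 400 trees. XGBoost: learning rate 0.06, max
depth 3, min child weight 5; the tree count is not part of that trio and
is set to 400 to pair with the small learning rate. Grid search
(forest: depth {5,10,15,unlimited} x trees {100,200,400,800}; boosting:
lr {0.03,0.06,0.1} x depth {3,5,7} x min child weight {1,3,5}) is scored
by 5-fold mean test adjusted R², ties broken toward fewer trees then
shallower depth.

MCCV draws a fresh random partition per iteration — train fraction 0.70,
or drawn uniformly from {0.5,...,0.9} in `variable` mode — and scores
both sides with adjusted R² using each set's own n and p = number of
features. Iterations with n_test <= p + 1 are skipped and logged. The
best iteration (highest test adjusted R², ties by train, then earliest)
supplies the fitted predictor for plot-level estimates; its predictions
cover all plots with train/test membership labels. 10-fold CV provides a
second protocol. All randomness flows from a single integer seed;
identical seeds reproduce identical partitions, scores and predictions.

## Evaluation

Per-flight Pearson r between each trait and yield (>= 3 plots, else
missing; zero-variance traits reported missing). OLS of estimated on
measured yield overall and per year — two seasons with very different
means form two clusters that anchor the pooled line, so the within-year
R² is the honest figure (a constructed fixture in the tests demonstrates
the inflation). Repeatability uses method-of-moments one-way ANOVA
(σ²_e = MS_within, σ²_g = (MS_between − MS_within)/r̄, r̄ = mean
replicates; negative σ²_g truncated to zero and flagged), chosen over
REML for determinism and light dependencies; R is reported on an
entry-mean basis. Genotype means are binned Excellent/Good/Mediocre/Poor
at cumulative 10/25/50% boundaries converted to counts with round-half-up
so the partition is exact for any genotype count; each prediction method
is binned by its own percentile ranks, making the confusion matrix a pure
ranking-agreement measure, with Excellent<->Poor counted separately as
catastrophic selection errors.

## Synthetic trials

The generator emulates the structure the analysis assumes: two seasons
(12 and 18 flights spanning 10-129 DAP), 73 genotypes x 3 replicates in
an RCBD (219 plots/year), genotype-level Gompertz parameters drawn
log-normally around trait medians (CC asymptote ~0.9, displacement ~8,
rate ~0.08/day; analogous medians for CH, CH90, ExG), plot-level
log-normal parameter noise (sigma 0.05), additive observation noise
(SD ~0.02 per trait), observations missing completely at random (1%),
CV/CV90 formed as products, and yield = intercept + a linear combination
of five latent features of the plot's own true CC/CH90/ExG curves +
genotype effect (SD 0.35) + Gaussian residual (SD 0.30), in tons/ha.
A helper calibrates the residual SD to any target feature-signal R².
The tile renderer draws an exact pixel count of a single canopy color
(hue 60, inside the segmentation band) over uniform soil (hue 15,
outside) with a flat DEM offset — enough to exercise the segmentation
and height chain, with no radiometric texture, shadows or weeds.

What passing tests therefore show: the mathematics (fitting, feature
extraction, selection, validation, evaluation) is correct and
recoverable on data with the assumed structure. What they do not show:
robustness to real-world imaging artifacts (brightness drift beyond
CLAHE, occlusion, georeferencing error) or to trait dynamics that are
not sigmoid.

## Problem sizes and known limitations

The test suite and the reproduction script run at desk scale: 200 MCCV
iterations (the full protocol of 1000 is a parameter), 2-4 fit restarts,
and RFE sweeps with a few Monte-Carlo splits; the default two-year trial
is 438 plots and ~6,500 trait rows.

Tree ensembles smooth and cannot extrapolate, which costs roughly 0.10-
0.15 of test R² on smooth additive signals at a few hundred plots: in the
end-to-end recovery experiment with a known feature-signal R² of 0.85,
the forest and the boosting model plateau near 0.70 on extracted features
— and near 0.74 even when trained on the generating features themselves —
while ordinary least squares reaches ~0.81/0.87. Mean MCCV test adjusted
R² should therefore be read as a conservative lower bound on the signal
these models exploit; the corresponding recovery test records this gap.
Genotype effects independent of the canopy signal are, by construction,
unlearnable from features and depress test R² further at small trial
sizes.
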