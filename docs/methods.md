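# Methods

`promirt` implements the analysis pipeline used to establish cross-language
comparability and population reference values for PROMIS-style item banks:
graded-response-model (GRM) calibration, hybrid ordinal-regression/IRT
differential-item-functioning (DIF) detection, Stocking-Lord equating,
DIF-impact assessment on T-scores, and stratified reference values. This
note records the models, the defaults and why they were chosen, the
numerical decisions, and the known limitations.

## The measurement model

Items are ordinal with K categories (K = 5 by default: never … always).
Samejima's graded response model describes the probability of responding in
category k or higher through boundary curves that are two-parameter
logistics sharing one slope per item:

    P*(X >= k | theta) = 1 / (1 + exp(-a (theta - b_{k-1}))),   k = 2..K

with discrimination a > 0 and strictly increasing thresholds
b_1 < … < b_{K-1} on the latent-trait scale. Category probabilities are
adjacent differences of the boundary curves. Slopes are in the
**pure-logistic metric**: no 1.7 scaling constant is applied anywhere.
Published PROMIS parameter tables use this convention; normal-ogive-scaled
parameters must be converted before use.

The latent trait theta is standard normal in the scaling population, and
scores are reported as T-scores, T = 50 + 10 theta, so the scaling
population has mean 50 and SD 10.

## Scoring

Person scores are expected-a-posteriori (EAP) estimates under a
standard-normal prior, computed by quadrature over 101 equally spaced nodes
on [-6, 6] with renormalised normal-density weights. The node count is
set by the sharpest posteriors the package must handle: a long bank with
slopes up to 4.5 has posterior SDs near 0.15, and the 0.12 node spacing
keeps the EAP integration error around 1e-10 (a 49-node grid, spacing
0.25, errs by up to 2e-3 there). Missing responses simply drop out of
the likelihood (response-pattern scoring); a person with no responses
receives the prior mean (T = 50) and is flagged. A 10x-refined
(1001-node) grid serves as the integration oracle in tests; the default
grid agrees with it to much better than 1e-3 on theta. EAP estimates are shrunken toward
the prior mean, so the T-score SD of a scored standard-normal population is
slightly below 10 (about 9.85-9.9 for a 29-item well-discriminating bank);
that is a property of EAP scoring, not an implementation artifact.

## Calibration

`fit_grm` is a Bock-Aitkin EM marginal-maximum-likelihood fitter under a
standard-normal latent prior. The E-step computes each person's posterior
over the quadrature nodes; the M-step maximises the expected complete-data
log-likelihood item by item with L-BFGS on (log a, b_1, log increments),
an order-preserving reparameterisation with an exact analytic gradient, so
threshold ordering cannot be violated mid-optimisation. Convergence is
declared when the largest absolute parameter change falls below `tol`
(default 1e-4, maximum 500 cycles; runs hitting the cycle limit are
flagged). The marginal log-likelihood is non-decreasing across cycles and
this is asserted in tests. Categories never observed for an item are
collapsed into the adjacent lower category before fitting and the recoding
map is returned; items with fewer than two observed categories raise a
calibration error naming the item. Calibration below n = 100 warns.

## DIF detection

For each item, three nested cumulative-logit (proportional-odds) models are
compared, with the EAP trait estimate as the conditioning variable (the
"hybrid" of logistic regression and IRT):

    model 1: item ~ theta
    model 2: item ~ theta + group          (uniform DIF, 1 df)
    model 3: item ~ theta + group + theta:group   (non-uniform DIF, 1 df)

Likelihood-ratio chi-squared statistics and p-values are reported for the
1-2, 2-3 and 1-3 comparisons. DIF magnitude is McFadden's pseudo-R-squared
(baseline: the intercept-only model) and **flagging is by magnitude**: an
item is flagged when the 1-3 R-squared change reaches the critical
threshold (default 0.02, configurable); the 1-2 vs 2-3 decomposition labels
the dominant DIF type. The chi-squared tests are reported but do not gate
flagging, because at reference-sample sizes in the tens of thousands even
negligible effects reach significance.

The proportional-odds likelihood is maximised by a damped Newton solver
with the exact gradient and Hessian (the cutpoint block is tridiagonal),
warm-started along the nested-model chain, with an L-BFGS fallback;
statsmodels' `OrderedModel` is the independent cross-check in the test
suite (agreement to ~1e-6 on the log-likelihood). Quasi-separation is
detected by runaway coefficients and flagged on the fit rather than raised.

**Purification.** The iterative scan first scores everyone from a single
pooled calibration (or supplied reference-metric parameters). After each
pass, flagged items get group-specific parameters: the focal group is
refit, linked to the base metric by Stocking-Lord on the unflagged anchor
items, and the flagged items' focal estimates (rescaled) replace the shared
ones when re-scoring the focal group. The scan stops when the flag set
repeats (cycle detection) or after 10 iterations. Items whose focal
calibration collapsed a category cannot serve as anchors or replacements
and are carried with shared parameters.

**Monte-Carlo null thresholds.** No-DIF data are simulated under the
fitted parameters at the observed group sizes, with group traits drawn
from normal distributions (by default standard normal; configurable, e.g.
to EAP-moment fits with shrinkage correction), scored, and tested. The
alpha-quantiles of the pooled null p-values and the (1 - alpha)-quantiles
of the null R-squared changes are reported. Under the null the p-value
thresholds sit at the nominal level (~0.01) and the R-squared quantiles are
of order 1e-3 or below — far under the 0.02 magnitude criterion, which is
why the conventional thresholds are retained.

**A power caveat for non-uniform DIF.** With the magnitude criterion, pure
slope-change DIF of realistic size produces interaction R-squared changes
of order 0.001-0.01 — usually below 0.02 — because a slope change with
fixed IRT thresholds also compresses the regression cutpoints, and when the
thresholds sit to one side of zero much of the signal is absorbed by the
group main effect (it masquerades as uniform DIF). Detection of the
non-uniform *type* is therefore reliable mainly for crossing DIF on items
whose thresholds straddle the population centre, or at a lowered
(configurable) magnitude threshold. Uniform DIF of the magnitudes studied
(threshold shifts around 0.4-0.8) is detected with high power. The test
suite verifies both facts.

## Equating and the hybrid parameter set

Stocking-Lord linking finds (A, B) minimising the weighted squared
difference between the anchor items' test characteristic curves,

    Q(A, B) = sum_q w_q [TCC_ref(theta_q) - TCC_focal->ref(theta_q; A, B)]^2,

where focal parameters transform as a -> a / A, b -> A b + B. The
criterion grid is 49 nodes on [-4, 4] with standard-normal weights. The
objective is optimised over (log A, B) — guaranteeing A > 0 — with three
starts (identity, expanded, contracted), Nelder-Mead polished by BFGS.
The transformation leaves category probabilities invariant under
theta -> A theta + B (verified to 1e-10), planted transforms are recovered
to better than 0.02, and equating an already-linked set returns (1, 0).
The hybrid parameter set is the reference set with the DIF items' rescaled
focal estimates substituted.

## Impact and reference values

Impact is quantified by scoring the same respondents twice — original
(reference) parameters vs the hybrid set — for the full bank and any
short-form subsets, reporting population means/SDs per approach and the
per-person |Delta T| distribution (mean, SD, range), plus a per-person
table for Delta-T-vs-T scatter plots. Subsets are scored with the same
response-pattern EAP machinery restricted to the subset. With two DIF
items in a 29-item bank the full-bank impact is diluted (well under one
T-point on average) while a 4-item form containing a DIF item shows
visibly larger differences; the largest individual differences occur at
the extremes of the score range, where the DIF items carry relatively more
information. Short-form memberships are configuration data, not code;
the bundled defaults are positional placeholders to be replaced with real
instrument definitions.

Reference values are unweighted means and SDs of T-scores for the total
sample, by gender, and by age bin (18-34, 35-44, 45-54, 55-64, 65-74, 75+;
lower bound inclusive, whole-year ages). Severity thresholds are the
reference mean plus 0.5, 1 and 2 SDs — (55, 60, 70) on the standard
metric, rounded to integers by default. Classification treats the mild
cutoff as part of the normal range (normal <= 55 < mild <= 60 < moderate
<= 70 < severe); by default T-scores are rounded to integers first,
emulating reporting against integer cutoff ranges, with the unrounded
variant available. On Normal(50, 10) scores the unrounded split matches
the closed-form 69.1 / 15.0 / 13.6 / 2.3 percentages.

## The synthetic-data generator

`simulate_two_group_study` emulates the two-sample design the pipeline
targets: a large reference sample (default n = 14,836) and a smaller focal
sample (default n = 1002) answering a 29-item, 5-category bank, both with
standard-normal traits by default (the focal mean/SD on the reference
metric is a choice, not an inference — no external information pins it
down). Slopes are drawn uniformly on 1.0-4.5 and thresholds start in
[-1.2, 0.6] rising by 0.4-1.1 steps, bracketing published item-bank
magnitudes. DIF is planted per item as a uniform threshold shift and/or a
slope factor; covariates (gender 47.9/52.1, age-bin proportions
25/15/17/22/19/2 percent) mirror the study's sample compositions, with an
optional per-bin trait shift for testing stratified norms. Responses are
complete by default (the emulated survey disallowed skipping); an optional
missing-completely-at-random rate is available. One master seed spawns
deterministic sub-streams per stage, so outputs are byte-identical across
runs.

What the generator does **not** emulate: real item content, local
dependence, careless or "suspicious" response patterns, non-normal trait
distributions, differential nonresponse, and DIF shapes other than
shift/slope-factor (in particular, category-specific threshold distortion).
Passing tests therefore demonstrate the correctness of the machinery under
the model's own assumptions, not robustness to their violation.

## Problem sizes used in the test suite

The acceptance-style checks run at: n = 10,000 for the T-metric
convention; n = 2000 for 29-item calibration recovery; 500 no-DIF
replications at the scaled two-group design (5000 vs 1002) for type-I
error and null thresholds; 50 replications for uniform-DIF power; and
n = 100,000 for the classification oracle. These sizes give Monte-Carlo
error comfortably inside the asserted tolerances.

## Known limitations

- The EM fitter assumes a standard-normal latent prior; no latent-density
  estimation.
- Only binary-group DIF is implemented (no covariate DIF, no
  Mantel-Haenszel or IRT-LR alternatives); magnitude is McFadden's
  R-squared only.
- Linking supports Stocking-Lord only (no Haebara or moment methods).
- Sum-score-to-T conversion tables are out of scope; all scoring is
  response-pattern EAP.
- The non-uniform DIF power caveat above.
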