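# Methods

## Problem and scope

`adscore` implements a structural-neuroimaging phenotyping pipeline for
Alzheimer's disease (AD). From a fixed table of 155 FreeSurfer-style
morphometric features per scan (68 Desikan–Killiany cortical thickness
values, 68 cortical volumes, the brainstem volume and 9 subcortical volumes
per hemisphere), it derives a probability-like **AD score** with an
uncertainty, and then runs the downstream statistics that make such a score
clinically interpretable: Bayesian group comparisons with Region of
Practical Equivalence (ROPE) verdicts, piecewise (breakpoint) regression of
cognition on the score, and ELPD-based model comparison.

The clinical cohorts this kind of analysis is normally run on (research
case-control panels, memory-clinic registries, population biobanks) are
access-controlled, so the package ships a first-class synthetic cohort
generator that reproduces the statistical structure the method assumes.
Everything downstream of FreeSurfer feature extraction is in scope;
segmentation itself, scanner harmonization and real-cohort reproduction are
not.

## Confound residualization

One ordinary-least-squares regression per feature, fitted on the training
split only: thickness ~ 1 + age; volume ~ 1 + age + eTIV + sex (sex coded
0/1; intercept always included so training residuals are exactly mean
zero). Residuals are standardized by the training residual mean and SD
(denominator N−1). Applying the fitted model to any other table is a pure
function of the stored coefficients — validation, external and screening
tables never update the statistics, which is the no-leakage guarantee the
pipeline manifest attests. Features whose training residual SD falls below
1e−12 raise an error rather than silently producing infinities. A
rank-deficient design (e.g. a single-sex training set) is also a hard
error naming the collinear confound.

An open choice: residuals could be standardized by the raw post-residual SD
or the residual SD; we use the residual SD so that the training table maps
exactly to mean 0 / SD 1.

## The classifier

A fully-connected network 155 → 128 → 128 → 1 with tanh hidden activations,
sigmoid output, and dropout rate 0.8 after each hidden activation; 36,609
trainable parameters. Training: Adam (learning rate 0.001, weight decay
0.0001), binary cross-entropy, 100 epochs, mini-batches of 64 with seeded
shuffling; the checkpoint with the smallest validation loss is selected
(earliest epoch on ties). Validation loss is computed with dropout
disabled. An optional balanced-training flag subsamples the majority class
with a seed.

The network is implemented directly in NumPy (forward pass, backprop, Adam,
dropout): at this parameter count CPU training takes seconds, and the
implementation keeps every arithmetic step seedable and testable against
hand-computed oracles. Conventions fixed for bit-reproducibility: inverted
dropout (kept units scaled by 1/keep during stochastic passes, so the
dropout-free pass needs no rescaling); uniform fan-in weight
initialization U(±1/√fan_in); uncertainty SD with denominator n−1.

**Monte-Carlo dropout.** At prediction time dropout stays active; each of
N=50 forward passes applies fresh Bernoulli(keep) masks and constitutes an
approximate draw from the posterior over weights. The mean over passes is
the AD score, the SD is the model uncertainty (bounded by 0.5 for values in
[0, 1]). The construction is verified against an exhaustive enumeration of
all dropout masks on a 2-hidden-unit toy network: with 4 possible masks the
exact mixture mean/SD are computable in closed form, and 10⁵ stochastic
passes must agree within 3 Monte-Carlo standard errors.

## Evaluation

Classification metrics at a cutoff of 0.5 (a score exactly at the cutoff is
negative); accuracy, sensitivity, specificity, PPV, NPV from the 2×2 table,
with zero-denominator ratios reported as missing, never imputed. AUC is the
rank-based (Mann–Whitney) probability with tie correction; the test suite
cross-checks it against an exhaustive pairwise oracle. A five-predictor
linear-probability baseline (left/right hippocampal volume, age, eTIV, sex;
OLS on the raw features) anchors how much the 155-feature network adds:
when atrophy is planted across ~20 regions the network's AUC exceeds the
baseline's, and when only the hippocampi carry signal the two converge.

Uncertainty diagnostics: on a trained model, misclassified subjects should
carry higher mean uncertainty than correctly classified ones, and scores
near 0.5 should carry more uncertainty than extreme scores (an inverted-U
over score bins). Both are computed as boolean flags in the uncertainty
report and exercised end to end.

## Bayesian phenotype statistics

Group comparisons regress a phenotype on the score-positive indicator with
age as a covariate, under one of five likelihoods: Gaussian, skew-Gaussian
(chosen automatically when |sample skewness| > 0.5, the documented
threshold), Bernoulli-logit for binary outcomes, ordinal-probit and
adjacent-categories for small ordered scales (intercept absorbed into
ordered cutpoints: first cutpoint free, increments log-parameterized).
Priors: Cauchy(0, 2.5) on slopes of standardized predictors, Cauchy(0, 10)
on the intercept, half-Cauchy(0, 5) on residual scales, Normal(0, 5) on the
skew shape and first cutpoint. These scales are package defaults,
configurable through `PriorSpec`.

**Sampling.** Affine-invariant ensemble MCMC (emcee) with 32 walkers,
differential-evolution moves, 4000 steps with the first 2000 discarded and
thinning by 2; walkers are initialized by small jitter around a
maximum-likelihood point. Walkers are treated as chains for split-R-hat and
ESS (ArviZ); a fit whose worst R-hat exceeds 1.01 is rerun with a doubled
chain (at most twice) and then fails loudly. This sampler was chosen over
gradient-based NUTS-style samplers because the posteriors here are
low-dimensional (≤ 8 parameters) and the ensemble sampler needs no gradient
of the ordinal likelihoods; mixing was verified empirically (ESS in the
thousands for all reported parameters).

**ROPE verdicts.** The ROPE is ±0.1 of the control-group SD for continuous
outcomes (±0.1 on the log-odds/probit scale for binary/ordinal ones).
Verdict rule on the central 95% credible interval: *strong evidence* if the
CI lies entirely outside the ROPE; *some evidence* if the posterior mean is
outside but the CI overlaps; *accept null* if the CI lies entirely inside;
otherwise *indeterminate*. The rule is a pure function tested against a
brute-force geometric oracle over randomized interval topologies. 75%
intervals are reported alongside but play no role in verdicts.

**Piecewise regression.** Cognition (z-scored to control-group units) is
regressed on the AD score with the continuous hinge
y = a + b₁·min(x, bp) + b₂·(x − bp)₊ + ε, in three modes: breakpoint fixed
at 0.5, breakpoint free in (0.25, 0.75) with a uniform prior, or no
breakpoint. The slope difference is formed draw-by-draw. Fixed mode
requires at least 10 points on each side of the breakpoint. Models are
compared by ELPD using PSIS-LOO on stored pointwise log-likelihoods
(thinned to ~1000 draws); if any model's Pareto-k diagnostic exceeds 0.7
all models are re-scored with WAIC, with a warning, so differences stay on
one scale. Pairwise differences are reported with the paired SE
(√(n·var) of pointwise differences), best model at 0 by convention.

## Synthetic cohorts

The generator draws, per subject: age ~ U(55, 90); sex ~ Bernoulli(0.5);
eTIV ~ Normal with sex-dependent mean (1.55e6/1.35e6 mm³, SD 1.3e5/1.1e5) so
the sex+eTIV design is non-degenerate; diagnosis with AD fraction 331/736
by default (the case-control mix of a 736-subject research panel); a latent
disease severity U(0.3, 1) for AD subjects (0 for controls). Each feature
is baseline + linear confound effects (age on thickness; age, eTIV, sex on
volumes — mirroring the residualization design) + planted standardized
atrophy × severity (hippocampus −1.5 SD, amygdala −1.0, entorhinal and
other medial-temporal/parietal thickness −0.5 to −1.2 by default) +
Gaussian noise. Baseline regional means are fixed plausible values; their
absolute scale is irrelevant after z-scoring. One global seed spawns
independent substreams per stage, and the same seed + spec is byte-identical.

Cognition is generated against a *supplied* score (the generator never sees
the classifier): score = control_mean + slope_below·min(x, bp) +
slope_above·(x − bp)₊ + noise, slope_below 0 by default — no association in
the score-negative range. Risk factors get group shifts in the positive
cohort: systolic +2.29 mmHg, diastolic +1.12 mmHg, pack-years +2.98,
smoking +0.25 log-odds, self-rated health +0.14 probit, and deliberately
null sleep duration and hip circumference.

What the generator does **not** emulate: site/scanner effects, non-linear
confound effects, longitudinal change, label noise, non-AD degenerative
subgroups (a generic "other" level exists in the schema only), and
real-data feature covariance (features are conditionally independent given
confounds and severity). Passing tests therefore demonstrate the
correctness and statistical calibration of the machinery under its own
assumptions, not real-world classification performance.

The severity distribution within cases is a modelling convenience (no
published value exists); planted-effect recovery tests pin
`severity_range=(1, 1)` so a planted −1 SD shift is exactly the expected
standardized group difference.

## Problem sizes and numerical choices

Default test and demonstration scales, chosen to make every statistical
check well-powered at desk scale: cohorts of 736 (classifier checks) and
2000 (end-to-end demo and piecewise recovery), 5000–20000 for generator
moment checks, 10 seeds for replicate-based properties. The end-to-end
demonstration trains in a few seconds and completes, including all MCMC,
in about a minute on one CPU.

Tie-breaks and edge cases: score exactly at the cutoff → negative class;
equal validation losses → earliest epoch; empty external table → empty
outputs with a warning; single-class labels → AUC refuses; constant
covariate → error. The end-to-end "accept the null" check treats both
`accept_null` and `indeterminate` as not-flagged: with a ROPE of 0.1
control SD, a strict accept-null verdict requires the CI half-width to be
smaller than the ROPE, i.e. cohorts of roughly 10⁴ — at the demo scale the
attainable guarantee is that null phenotypes are never *flagged*, and that
is what the tests assert.

## Known limitations

* Exact weight-level replication of any particular published classifier is
  impossible (batch size, initialization and split membership of such
  models are unreported); the package reproduces the architecture,
  training recipe and all self-contained arithmetic identities instead.
* The ensemble sampler's walkers are interacting, so split-R-hat across
  walkers is a conservative but noisy convergence check; the adaptive
  chain-doubling keeps it below 1.01 at some compute cost.
* Linear-probability baseline scores are not clipped to [0, 1]; they are
  only thresholded and ranked.
* FreeSurfer output directories are not parsed; the canonical CSV schema
  is the documented extension point.
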