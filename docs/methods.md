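# Methods

`fearfit` implements a complete analysis pipeline for differential
fear-conditioning studies that measure fear-potentiated startle (FPS):
trial-level QC, NA-adjusted conditioning metrics, symptom-based cohort
assembly, a four-variant Rescorla–Wagner (RW) model family fit
hierarchically with leave-one-out model comparison, and prospective risk
models linking pre-trauma fear learning to post-trauma outcomes.  Because
cohort data of this kind are rarely shareable, the package ships a
synthetic-cohort generator with known ground truth; every claim the test
suite makes is a claim about recovery of quantities that the generator
planted.

## Task and observation model

A session has two phases.  Acquisition presents 8 CS+ trials (the threat
cue, reinforced by an aversive air puff at 75% contingency, i.e. exactly 6
of 8), 8 CS− trials (the safety cue, never reinforced), and 8 noise-alone
(NA) startle probes that measure baseline.  Extinction presents 16 of each
with no US at all.  Each phase opens with 6 stabilization pulses that
settle the startle reflex; they are simulated but excluded from all
modeling and metrics.  Trial order is a seed-controlled constrained shuffle
(no more than two consecutive trials of a type) — the original task's exact
pseudo-random order is not public, so the shuffle is a stand-in, not a
reconstruction.

US expectation follows the delta rule `E ← (1 − λ)E + λ·US` with
expectations on [0, 1].  Two parallel processes are tracked: a
*discrimination* expectation per stimulus, updated only for the cue shown,
and a single shared *generalization* expectation updated on every CS trial.
The four model variants cross (one vs. two acquisition learning rates —
separate rates for reinforced and non-reinforced trials) with (presence vs.
absence of the generalization process): M1 = 1 rate/discrimination-only …
M4 = 2 rates + generalization.  A third, separate rate governs extinction
updates in all variants.

Observed startle is Gaussian around a linear function of the expectations
on a habituating baseline:

    startle(t) ~ Normal(β0_j + β_trial·t + β_disc·E_disc + β_gen·E_gen, σ)

with subject-level intercepts β0_j and learning rates, and group-level
slopes and noise SD.

Choices the source analyses leave open, fixed here and configurable:

* initial expectations start at 0.5 (participants are told one cue
  predicts the puff, but not the contingency strength);
* the trial index `t` is 0-based and runs continuously over the modeled
  session, NA trials included, not resetting at the phase break;
* expectations carry across the acquisition→extinction break (the phases
  are fitted jointly);
* NA trials enter the likelihood with zero expectation terms — without
  them the baseline and habituation terms would be confounded with the
  expectation weights;
* the generalization update uses the same outcome-dependent learning-rate
  selection as the discrimination update.

## Preprocessing

Eyeblink magnitudes are accepted at trial level.  A response must peak
within the closed window [0, 100] ms of pulse onset to count; later peaks
are treated as artifact ("within 100 ms" is read inclusively; the window is
configurable).  Artifact trials are replaced by the mean of the nearest
preceding and nearest subsequent clean trial of the same stimulus type in
the same phase, single-sided at edges; runs of artifacts all resolve to
clean donors, which makes imputation idempotent and keeps imputed values
inside the clean range.  A subject with no clean trial left in some
(phase × stimulus) cell is unusable and routed to exclusion.

Metrics follow the standard FPS analysis: two-trial block means per
stimulus, NA-block subtraction, cue discrimination index (last-half
acquisition CS+ minus CS− adjusted means), and % conditioned fear
(100 × adjusted extinction CS+ block / subject's maximum adjusted CS+
across acquisition blocks), averaged into Early/Mid1/Mid2/Late 4-trial
blocks.  The percentage is deliberately not clipped: negative and >100
values are what the formula produces.  Subjects whose last-half adjusted
CS+ mean is not strictly positive are non-potentiators and excluded.  A raw
difference-score alternative to the percentage metric is available as a
toggle.

Cohort assembly applies ordered gates — technical loss/missing data,
non-potentiation, loss to follow-up, pre-deployment symptom positivity,
then post-deployment labels with comorbid cases split off — and asserts
that counts partition N at every gate.  Partial-PTSD status requires ≥1 B,
≥2 C, ≥2 D cluster symptoms (the pipeline accepts pre-counted clusters;
item-level filtering is upstream of its scope); anxiety and depression use
strict cutoffs (BAI > 15, BDI-2 > 19).  The deployment-stress composite
centers each DRRI subscale on the cohort mean and averages them; centering
means are computed once on the post-deployment-assessed sample before any
symptom-based exclusion so the composite does not depend on downstream
filtering.

## Inference

Learning rates are sampled on the logit scale with Normal population
distributions (non-centered in spirit: subject values are drawn around
estimated population location/scale).  Default priors: population logit-LR
mean Normal(0, 1.5); subject SD half-Normal(1); intercept population mean
Normal(data mean, 2·SD(y)); coefficient priors effectively flat in the
conjugate group step; noise SD via its scaled-inverse-χ² conditional.  All
scales are overridable through `PriorConfig`.

The default fitting path has two stages.  (1) A deterministic alternation:
per-subject penalized maximum likelihood (L-BFGS over logit rates and
intercept) with group coefficients profiled out by within-subject centering
and population hyperparameters re-estimated between sweeps.  (2) A seeded
Gibbs-within-Metropolis sampler started at that optimum: per-subject
Metropolis blocks (random-walk proposals shaped by per-subject Laplace
covariances, mixed 50/50 with independence proposals from the Laplace
approximation; scales adapt during burn-in), an exact conditional draw for
(β_trial, β_disc, β_gen, σ), and conjugate/Metropolis hyperparameter
updates.  Defaults: 800 burn-in sweeps, thinning 4, 400 retained draws.
Sampling the joint posterior rather than plugging point estimates of the
expectations into the group regression is essential: plug-in estimates
produce a visible errors-in-regressors attenuation of β_disc with a
compensating inflation of β_gen.

An ensemble-sampler path (`method="mcmc"`, emcee over the full joint
posterior, initialized at the deterministic solution) serves as a reference
implementation; it is practical for small cohorts and is cross-checked
against the default path in the test suite.

Per-trial pointwise log-likelihood matrices feed PSIS-smoothed
leave-one-out cross-validation (arviz), reported as elpd/LOOIC with SEs,
pairwise elpd differences with difference-SEs, and Pareto-k tallies.
Model comparison refuses fits on non-identical observation sets.  An exact
leave-one-observation-out routine refits the model once per trial for tiny
cohorts; a left-out trial keeps driving the expectation updates (it is a
predictor for later trials) — only its likelihood term is dropped.

Known limitation: with 60 subjects at the default noise level the
β_disc/β_gen split is weakly identified (their regressors are strongly
collinear; the CS− trials carry most of the contrast).  The posterior for
that contrast is prior-sensitive, and the frequentist coverage of its 90%
intervals in the recovery study sits at the edge of the documented 80%
bound rather than at the nominal 90%.  Chains agree from different
starting points (including the truth), so this is a finite-sample
identifiability property, not a sampling defect.

## Risk models

The status model is a maximum-likelihood logistic regression of
post-deployment group (healthy reference vs. PTSD) on the z-scored
discrimination index plus pre-deployment severity, deployment stress and
trauma-history covariates (covariates other than the index enter on their
raw scale).  The stepwise sequence used in this literature is available:
drop the trauma-history count if uninformative, test the discrimination ×
deployment-stress interaction, retain the final model.  Complete separation
triggers a flagged ridge-penalized fallback.  The severity model is a
single linear model of post-deployment CAPS on the three posterior-mean
learning rates simultaneously, with optional covariate adjustment, partial
η² effect sizes, and a partial-residual table for the extinction-rate
effect.  p-values are reported unadjusted.

## Synthetic cohorts

Per subject the generator draws learning rates as logit-normals (means
0.25 / 0.12 / 0.15 for US+, US− and extinction; logit SD 0.5 — acquisition
from reinforced trials is faster than from non-reinforced ones, and
extinction is slow), an intercept Normal(100, 20) in arbitrary startle
units, and uses group-level β_trial = −0.6/trial, β_disc = 150,
β_gen = 100, σ = 30.  These values put adjusted late-acquisition CS+
responses near 200 and CS− near 100, matching the magnitudes typical of
published FPS tables.

Group structure: labels (healthy / PTSD / comorbid / depression-anxiety
alone) are drawn at configurable prevalence (default 5%, matching a
~32-in-643 cohort).  Two effects can be planted: (1) PTSD-group subjects
have their stimulus-specific expectation shrunk toward the shared one by a
multiplier (default 0.4) inside the startle generator — physiological
overgeneralization with intact expectancy discrimination, since keypresses
are generated from the un-attenuated expectations; (2) post-deployment
CAPS depends on the subject's extinction rate with slope −40 CAPS units
per unit learning rate (noise SD 8), sized so the severity signal is
detectable at the cohort sizes the simulation studies use while remaining
a small fraction of CAPS variance.  Questionnaire panels are truncated to
instrument ranges and made consistent with the planted labels; only
post-deployment CAPS carries a model-parameter dependence.

Planted non-learners (default 10%) have no cue-driven startle at all, so
their NA-adjusted CS+ response is symmetric noise around zero and the
potentiation gate removes about half of them; the gate essentially never
removes true learners.  Artifacts are planted at 2.1% of modeled trials
with a large positive corruption so imputation is consequential.
Expectancy keypresses (+1/0/−1) threshold a noisy latent judgment at
(0.40, 0.75), calibrated so typical learners average about +0.6 (CS+) and
−0.75 (CS−) late in acquisition.

What the generator does not emulate: raw EMG waveforms, trial-timing/ITI
structure, session-level non-stationarities other than linear habituation,
heavy-tailed startle noise, item-level questionnaire structure, and any
dependence of drop-out on task performance.  Passing tests therefore show
method correctness and recovery under the stated generative assumptions,
not robustness to real-data violations of them.

## Problem sizes and numerics

The simulation studies use sizes chosen to make their statistical targets
meaningful while staying desk-scale: parameter recovery on 10 cohorts of
60 subjects (full design, default noise); model selection on 6 cohorts of
40 subjects with extinction shortened to 8 trials per type; exact-vs-PSIS
LOO on a 5-subject, 20-trial design (4/4/6 acquisition + 2 per type
extinction); the two-stage pipeline on cohorts of 300 at 10% prevalence,
elevated relative to 5% for statistical power at these cohort sizes, with
point-estimate fits.  Numerical details: logit parameters are bounded to
[−7, 7] in optimization and ±9 in sampling; Hessians are made positive
definite by eigenvalue flooring; the within-subject centering in the group
step avoids the slow intercept↔coefficient alternation that the shared
generalization/trend regressors would otherwise cause; analytic identities
(geometric extinction decay, model nesting) are asserted at float-rounding
tolerance (≤1e−12).
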