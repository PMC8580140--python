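# Methods

This package re-implements, as a tested pipeline on synthetic data, the
full analysis chain used to ask whether the age-related rise of
ipsilateral motor-cortex activation during right-hand finger responses
(the HAROLD pattern — hemispheric asymmetry reduction in older adults)
is *compensatory*: whether the extra ipsilateral activity helps
behaviour or carries task information beyond what the contralateral
hemisphere already provides.

## The synthetic cohort generator

The generator defines the study conditions every downstream stage is
tested under.  It emulates two event-related designs:

* **sensorimotor**: 120 bimodal audio/visual trials plus 8 rare unimodal
  catch trials, SOAs between 2 and 26 s (a 2 s floor plus a geometric
  number of 0.5 s null slots, clipped at 26 s), TR 1.97 s, 261 scans.
  The published SOA-generating algorithm is not public; this generator
  reproduces the stated range and null-trial sparsity without claiming
  to match it.
* **free selection**: 240 trials over four right-hand fingers — 120
  specified (30 per finger) and 120 free-choice among three cued fingers
  (uniform choice, optional repetition-bias knob, off by default) — in
  blocks of 20 separated by 4.2 s or 6.2 s gaps, 2 s within-block SOA,
  296 scans.  Condition types never repeat four or more times in a row.

**Amplitude laws.** Per-participant mean condition amplitudes follow
quadratic lifespan laws (units: peak percent signal change per event on
data scaled to a grand mean of 100; age pivot 50 y):
contralateral `1.8 − 0.012·(age−50)` (declining), ipsilateral
`0.55 + 0.011·(age−50) − 0.00012·(age−50)²` (rising, flattening in old
age), plus subject-level Gaussian deviations (SD 0.25 / 0.15).  These
magnitudes put single-voxel contrast-to-noise in the range typical of
primary sensorimotor cortex at 3 T.

**Information structure — what the scenarios mean.**  All voxels of both
hemispheres load uniformly on a shared latent `u(t) = s(t) + η(t)`,
where `s` is the HRF-convolved event train and `η` ROI-shared
"physiological" noise (AR(1), SD 0.5).  Unique, decodable information
enters as heterogeneous zero-mean voxel loadings on the clean `s(t)`:

* `haroldnull` — contralateral voxels carry a unique pattern (loading SD
  0.35); ipsilateral voxels carry none.  The ipsilateral univariate mean
  rises with age (through the uniform `u` channel), but because the
  contralateral ROI already measures `u` to near-saturation, adding
  ipsilateral voxels cannot improve decoding at any age.  This is the
  dissociation at the heart of the study: univariate HAROLD without
  multivariate compensation.
* `compensation` — ipsilateral voxels additionally carry a unique
  pattern whose magnitude grows with age (`0.25 + 0.005·(age−50)`), and
  reaction-time variability is negatively coupled to the age-residual of
  ipsilateral amplitude, with the coupling growing linearly with
  standardized age and set to half the RT-variability age slope.
* `dedifferentiation` — like `haroldnull` with the contralateral pattern
  magnitude declining with age.

**Noise.** Per-voxel AR(1) noise (coefficient 0.3, innovation SD 0.95),
ROI-shared AR(1) noise, and slow drift built from cosines below the
1/128 Hz cutoff (so the high-pass filter is genuinely exercised).  RTs
are Gaussian per participant with mean `320 + 1.3·(age−50) +
0.012·(age−50)²` ms and SD `65 + 0.55·(age−50)` ms plus subject-level
scatter, sampled over 50 trials.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: head motion and other imaging artifacts,
slice-timing and spatial normalization errors, spatially structured
(smooth) noise within an ROI, non-Gaussian RT distributions,
multi-run sessions, and any vascular age confound.  Synthetic voxels
are exchangeable within a hemisphere; real ROI voxels are ranked by a
group statistic.

## GLM estimation

Canonical double-gamma HRF (delays 6/16 s, dispersions 1/1, ratio 6,
32 s kernel; sampled via nilearn and rescaled to unit peak so that
amplitudes read as peak percent signal change), optionally with temporal
and dispersion derivatives (three regressors per condition; the
free-selection design uses the canonical only, since blocked trials
prevent stable derivative estimation).  Discrete-cosine high-pass with
`floor(2·run_seconds/128) + 1` columns including the constant.  Data are
grand-mean scaled to 100 (synthetic sessions are generated on that scale
already, so the scaling step is an exercised identity there).

Serial correlation is modelled as white plus AR(1)-induced covariance,
`V = h_w·I + h_a·K(φ)`, fitted by restricted maximum likelihood pooled
over the analyzed voxels (per-voxel variances normalized out): Fisher
scoring on the two variance components (tolerance 1e-6, 64-iteration
cap) inside a bounded 1-D profile search over φ ∈ (−0.9, 0.9).  Both
model and data are whitened by `V^{−1/2}` before OLS.  The *reported*
AR coefficient is the lag-1 autocorrelation of the fitted covariance:
for genuinely autocorrelated noise it equals φ, while for white noise —
where the raw φ sits on a flat likelihood ridge and is unidentified —
it correctly goes to zero.

Trial-wise amplitudes for MVPA use the least-squares-separate (LSS)
approach: one model per trial with a target-trial regressor, a single
regressor aggregating all other trials, and the high-pass set (an
intercept is retained even when filtering is disabled).

## ROI definition

The contralateral ROI is the 70 top-statistic voxels grown by
26-connectivity from the suprathreshold peak nearest the hand-knob
landmark on a 10 mm-FWHM-smoothed map; smoothing is used for definition
only and all analyses read unsmoothed data.  Mirroring reverses the sign
of the world x coordinate.  The source study reports the combined ROI
once as 138 voxels and once as "from 140 to 70"; this implementation
fixes 70 + 70 = 140.  Because selection uses the age-averaged map, ROI
definition is unbiased with respect to age — verified by a null
simulation of the false-positive rate of the downstream age test.

## Multivariate Bayes decoding

The decoding model reverses the GLM mapping: the target is a
one-dimensional contrast over task regressors (here, action versus
baseline), and everything in the contrast's null space — the remaining
task regressors, high-pass set, nuisance — is projected out of both
target and voxel data after whitening.  The model is Bayesian linear
regression `t = Xw + e` with a *sparse* spatial prior (patterns are
individual voxels) whose variances are grouped into nested subsets.

The greedy search orders voxels by the magnitude of a ridge-regularized
joint projection of the target onto the voxels (so a voxel masked by a
correlated neighbour still ranks by its unique contribution), doubles
the active subset each step (1, 2, 4, …; each step's new voxels share
one pattern variance), re-estimates all hyperparameters at each step by
maximizing the log marginal likelihood (L-BFGS on log-variances through
the Woodbury identity; noise-variance floor 1e-6 of target variance),
and stops when the free energy no longer improves, with an 8-step cap.
The reported free energy F is this maximized (empirical-Bayes) log
marginal likelihood; with fixed hyperparameters and a single all-voxel
subset it reduces exactly to the Bayesian-ridge log evidence, which is
the oracle the tests check against.  Note the literature sometimes calls
this quantity an "upper bound" on the log evidence; the conventional
reading — and what is implemented — is the variational *lower* bound
that hyperparameter optimization maximizes.

Decoder reliability uses phase-shuffled targets (Fourier amplitudes
preserved, phases randomized with conjugate symmetry): a participant
enters the boost analysis only if their bilateral-model F beats the mean
of the shuffled-reference fits by more than 3 nats (20 shuffled fits per
participant by default; the one-tailed group t-test against a mean
margin of 3 is also reported, since the source description is ambiguous
about which rule drove exclusions — both are computed).

## The boost comparison

Δ = F(bilateral) − F(contralateral-only), categorized at ±3 nats
(a log-evidence difference of 3 corresponds to a Bayes factor of
e³ ≈ 20.09 > 20): boost above +3, reduction below −3, ambiguous in the
closed interval.  Voxel-count-matched controls: *halving* draws a seeded
uniform 35+35 subsample of the bilateral set (and re-runs the
phase-shuffling reliability step, since the bilateral model changed);
*doubling* extends the contralateral set with the next-ranked candidate
voxels (the synthetic generator simulates twice the ROI size per
hemisphere so ranked extension voxels exist).

## MVPA

One-vs-one linear SVM (C = 1), per-voxel [−1, 1] normalization across
trials, four random (seeded) cross-validation folds, balanced accuracy
(mean per-class recall, averaged over folds); stratified refolding is
applied only when a random draw leaves a class out of a training fold.
Specified and choice trials are pooled by executed finger.  Because
folds come from one run, serial correlation makes training and test
patterns non-independent and can bias absolute accuracy upward; only
between-ROI differences (the accuracy boost, bilateral −
contralateral) are interpreted.  Participants with bilateral accuracy
≤ 25% (four-class chance) are excluded from the boost analysis.

## Lifespan statistics

Continuous outcomes: Huber M-estimation (tuning constant 1.345, the
conventional 95%-efficiency choice) on standardized linear and quadratic
age terms (z-scored age; z² re-standardized).  Age effects are tested
hierarchically: a joint two-tailed robust Wald F of the age block first
(using the RLM asymptotic covariance of the M-estimator), per-term tests
only if the block is significant at α = 0.05.  R² is reported as the
percent of *weighted* variance uniquely explained by the block — which,
as the source also cautions, can run higher than OLS R².

Compensation models: RT summary ~ ipsilateral + age(lin+quad) +
ipsilateral×age(lin+quad), with the interaction block as the
compensation readout; the partial-compensation variant replaces age
with contralateral activation (ipsilateral×contralateral interaction).

Categorical boost outcomes: proportional-odds ordinal regression on
reduction < ambiguous < boost with standardized linear age (quadratic
optionally added), odds ratios per SD of age; binary logistic fallback
(flagged) when only two categories occur.  Reported models use the
linear term only, mirroring the source's treatment of categorical data.

Bayes factors: for continuous effects, the Zellner–Siow
mixture-of-variances (JZS) prior on standardized effects with scale
√2/4, each model compared with the intercept-only model via 1-D
numerical integration over g, and BF01 formed as the reduced/full
evidence ratio (the default comparison drops the interaction block
only).  For the categorical boost outcome, Bayesian logistic regression
of the boost indicator on standardized age under Student-t priors (7 df,
mean 0, scale 10 intercept / 1 slope), sampled with an affine-invariant
ensemble sampler (16 walkers, 700 steps, 200 burn-in, seeded; acceptance
fraction and sample count serve as the convergence diagnostic).  The
directional BF01 against "age effect > 0" combines the Savage–Dickey
density ratio at slope = 0 with the prior/posterior mass ratio on
slope > 0, both evaluated from a Gaussian approximation to the sampled
slope marginal — this keeps the tail quantities stable when the slope
sits far from zero, where kernel-density and Monte-Carlo mass estimates
break down.  BF01 bands follow Jeffreys: 1–3 anecdotal, 3–10
substantial, >10 strong evidence for the null.

## Numerical and design choices

* Boundary semantics are strict everywhere they matter: Δ = 3 is
  ambiguous, a reliability margin of exactly 3 is excluded, 25.0%
  accuracy is excluded, BF01 = 1 is labelled "anecdotal (boundary)".
* The orchestrator reports TSV tables plus JSON summaries with a
  manifest of every seed, threshold and stage timing; figures are not
  part of the report surface.
* The pipeline operates on ROI-level voxel sets produced directly by the
  generator; map-based ROI selection and mirroring are exercised on
  synthetic 3-D statistic maps through their own API.
* Statistical calibration (Wald false-positive rate, robust-regression
  bias, Bayes-factor behaviour) runs on the generator's fast cohort-table
  path — subject-level amplitudes and RTs drawn from the same age laws
  plus measurement noise — at the full n = 586; decoder-level validation
  runs the full BOLD → GLM → MVB path at reduced sizes (8–16 voxels per
  ROI, 120–140 scans, 40–56 trials, 4–6 phase shuffles) so the whole
  battery completes in minutes on one CPU.  Null calibration uses 1500
  replicates.
* The tiny fixture is 12 subjects × 16 voxels/ROI × 120 scans; the
  standard fixture is 100 × 70 × full-length runs.

## Known limitations

* The MVB scheme is a from-scratch implementation of the described
  model class (sparse voxel prior, greedy nested-subset search,
  ReML/empirical-Bayes evidence); it is not a numerical clone of any
  particular software's internals, and absolute F values are not
  comparable across implementations — only differences within one
  implementation are meaningful, which is all the boost analysis uses.
* The directional Bayes factor's Gaussian posterior approximation is
  accurate for the well-behaved cohort sizes used here but degrades
  under separation (when one category is perfectly predicted by age).
* Synthetic-cohort results validate the *pipeline*, not the biology:
  they show the chain detects compensation when it is built in and stays
  calibrated when it is absent, under the generator's assumptions listed
  above.
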