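# Methods

This note documents the statistical model behind `pasbayes`, the conventions
and numerical choices the implementation makes, what the synthetic-data
generator does and does not emulate, and the known limitations.

## The analysis problem

Paired-associative-stimulation (PAS) experiments test whether repeatedly
pairing two stimuli increases the excitability of corticospinal projections.
Excitability is indexed by motor evoked potentials (MEPs): EMG responses in a
target muscle (here flexor carpi radialis, FCR, with extensor carpi radialis,
ECR, recorded for quality control) to transcranial magnetic stimulation (TMS)
pulses of increasing intensity. For each participant, condition and
measurement time (Pre, and 0/10/20/30 min post-intervention) a *recruitment
curve* is measured: MEP amplitude at 90–160 % of resting motor threshold
(rMT) in 10 % steps, six pulses per step plus twelve extra at 120 %. The
scalar endpoint is the **area under the recruitment curve (AURC)**, and the
question is whether post-intervention AURC exceeds pre-intervention AURC by
roughly the amount earlier studies lead one to expect.

## Pipeline stages

### Trial-level QC (`pasbayes.preprocess`)

Background EMG is summarised by the RMS of the 93–3 ms pre-stimulus window
(half-open, at the recording rate — 4 kHz by default). Three rules run in a
fixed order:

1. **absolute rule** — reject a trial when background RMS exceeds 2.5 µV in
   *either* muscle (strict inequality; a trial at exactly 2.5 µV survives);
2. **whisker rule** — per participant and per muscle, compute quartiles of
   all *retained* RMS values pooled across conditions and timepoints, and
   reject trials above Q3 + 1.5 · IQR (strict). Quantiles use linear
   interpolation between order statistics (numpy `method="linear"`, the
   common "type 7"); this is a convention choice, exposed as an option, since
   several quantile definitions exist. Participants with fewer than four
   retained values still get quartiles under the same convention.
   Whether pooling should instead be per session is not decidable from the
   published description; pooling per participant is the default, per-cell
   pooling is available behind a flag;
3. **minimum cell count** — an analysis cell (participant × condition ×
   timepoint × intensity) must keep at least five trials; otherwise the
   entire cell is invalid.

Rejection reasons are tracked in a `qc_status` column; the sequence is
idempotent and conserves trial counts across categories.

### Recruitment curves and AURC (`pasbayes.recruitment`)

Per-cell amplitude is the mean of natural-log-transformed amplitudes,
inverse-transformed to mV — the geometric mean, appropriate for the
log-normal-like distribution of single-trial MEPs. All retained 120 % trials
are pooled (curve sequence plus extras) by default; restricting to the first
six is an option. The AURC is the trapezoidal-rule area over intensity.

Conventions:

* the x axis is intensity in %rMT, so AURC has units mV·%rMT. Absolute field
  strength per participant is unrecoverable from the data, and every
  inference in the pipeline is a within-participant contrast, which is
  invariant to a fixed rescaling of the x axis;
* a curve with *any* invalid intensity cell yields a missing AURC rather
  than a partial trapezoid; partial areas would not be comparable across
  timepoints;
* threshold-sanity flags (90 % amplitude < 0.05 mV; 100 % amplitude in the
  closed band [0.05, 0.1] mV) are advisory only — during acquisition a
  failure triggers re-thresholding, which is out of scope here.

### Missing-cell imputation (`pasbayes.impute`)

Missing AURC cells are filled by a deterministic sequential k-nearest-
neighbour scheme (k = 10 by default): the feature vector of a cell is its
condition (categorical, simple matching), its timepoint (ordered categorical,
normalised rank distance) and the participant's observed AURC profile at the
other timepoints (numeric, range-normalised); distances are Gower-type
averages of the available components; the k nearest observed cells donate
the median of their values; cells are filled in order of increasing row
missingness, and ties among equidistant donors break lexicographically by
(participant, condition, timepoint). Observed values are never altered.

This is a re-specification, not an emulation, of the sequential kNN methods
common in this field: the exact feature coding of any particular external
package is not recoverable, very few cells are ever imputed in practice
(six of 210 in the motivating study), and determinism is worth more here
than bug-for-bug compatibility. Single imputation only; no uncertainty
propagation.

### Informed priors (`pasbayes.priors`)

Each experimental hypothesis is an *interval* of standardised effect sizes
(Cohen's d). The packaged default table is:

| contrast      | d     | lower | upper |
|---------------|-------|-------|-------|
| Pre vs Post0  | 0.601 | 0.403 | 0.799 |
| Pre vs Post10 | 0.684 | 0.474 | 0.893 |
| Pre vs Post20 | 0.766 | 0.556 | 0.976 |
| Pre vs Post30 | 0.849 | 0.634 | 1.063 |

Point estimates at 10 and 20 min are linear interpolations (in minutes)
between the 0- and 30-min values; extrapolation outside [0, 30] is refused.
The same priors apply to every condition (the sham condition serves as the
negative control under identical hypotheses). Priors are data, not code:
they can be replaced from a delimited file for new studies.

`adjust_interval` implements hypothesis updating for a replication: the
interval keeps its half-width ("the same confidence intervals") and is
re-centred on the effect size actually observed; bounds are rounded to two
decimals for reporting. Re-centring [0.556, 0.976] on an observed d of 0.66
gives [0.45, 0.87]. Width preservation is the inferred rule; it reproduces
the published example exactly.

### Interval Bayes factors (`pasbayes.bayes`)

The prior on the standardised effect δ is a zero-centred Cauchy with scale
r = √2/2 (the JZS default for one-sample designs), restricted to the
hypothesis interval [a, b]. Because the marginal likelihood of a paired
design depends on the data only through (t, n), with the likelihood of t
being noncentral-t with df = n − 1 and noncentrality δ√n, Bayes factors can
be computed from a bare t-statistic — which is what makes published tables
reproducible from print.

Three comparisons are supported: interval vs point null, complement vs point
null, and interval vs complement (the ratio of the first two). **The package
default is interval-vs-point-null with r = √2/2**, selected by the
calibration harness (`pasbayes.calibration`): across candidate
parameterisations (both comparison forms; r ∈ {√2/2, 0.5, 1.0, per-contrast
point estimate}) only this one reproduces the twelve published (t, BF)
worked examples — ten of twelve within ±0.05 on their printed one-decimal
scale, and the remaining two within the ±0.005 rounding band of their
two-decimal printed t inputs. The interval-vs-complement form is off by an
order of magnitude on the strongest rows, so although the published *prose*
describes odds against the complement, the published *numbers* are
interval-vs-null quantities, and the package follows the numbers.

Quadrature: `scipy.integrate.quad` per segment, with the δ axis split at the
interval bounds and at 0 (the prior's peak); infinite tails are handled by
quad's internal transformation; absolute tolerance 1e-10. The integrand is
smooth and unimodal on each segment. Prior interval masses use the arctan
closed form. Mass conservation holds to 1e-12; quadrature agrees with
importance sampling from the truncated prior within Monte-Carlo error.

### Frequentist companions (`pasbayes.stats`)

* one-tailed paired t-test, direction fixed to post > pre (the hypotheses
  predict increases); negative t gives p > 0.5, never a reflected tail;
* Cohen's d with the pre-intervention SD as standardiser (n − 1 denominator
  — the published description does not fix the denominator; n − 1 is the
  default and is flagged);
* between-condition d on baseline-subtracted changes, standardised by the
  sham-condition SD — used because the between-session reliability of the
  pre-intervention AURC is modest (ICC(3) ≈ 0.34), so subtracting baseline
  per session mitigates inter-session variance;
* BCa bootstrap CIs (default 10,000 resamples) resampling participants with
  pairing preserved; bias correction z₀ from the bootstrap fraction below
  the estimate, acceleration a from jackknife skewness. Resamples on which
  the statistic is undefined (e.g. a resample that drew one participant n
  times) are dropped. With z₀ = a = 0 the interval reduces exactly to the
  percentile interval; a degenerate bootstrap distribution collapses to the
  point estimate with a warning. Empirical coverage of the nominal 95 %
  interval at n = 14 is ≈ 94–95 % in the test suite's simulation;
* ICC(3,1) — two-way mixed, consistency, single measure — from the two-way
  ANOVA mean squares, on case-complete, non-imputed pre-intervention values
  only;
* Shapiro–Wilk normality screening, advisory (nothing is gated on it).

## The synthetic-data generator (`pasbayes.simulate`)

The generator produces trial-level tables with known ground truth so every
downstream stage is testable without any data download.

**Amplitude model.** log MEP amplitude = sigmoid recruitment term + b_i
(participant, SD `tau_participant` = 0.27) + s_ic (session = participant ×
condition, SD `tau_session` = 0.16) + h_ict (measurement block, SD
`tau_timepoint` = 0.28) + effect shift + trial noise (SD `sigma_log` = 0.6).
The sigmoid is anchored so the population geometric mean is ≈ 0.04 mV at
90 % rMT and ≈ 0.06 mV at 100 % (the defining property of the motor
threshold), saturating near 1.6 mV at 160 %. All SDs are log-scale
(dimensionless) because the model is multiplicative.

Rationale for the three variance tiers: the participant:session split is
tuned (once, by simulation) so the median ICC(3) of pre-intervention AURC
across the three sessions is ≈ 0.34, the modest week-apart reliability
typical of TMS measures; the block-level term models the drift of
corticospinal state between measurement blocks within a session — without
it, paired pre/post differences are implausibly noiseless (t ≈ 7 at
d ≈ 0.4, where real data show t/d ratios around 3). Its size trades
realism of t against the small-sample bias of mean(diff)/sd(pre) (a
regression-to-the-mean effect under skewed data; the pipeline's null-case
mean d stays below 0.05 at the default).

**Effect injection.** A target effect size d at a timepoint is injected as a
uniform multiplicative shift e^s of that block's amplitudes. Since the AURC
is then scaled by e^s, the population effect size is
d = (e^s − 1)·E[AURC]/SD[AURC], and the generator solves
s = log1p(d · cv) with the AURC coefficient of variation computed in closed
form from log-normal moments (trapezoid weights, per-cell trial counts, and
all variance components). The default `d_true` follows the informed-prior
point estimates for the active conditions and zero for sham.

**Background EMG.** Clean trials: participant base level (0.8–1.5 µV) ×
session multiplier (log-SD 0.30) × trial multiplier (log-SD 0.10), truncated
below 2.45 µV. Contaminated trials draw RMS uniformly from 2.6–8 µV.
Contamination is governed by a per-block propensity drawn from a Beta
distribution with mean `contamination_rate` (0.03) and variance
`contamination_clustering` · rate·(1 − rate) (clustering 0.85): elevated
background EMG is a participant-state phenomenon that arrives in
session-long runs. Clustering is what lets a session lose many trials while
most cells keep their five-trial minimum — with independent per-trial
contamination at realistic loss rates, nearly every 6-trial cell would fall
below the minimum, which is not what real datasets look like. At
clustering 0 contamination is exactly Bernoulli per trial.

`missing_rate` optionally deletes whole AURC cells post-hoc (by pushing one
intensity cell's trials above the absolute threshold, so the min-count rule
fires), exercising the imputation path end to end.

**Determinism.** One master seed; per-participant substreams via
`SeedSequence(seed, spawn_key=(i,))`, so adding participants leaves existing
rows bit-identical.

**What the generator does not emulate.** Raw 4 kHz EMG traces (the RMS is
generated directly; `background_rms` is tested on synthetic sinusoids and
noise); heavy-tailed or artefact-laden amplitude distributions beyond the
log-normal; order effects, fatigue, or drift of the motor threshold within a
session; any dependence of contamination on amplitude. Passing recovery
tests therefore show that the pipeline's estimators are calibrated under the
generative model the analysis itself assumes — not that real recordings meet
those assumptions.

## Problem sizes used in tests

The test suite runs the full pipeline at the study's scale (n = 14
participants) with 150 replicates for effect-size recovery (mean recovered d
within ±0.1 of truth at d = 0.60–0.85), 80 null replicates (mean |d| < 0.1,
observed < 0.05), 60 replicates for the median-BF gate and 40 for the sham
gate; BCa coverage uses 1000 simulated datasets at 1500 resamples; the
noncentral-t density check uses 10⁷ simulated t-statistics. These sizes give
Monte-Carlo standard errors comfortably below the asserted tolerances.

## Known limitations

* The Bayes-factor engine covers the one-sample/paired design only; no
  hierarchical, model-averaged, or estimation-oriented output.
* Single imputation; imputation uncertainty is not propagated into the
  bootstrap intervals.
* The d estimator mean(post − pre)/sd(pre) is upward-biased at n = 14 under
  skewed data (≈ +0.05–0.08 at d ≈ 0.6–0.85 in the generator's regime); the
  package reports the estimator as published rather than a bias-corrected
  variant.
* The calibration harness can only distinguish parameterisations that
  differ on the published worked examples; parameters the examples are
  insensitive to (notably r within the interval-vs-null form) are fixed by
  convention (√2/2).
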