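# Methods

`emopower` implements, end to end and on synthetic data with known ground
truth, an analysis chain for comparing two single-trial EEG indices of
emotional engagement: the scene-evoked late positive potential (LPP) and a
video-driven "oscillation-power" measure derived from a 7–8 Hz Hilbert
envelope during flicker-evoked steady-state stimulation.  The package's
central demonstration is methodological: a narrow-band envelope centered on
the driven frequency integrates whatever power falls inside its pass band,
so an emotion effect carried by *broadband* 3–10 Hz power masquerades as a
steady-state visual evoked potential (ssVEP) effect, while the driven
7.5 Hz bin itself is unaffected.

## The synthetic study

`synthgen.SimulationConfig` defaults are the study conditions: 45
participants, 90 stimuli in three valence categories of 30 (8 erotica items
within pleasant, 5 surgery items within unpleasant), integer 1–9 SAM
ratings of valence and arousal, 128-channel montage, scene epochs from
−125 ms to 2 s and video epochs from −2 s to 10 s around onset.  Sampling
rate defaults to 256 Hz (512 Hz available); all signal content is below
30 Hz, so 256 Hz is comfortably oversampled and halves memory and time.

Every trial draws a latent (amplitude deviation, experienced arousal) pair
from the participant's own bivariate normal, centered at structural means
(participant mean + stimulus effect; participant arousal offset + stimulus
normative arousal).  Both downstream hierarchical models are therefore
literally true of the generated data, with known parameters:

* participant means ~ Normal(5, 3) µV; per-trial residual SDs ~
  Normal(5, 1.5) µV truncated positive (the implied per-trial SNR of a
  ~1.6 µV emotional–neutral contrast is ≈ 0.3, in the range reported for
  single-trial ERP emotion effects);
* stimulus effects = content-tag means (erotica 2.6, pleasant-other −0.1,
  neutral −1.05, unpleasant-other 0.2, surgery 1.6 µV, then centered) plus
  Normal(0, 0.8) jitter — the erotica/gore sensitivity pattern of the
  scene-ERP literature;
* per-participant amplitude–arousal correlations ~ Normal(0.15, 0.10);
* normative arousal per content tag (erotica 6.5, pleasant-other 5.8,
  neutral 4.2, unpleasant-other 6.8, surgery 6.7) with 0.5 jitter.

Scene epochs inject a rectangular centro-parietal positivity spanning
400–900 ms on the 9-sensor CPz-centered cluster, with the trial's latent
amplitude; video epochs inject, on the 9-sensor Oz-centered cluster:

1. a 7.5 Hz sinusoid whose amplitude is **never** category-dependent —
   1 µV base scaled by a per-participant lognormal gain (SD 0.3, producing
   the large between-participant variance that dominates the video
   measure's R²) and a per-trial lognormal jitter (CV 0.25, attentional
   fluctuation);
2. band-limited Gaussian noise over 3–10 Hz whose SD is an affine
   decreasing function of the trial's experienced arousal
   (`1.1 − 0.3·(arousal − 5)` µV, floored at 0.1).  No generative model for
   the suppression is available from the literature; this affine stand-in
   was calibrated once so that, after the standard preprocessing chain, the
   band analyses reproduce the qualitative pattern of interest (driven bin
   null; 7–8 Hz effect large; 3–10 Hz effect larger; by-stimulus arousal
   correlation of the envelope measure roughly −0.4 to −0.8) at desk-scale
   cohort sizes;
3. the broadband process carries a ±0.3 Hz spectral notch at the driven
   frequency: entrainment *replaces* endogenous activity at the flicker
   frequency rather than adding to it, so category-dependent broadband
   suppression cannot touch the driven bin by construction.

Everything rides on 1/f-shaped background noise (exponent 1, SD 1 µV,
spectral shaping of white noise), with the pre-onset scrambled-video
baseline period carrying 1.5× elevated noise.  Artifact injection
contaminates chosen trial×channel cells with a step, a linear drift, and
three spikes scaled to ±250 µV, and returns the ground-truth mask.

What the generator does *not* emulate: spatial correlation of background
noise across sensors (channels are independent), volume-conducted
topographies and spatial falloff outside the named clusters, harmonics of
the driven response, eye-movement/EMG spectra (artifacts are generic
steps/spikes), rating-scale use pathologies beyond rounding/clipping, and
any within-video temporal dynamics of emotion.  Passing tests therefore
validate the *analysis machinery* — measure extraction, screening,
inference, model comparison — not claims about real cortical dynamics.

## Signal processing

Butterworth designs follow the printed recording-pipeline corners
(18th-order low-pass, 30 Hz at −3 dB / ≥45 dB by 40 Hz; 4th-order 0.1 Hz
high-pass for scenes; 3rd-order 3 Hz high-pass for videos, ≥18 dB at 1 Hz);
when an explicit order is given it wins and the realized response is
asserted by tests.  All epoch filtering is zero-phase (forward–backward
second-order sections), protecting the 400–900 ms LPP latency window; the
printed corner specs are therefore checked on the single-pass response.
The envelope is the analytic-signal modulus; no edge trimming is applied
inside the operator because the 1–9 s video analysis window already
excludes onset/offset transients.  Spectra use a rectangular window over
exactly `duration × srate` samples, so an 8 s window yields 0.125 Hz bins
and 7.5 Hz is bin-exact; power is normalized to satisfy Parseval (sum of
bin powers = time-domain mean square).  Band power is the mean over bins
inside `[lo, hi]`, with `lo == hi` selecting a single bin.

A known artifact of the rectangular window: power just outside the
synthesized notch leaks into the 7.5 Hz analysis bin through sinc
sidelobes, so at unlucky seeds a small residual category effect can appear
at the driven bin (p ≈ 0.02 in roughly one seed in six at n = 10).  The
effect-size ordering — broadband ≫ narrow-band ≫ driven bin — is stable in
every seed examined.

## Artifact screening

Per trial×channel cell, three indices (max |amplitude|, max |first
difference|, SD) are robust-standardized per channel (median/IQR across
trials, 1.349 converting IQR to SD units) and averaged into a composite.
Standardizing within channel rather than across all cells pooled keeps
sensors that legitimately carry large signal (the occipital cluster during
flicker) from being flagged wholesale.  Defaults: cell bad above composite
3, trial rejected above 10% bad channels, bad cells in retained trials
replaced by the inverse-great-circle-distance weighted mean of the 6
nearest clean sensors — an explicit approximation of spherical-spline
interpolation.  Participants are excluded when *over* 50% of trials are
lost from any category within either stimulus series; retaining exactly
half keeps the participant (strict inequality).

## The two multilevel models and their sampler

Model 1 (participant + stimulus):
`Amplitude_i ~ Normal(beta1_{j(i)} + beta2_{k(i)}, sigma_{j(i)})` with
`beta1_j ~ Normal(ParBar, sigmaPar)`, `beta2_k ~ Normal(0, sigmaStim)`,
`sigma_j ~ Normal(sigmaBar, tau)` constrained positive, ParBar given a
Normal(mean(y), 2·SD(y)) prior and all scale hyperparameters
HalfNormal(0, 2·SD(y)).  Model 2 (bivariate amplitude–arousal): each
trial's pair is MVNormal with per-participant means and 2×2 covariance,
every participant-level parameter partially pooled through normal
hyper-distributions; the grand arousal mean has a 1 + 8·Beta(1.1, 1.1)
prior on [1, 9], arousal scales HalfNormal(0, 4), amplitude scales
HalfNormal(0, 2·SD(amplitude)), and the covariance-mean hyper
Normal(0, 2·SD(amplitude)).  Positive-definiteness of each covariance is
enforced by proposal rejection.  Model 2's predictive quantity is the
conditional normal of amplitude given arousal (mean
`muAmp + sAmpAro/sAro² (aro − muAro)`, variance
`sAmp² − sAmpAro²/sAro²`), verified against a numerical grid-conditioning
oracle.

Both models are fit by a hand-written vectorized Metropolis-within-Gibbs
sampler.  Location parameters have conjugate normal full conditionals and
are Gibbs-sampled exactly; scale parameters use adaptive log-scale
random-walk Metropolis (Robbins–Monro adaptation to 0.44 acceptance during
warmup only), with the positivity-truncation constants of truncated-normal
group priors included in the hyperparameter conditionals.  Hierarchical
funnels — the classic pathology of such models — are traversed by three
kinds of extra moves: collapsed updates of group-SD hyperparameters with
the group effects analytically integrated out (Woodbury form), joint
rescale/translate moves that move a whole group of parameters with its
hyperparameter while leaving standardized deviations invariant, and (in
Model 2) correlation-preserving joint proposals of an SD component with
the covariance term.  Defaults are 4 chains × (600 warmup + 1500 draws);
convergence is gated on rank-normalized split R-hat < 1.01 for every
scalar parameter, and a failed gate triggers a refit with doubled length
(up to twice) before raising — never a silent return.  The sampler is a
contract, not a mandate: any configuration passing the gate is acceptable.

R-hat and PSIS-LOO (Pareto-smoothed importance sampling, 20% tail) are
delegated to arviz; expected log pointwise predictive density (ELPD)
differences and stacking weights (simplex weights maximizing the combined
leave-one-out predictive density, optimized through a softmax
parameterization) are computed in `modelcmp`.  PSIS-LOO is validated in
tests against closed-form exact leave-one-out on conjugate normal models.
Trials whose log-likelihood is constant across draws are treated as exact
(uniform importance weights).

Per-trial variance explained is draw-wise
`var(predicted) / (var(predicted) + residual variance)` with the residual
variance taken as the draw's mean modeled trial variance; the
predictor-only variant removes each participant's predicted effect first.
The per-trial signal-to-noise posterior is the draw-wise
(emotional − neutral mean stimulus effect)/sigmaBar, compared across
measures on absolute value because the two effects have opposite signs.

## Group statistics

Within-participant category means are z-scored within participant
(sample-SD convention, `ddof=1`, so (1, 2, 3) → (−1, 0, 1); configurable),
then analyzed by sphericity-assumed repeated-measures ANOVA (statsmodels
`AnovaRM`; 45 participants × 3 categories gives the (2, 88) dfs).  Partial
η² is derived as `F·df_num / (F·df_num + df_den)`.  Paired t-tests report
Cohen's D = mean(diff)/SD(diff), which satisfies D = t/√n.  By-stimulus
analyses z-score single trials within participant, average per stimulus
across participants, and correlate with mean arousal (Pearson); the
between-measure slope difference is the interaction F of an OLS
`z ~ arousal × measure` model.

## Desk-scale choices

Default pipeline geometry is 12 participants × 30 stimuli × 24 channels at
256 Hz; the full 45 × 90 × 128 study is a config change.  Recovery and
calibration tests use 12 × 30 with residual SD 2.5 µV and stimulus SD
1.5 µV — chosen by a power argument (the posterior-median ~ truth
correlation has expectation ≈ 0.9 there, so the test discriminates a
working sampler from a broken one), not tuned to any observed run.
Simulation-based calibration of the grand mean runs 60 tiny replicates
(5 × 6) with fixed prior scales, because the models' default empirical-Bayes
prior scaling (2·SD of the data) would make the prior data-dependent and
the calibration circular.

## Known limitations

* The interpolation is inverse-distance, not a true spherical spline; on a
  dense montage with smooth fields the difference is small, and tests only
  rely on redundant-neighbor reconstruction.
* The SCADS-style screening is per-trial; session-level sensor rejection is
  not implemented.
* The rectangular-window leakage at the driven bin discussed above.
* Ratings enter Model 2 as continuous despite being integers; at arousal
  SDs ≈ 1.6 the discretization attenuates correlations by only a few
  percent, absorbed by the recovery tolerances.
* The MH sampler is slower per effective draw than gradient-based samplers;
  at the shipped problem sizes a Model 1 fit takes seconds and a Model 2
  fit tens of seconds.
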