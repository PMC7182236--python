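# Methods

This note documents the models and procedures implemented in `fpvs`, the
defaults chosen where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real recordings.

## Stimulus scheduling

A session plan is a randomized list of trials, each a sequence of
(identity, expression) cycles at the stimulation rate. Constraints, in
decreasing order of strictness:

- **Regularity.** In regular conditions the designated category occupies
  every first triplet position (cycles 0, 3, 6, …) — exactly ⌈cycles/3⌉
  positions — and never appears as a filler. Happy and disgusted are
  filler-only categories. Irregular triplets contain distinct categories
  (all three in the 3-expression design; three of four, balanced, in the
  4-expression designs).
- **Filler balance.** Filler slots draw the least-used categories with
  random tie-breaks, so counts are balanced within each trial (a
  per-trial reading of "evenly distributed"; session-level balance
  follows).
- **No short-term repeats.** No identity+expression token of triplet *t*
  recurs in triplet *t+1*. With a single identity per trial this is
  infeasible at the regular position (the regular expression repeats by
  design) and for fillers when fewer distinct categories remain than
  slots; those cases are exempted rather than failing the build.
- **Targets.** A fixed number of trials per condition (36 of 96 in the
  15 Hz detection designs, scaled proportionally elsewhere) receive 1–3
  dot targets. Onsets are drawn uniformly on the frame grid subject to a
  minimum inter-onset interval (600 ms; 800 ms in the 6 Hz task) using the
  standard gap-shift construction, so every admissible schedule has equal
  probability. The published "40% of trials" is approximate; the exact
  count reproduces the printed 216 discarded trials and the resulting
  360 analyzable epochs (60 per condition) in the Pilot-1 design.
- The passive-viewing preset (`exp2`) presents 360 trials with no targets;
  its 12 factorial cells hold 30 trials each, i.e. 60 per
  orientation × regularity condition with the two identities split evenly.

## Forward simulation

One trial of `n = round(duration × 256)` samples (973 for 3.8 s, 1792 for
7 s) is the sum of:

- **Stimulation SSVEP** — `amp_stim · sin(2π f_stim t + φ)` through a
  Gaussian-blob topography centered near Oz; phase-locked across trials
  (φ = 0 by default), amplitude 1 µV.
- **Regularity SSVEP** (regular conditions only) — amplitude 0.8 µV
  through a topography near POz, with trial phase θ ~ von Mises(0, κ).
  κ is the per-condition knob for inter-trial phase clustering; its
  analytic image on CS is E[CS] = (I₁(κ)/I₀(κ))² (`expected_cs`). Default
  presets: neutral κ = 1.2, angry κ = 0.8, ×0.7 under low variability,
  amplitude 0 in irregular conditions — a preset mirroring the empirically
  observed ordering, not a calibration target.
- **Background noise** — per-channel 1/f^β noise (β = 1) synthesized in
  the frequency domain with random phases (exact spectral control), then
  spatially colored by the Cholesky factor of a squared-exponential
  channel covariance (length scale 6 cm, ridge 0.1); 1 µV RMS per channel.
- **Alpha rhythm** — 10 Hz, 0.5 µV, random phase per trial, parietal
  topography.
- **Blinks** (off by default) — Poisson events at `blink_rate`/min, 400 ms
  raised-cosine transients of 300 µV on the EOG channels with 10% leakage
  onto scalp channels; included solely to exercise the rejection cascade.

Per-participant heterogeneity is modeled as a log-normal factor
(SD 0.3) multiplying all κ values. No head-model (BEM/FEM) forward
computation, saccades or EMG are attempted: the fixed topographies stand
in for the parieto-occipital response distributions of real data.

Consequences for interpretation: passing tests show that the analysis
chain recovers planted phase clustering and rejects planted artifacts
under this generative model; they do not certify performance under
realistic source geometry, non-stationary noise, or real ocular dynamics.

## Artifact screening

All criteria are z-scores of simple metrics with |z| > 3 flagging an
outlier, following the FASTER family of screens:

1. whole-recording channel screen: variance, mean absolute pairwise
   correlation, Hurst exponent. The Hurst exponent is estimated by
   detrended fluctuation analysis with dyadic windows of 16–256 samples.
   The correlation criterion is one-sided (low correlation flags a
   disconnected channel; high correlation is what healthy neighbors look
   like). Flagged channels are interpolated by spherical splines.
2. epoch screen on channel-averaged amplitude range, variance, and
   channel deviation (|channel mean − grand mean|, the FASTER
   convention).
3. within-epoch channel screen (variance, median gradient, amplitude
   range, deviation) with per-epoch spherical-spline interpolation.
4. condition-wise epoch screen on the same metrics plus maximum absolute
   EOG value, z-scored within condition (this stage feeds the
   per-condition rejection percentages).
5. epochs with more than 12 interpolated channels are discarded.
6. kurtosis screen: epochs beyond ±5 SD of single-channel or all-channel
   mean kurtosis.
7. spectral screen: per-epoch mean log-spectrum against the median
   across epochs (the "baseline", which the screen's source description
   leaves undefined); deviations beyond ±50 dB at 0–2 Hz (blinks) or
   +25/−100 dB at 20–40 Hz (muscle) reject the epoch.

Spherical-spline interpolation uses the Legendre-series Green's function
with order m = 4, ridge λ = 1e−5 and 50 series terms; it agrees with
mne-python's `interpolate_bads` to a few percent RMS (checked in the test
suite, which keeps mne as an independent oracle).

On artifact-free simulations the cascade's false-positive rate is about
3–6% of epochs per condition, dominated by the kurtosis screen: on
temporally correlated (1/f) noise the sample-kurtosis distribution has
heavy tails, so a ±5 SD criterion fires more often than a Gaussian
calculation suggests. This matches the intent of a screen tuned for
abrupt spikes while remaining conservative.

## Spatial filtering and phase extraction

Epochs are truncated to the analysis window (0.5 s after stream onset;
3 s for 15 Hz sessions, 6.5 s for 6 Hz sessions) and linearly detrended.
The RESS filter at target frequency f solves the generalized eigenproblem
S w = λ (R + 0.01·mean eig(R)·I) w, where

- S is the mean per-trial covariance of data filtered at f with a
  Gaussian kernel of FWHM 1.0 Hz (the ±0.5 Hz signal bandwidth),
- R is the mean of the covariances at f ± 1 Hz (FWHM 0.5 Hz), pooled
  before regularization.

Per-trial covariances are averaged (rather than computed on concatenated
data) for robustness to trial-count imbalance. Filters are derived
separately per condition; the leading eigenvector is sign-fixed (largest-
|weight| entry positive) and its topography is S w, normalized. One null
covariance dimension is expected under average reference and is absorbed
by the ridge; a warning is raised only for deeper rank deficiency.

Projected trials are multiplied with a Tukey window (taper fraction
α = 0.25 by default — the taper is not pinned down by the published
description and is exposed in configuration), zero-padded to 10 s
(0.1 Hz grid, so 5 Hz and 2 Hz land exactly on bins 50 and 20), and
Fourier-transformed. Phase is taken from the exact bin; an off-grid
frequency is an error rather than a silent nearest-bin snap.

## Phase-clustering statistics

`cs_index_closed` ((R² − n)/(n(n−1))) is the production path and
`cs_index` (explicit pairwise sum) the reference; they agree to 1e−12 and
both are invariant to global phase rotation and trial order. CS is an
unbiased estimator of (I₁(κ)/I₀(κ))² under von Mises phases and has mean
0 under uniform phases for every n, whereas ITC (R/n) carries a
√(π/(4n)) small-sample bias — the reason CS is preferred for comparing
conditions with unequal trial counts. The CS-at-stimulation-frequency
analysis uses the identical machinery with f = f_stim.

## Multilevel model

CS values (one per participant × cell) enter a Gaussian cell-means model
with participant-varying intercepts. Priors: Normal(0, 3) on cell means,
half-Student-t(3, 0, 2) on the group SD τ; the residual SD σ, whose prior
the published description does not state, receives the same
half-Student-t(3, 0, 2). Cell-means coding is used because every reported
quantity is a pairwise cell difference.

Sampling is by Gibbs: cell means and intercepts have conjugate normal
full conditionals; σ and τ are updated by stepping-out slice sampling on
the log scale. The chain plan is honored exactly — 8 chains × 8,000
iterations, 4,000 warmup, thinning 2 — for 16,000 retained draws per
parameter (a reduced 4 × 2,000 plan is provided for quick checks).
Diagnostics (computed with arviz): rank-normalized split R-hat (flag at
> 1.05), ESS ratio (flag below 0.1), and MCSE. The conjugate updates mix
well; the full plan reaches R-hat < 1.01 and ESS ratios above 0.2 on the
synthetic presets.

Contrasts report the posterior mean of the cell difference, the 95% HDI
(narrowest window over sorted draws), and the evidence ratio — the ratio
of posterior draws on the stated side of zero to those on the other.
ER = ∞ when all draws fall on one side (band "very strong"); boundary
values 3 and 10 are assigned to the higher band. By default the reported
direction is the one the posterior favors, matching how tables of
pairwise comparisons are usually printed; planned one-sided hypotheses
can be stated explicitly, and calibration (< 10% "strong" under a true
null) holds for prespecified directions. Contrasts whose cells are both
irregular conditions are flagged `interpretable=False` and hidden by
default: deriving a narrowband filter where no source exists overfits
noise, so those differences carry no signal.

## Problem sizes in tests

The test suite runs scaled-down versions of the full designs: typically
10–40 trials per condition, 2–16 simulated participants, a 16-channel
reduced montage for simulation-heavy checks, and the reduced sampler for
repeated fits; the full 8 × 8,000 plan and the full 576-trial Pilot-1
session are each exercised directly where a check depends on them. These
sizes were chosen to keep each property comfortably detectable (planted
effects are several times their standard errors) while the whole suite
stays fast.

## Known limitations

- The forward model is a two-source caricature; topography-recovery
  results quantify the algebra of RESS, not localization accuracy.
- Sequence-level luminance/contrast confounds (the physical-difference
  explanations discussed for real data) are outside the generative model.
- The screening cascade's condition-wise stage assumes enough epochs per
  condition for stable z-scores; below ~20 epochs the |z| > 3 criterion
  cannot fire and the cascade under-rejects.
- No harmonic summing: analyses target the fundamental regularity
  frequency only.
- EDF/BDF ingestion is not wired in; `EpochSet` accepts any
  (trials × channels × samples) array, so mne-python readers can feed it
  directly.
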