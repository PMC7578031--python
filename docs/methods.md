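# Methods

This note documents the models, estimators, numerical choices, and known
limitations of the package. It describes what the code computes; every
empirical number it mentions is produced by the test suite or
`scripts/acceptance.py`.

## Reward schedule

`build_cue_set` derives the nine-cue schedule from three constraints: an
integer 1–11 outcome scale, mean-preserving symmetry of the two-point gambles
around the deterministic anchors (EV 3, 6, 9), and a common pair of offsets
across anchors. The largest offset admissible at every anchor is
min(EV−1, 11−EV) = 2, giving offsets ±1 and ±2 and variances {0, 1, 4}. The
construction makes the sample correlation of EV and variance across the nine
cues exactly zero, which is what lets downstream GLMs attribute effects to
either factor without confounding.

## Synthetic sessions

`simulate_session` draws everything from a single seed through named
substreams (trials, spikes, lfp, coupling, artifacts), so identical
(config, seed) pairs give byte-identical bundles.

**Trials.** Cue identity, cue location, and target location are drawn
independently and uniformly; draws are retried until every
(EV × variance × location) cell holds at least `min_trials_per_condition`
trials (default 5, matching the unit-inclusion rule). Licking is Bernoulli
with logit β₀ + β_EV·EV + β_var·Var + β_loc·loc + β_int·EV·Var; the default
slopes are 0.24 per EV point and 0.03 per variance point², the regime the
behavioral analyses are designed to detect, with β₀ = −2.0 chosen to put
lick probabilities in a graded mid-range across cues. Reaction times are
Gaussian (250 ± 40 ms, floored at 100 ms) with optional EV/variance slopes;
82% of trials are correct.

**Spiking.** Each unit has a lognormal base rate (median 8 spikes/s) and a
coding assignment: factor (EV, variance, or none) and polarity (±). During
cue+delay (0–800 ms) the rate is base + polarity·effect·factor, floored at
zero — the linear-rate link mirrors the identity-link GLM used for analysis
(a log link is available via `rate_link="log"`). Spike times are
piecewise-homogeneous Poisson. Trial-wise multiplicative gain latents
(SD 0.25) are shared within a subnetwork (same area, same factor) and enter
with the unit's polarity sign, so same-polarity pairs co-fluctuate and
opposite-polarity pairs anti-fluctuate — the simplest mechanism that
reproduces the observed ordering of noise correlations by pair class.

**LFP.** Each electrode trace is 1/f² background (integrated white noise)
plus white noise plus band-limited oscillations (centers 12 Hz for the
8–18 Hz band, 30 Hz for 18–43 Hz). Oscillation power is multiplied by
1 + β_EV·EV + β_var·Var during 0–800 ms only, consistent with pre-cue
baseline normalization; the defaults suppress the low band with both factors
in both areas and give the high band opposite-signed, area-specific effects.
Band oscillations share one phase per trial across an area's electrodes,
emulating the high within-array coherence of real recordings (without this,
spikes locked to one electrode's field would carry no locking to the rest of
the array). Default sampling rate 1 kHz; rates below 200 Hz (2× the 100 Hz
analysis ceiling) are rejected.

**Phase coupling.** For each configured direction (e.g. parietal spikes →
frontal field) and variance level, a von Mises concentration κ is specified.
Spikes of coupled units inside 0–800 ms are repositioned: target phases are
drawn von Mises(μ, κ) and mapped to uniformly chosen crossings of the
band-filtered analytic-signal phase (4th-order zero-phase Butterworth +
Hilbert transform), with linear interpolation between samples. The mean
resultant length of generated phases matches the Bessel ratio I₁(κ)/I₀(κ)
within Monte-Carlo error, which is the oracle the coherence stages are
checked against.

**Artifacts.** `inject_artifacts` corrupts a configurable fraction of
trial × electrode traces with labeled kinds: broadband power (amplitude
×√10, i.e. 10× power), 60 Hz line noise, rail saturation, or a 50 ms
high-amplitude transient. Labels live in the ground truth for sensitivity
scoring.

## Behavior

Trials are filtered to correct completions with RT within mean ± 2 SD of the
session's correct trials; the bounds are computed once and stored with the
table, making the filter idempotent. EV and variance enter the GLMs raw
(3/6/9 and 0/1/4) — coefficients are per point and per point², which is the
only scale on which a slope of 0.24 per EV point is interpretable. The
licking response defaults to the fraction of 1 ms lick-trace samples with
contact inside the subject's window (binary any-lick by config); the
binomial-logit fit is the licking coefficient of record. Model comparison
uses AIC (log-likelihood and BIC also reported): the parametric model keeps
variance as 0/1/4, the alternative replaces it with a probabilistic-vs-
deterministic indicator.

## Spikes

Inclusion requires ≥5 trials in each of the nine EV × variance cells
(location-split cells by config) and ≥5 spikes on average in −500…+1000 ms.
Selectivity is an OLS fit (identity-link normal GLM) of the 0–800 ms count on
[EV, Var, EV×Var, location], α = 0.05 two-sided per factor with no
correction across units, so labeled proportions have the same semantics as a
raw significance table. Units significant for both main factors contribute
to both factor classes. Noise correlations use raw (optionally z-scored)
counts in −600…0 ms; classes are within/across factor × same/opposite
polarity; the across-class comparison is Kruskal–Wallis and per-class tests
against zero are Wilcoxon signed-rank.

## Decoding

Responses are the closed-form window average of the 50 ms-SD
Gaussian-smoothed rate in 0–800 ms (an exact integral, no gridding). Each
repetition resamples m trials per unit and condition (m = the minimum count
over the units and the two discriminated conditions), stacks pseudotrials
with trial order randomized within condition, and scores a linear SVM (C=1,
features z-scored on training folds only) with stratified 5-fold CV. Excess
accuracy is real minus label-shuffled accuracy per repetition; the CI is the
2.5/97.5 percentile band of the bootstrap distribution. Incongruent regimes
map levels by rank (low↔low, high↔high) and draw test pseudotrials disjoint
from training ones; when train and test pools overlap (congruent control),
half the pool is reserved for testing.

## LFP

Preprocessing: 60 Hz notch (IIR, Q=30), 100 Hz low-pass (4th-order
Butterworth), both zero-phase, then linear detrend. Cleaning step 1 computes
five-band (0.5–4, 4–8, 8–12, 12–30, 30–90 Hz) sums of log multitaper power
(4 DPSS tapers), z-scores, projects to 2 principal components, and fits
Gaussian mixtures with K = 2…4 chosen by BIC. Dense clusters are collected
largest-first until they jointly hold ≥80% of trials, with the refinement
that a cluster smaller than half the largest is sparse outright — this keeps
a 20%-contamination artifact cluster from being absorbed as dense when the
clean cluster sits just under the coverage threshold. Sparse-cluster trials
are discarded; within dense clusters, trials whose Mahalanobis distance to
the cluster (centroid, covariance — the standard estimator for "distance to
all other trials") exceeds the 90th percentile are discarded. Step 2
z-scores peak-to-peak amplitudes of survivors and removes |z| > 0.5, read as
two-sided. This rule is deliberately severe: on a clean Gaussian
peak-to-peak distribution it removes 2Φ(−0.5) ≈ 61.7% of trials, which the
tests document, and it is condition-blind by construction.

Time-frequency power uses complex Morlet wavelets (`pywt` cmor family,
parameterized to 7 cycles — the trade-off favoring ~1 Hz resolution in the
8–43 Hz bands of interest). Normalization is relative power change against
the trial's own 300 ms pre-cue baseline per frequency. The default "safe"
mode applies the ratio to raw (positive) power; the "paper" mode that first
z-scores power per frequency across the session and then forms the same
ratio is preserved behind a flag, with near-zero denominators flagged NaN —
dividing z-scored values is numerically fragile, which is why it is not the
default.

Pixel GLMs (normal identity) are solved as vectorized OLS over all pixels at
once (closed form, identical to a per-pixel GLM fit); observations are
trials pooled across an array's electrodes. For ROI detection the
coefficient maps are instead fit per electrode: within each 200 ms epoch ×
frequency cell, coefficients are averaged over the epoch's time pixels per
electrode and tested against zero across electrodes with the Wilcoxon
signed-rank test (the one-sample analog of the rank-based across-group
test), BH-FDR corrected across frequencies per subject. Cells significant
with the same median sign in all subjects merge over contiguous frequencies
into band × epoch ROIs. Electrodes, not pixels, are the exchangeable
replicates here: wavelet maps are strongly autocorrelated across neighboring
pixels, and treating pixels as independent samples would break the null
calibration that the test suite enforces (zero ROIs on effect-free
sessions).

## Connectivity

Spike-triggered phase: each spike contributes the phase of a single
Hann-tapered 200 ms window of the LFP centered on the spike, evaluated at
1 Hz steps over 4–47 Hz; phase 0 is the oscillation peak, increasing with
time. Spikes whose window crosses the trace edge are dropped and counted;
spikes are assigned to 200 ms task-epoch bins.

PPC: with r_m the mean phasor of trial m's spikes, the estimator is
(|Σr|² − Σ|r_m|²) / (M(M−1)) — the average cosine of phase differences over
all cross-trial spike pairs with every trial pair weighted equally. Pairs
within a trial are excluded, which is what removes the dependence and
spike-count biases of the naive pooled estimator (`ppc_pooled`, kept for the
bias comparison). A brute-force double loop over cross-trial pairs is the
test oracle (agreement to 1e-10), and E[PPC] = (I₁(κ)/I₀(κ))² for i.i.d. von
Mises phases is the closed-form check. Cells with fewer than two
spike-bearing trials are NaN, never zero.

WPLI per time-frequency cell is |Σ_trials Im X| / Σ_trials |Im X| with X the
Morlet cross-spectrum; cells whose denominator is numerically zero relative
to Σ|X| (pure zero-lag coupling) are flagged NaN. The estimator is invariant
to amplitude scaling of either signal.

Condition statistics: per frequency (and epoch bin), Kruskal–Wallis across
condition levels over pairs, BH-FDR across frequencies, with modulation
direction given by the least-squares slope of condition means. The
directional contrast computes, per pair, the slope of mean PPC against
variance level within a band, and reports the difference in mean slope
between directions with a bootstrap-over-pairs 95% CI.

## Problem sizes

The verification suites run at desk scale, chosen once: sessions of 108–540
trials, 2–44 units and 1–8 electrodes per area, 12,000 trials for behavioral
recovery (matching the scale of the pooled behavioral dataset), 10–20 seeds
for rate-type criteria, 15–25 bootstrap repetitions for decoding, and
2 Hz-step frequency grids for time-frequency stages. Production analyses of
real-sized sessions (48-electrode arrays, 1 Hz grids, 200 repetitions) use
the same code paths with larger configuration values.

## Limitations

- The generator emulates the *statistical* structure of the task — reward
  schedule, opponent coding, latent-driven noise correlations, band-power
  effects, directional phase coupling — not biophysics: no conductance-based
  neurons, no current-source geometry, no eye movements, no learning across
  sessions. Passing parameter-recovery tests shows the estimators are
  correct and calibrated on data with known structure; it does not certify
  performance on pathologies the generator lacks (non-stationary drift,
  correlated broadband noise, spike-sorting errors).
- Spike-count GLMs use a normal identity link on Poisson-ish counts for
  fidelity to the analysis convention; at very low rates a Poisson GLM would
  be more efficient.
- The PPC variant implemented is the across-trial, equal-trial-pair-weight
  estimator; toolbox "PPC2" definitions differ in per-trial normalization
  details, so absolute values may differ slightly from other packages while
  the bias-control property is the same.
- The session generator draws trial types i.i.d. and retries to satisfy the
  per-cell minimum; extremely small sessions need a lower
  `min_trials_per_condition`.
- NWB import/export is not provided; the native bundle (CSV + HDF5 + JSON)
  is the interchange format.
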