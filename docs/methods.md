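# Methods

`songtune` re-implements, as a tested library, the quantitative workflow of
a courtship-hearing study in male *Drosophila melanogaster*: synthesize
playback stimuli, score song-induced chaining behavior, extract
stimulus-locked calcium responses from imaging movies, build inter-pulse-
interval (IPI) and intensity tuning curves, and test how neural tuning
relates to behavior. Because no raw recordings ship with the package, a
seeded synthetic-data generator plants known ground truth so every stage —
and the pipeline end to end — is verifiable by parameter recovery.

## Stimuli

Pulse song is modelled as a train of Gaussian-enveloped sinusoidal pulses

    s(t) = A · exp(−t²/2σ²) · sin(2π f_c t),   t ∈ [−3σ, +3σ]

with carrier f_c = 220 Hz and envelope SD σ = 2 ms (configurable; ~2.6
carrier cycles per pulse, consistent with fly pulse morphology). The IPI is
the peak-to-peak interval between envelope maxima, so an n-pulse train
spans (n−1)·IPI. Sine song is a 140 Hz tone of 1.4 s; white noise is
seeded Gaussian noise band-limited by the 10 kHz sampling rate and
RMS-calibrated. Calibration is relative: amplitude 1.0 ↔ 80 dB SPL and
scales as 10^((L−80)/20); the mapping from dB SPL to absolute particle
velocity is a hardware measurement, not computed here.

Two playback protocols are built in: an **intensity ramp** (60 s silence,
then continuous pulse song in 30-s blocks stepping 60→90 dB; the step size
is a configuration list defaulting to 2.5 dB since only the endpoints and
the 30-s cadence are fixed by the assay) and an **intermittent** protocol
(1 min silence, 2 min of 40-pulse trains delivered every 5 s — equal pulse
counts across IPIs — then 2 min silence).

## Chaining behavior

The number of flies (of six per arena) engaged in a courtship chain is
scored every 3 s; the chaining index (CI) of a 30-s block is the sum of its
ten counts (maximum 60). Partial trailing blocks are dropped rather than
padded so the CI bound stays exact. `summed_ci` totals blocks lying fully
inside a window (no fractional-block ambiguity); `chain_fraction` is the
proportion of samples with at least three flies chaining, the metric used
for optogenetic-activation experiments. Counts are treated as instantaneous
snapshots on the 3-s grid.

## ROI segmentation

Movies are T×H×W stacks at a nominal 13 frames/s. Two paths:

- **Soma**: k-means (default k = 2, seeded, n_init = 10) on the
  time-averaged image; the brightest cluster is foreground and its
  connected components become ROIs. A constant image yields an empty mask
  with a warning.
- **Neurite**: k-means (default k = 3) on per-pixel time traces, z-scored
  per pixel so kinetics rather than brightness drive the clustering; the
  cluster whose centroid trace has the largest temporal variance (the
  coherent, stimulus-locked population) supplies the candidate pixels.
  Note one cluster is always occupied by background pixels, so separating
  m distinct response populations needs k = m + 1.

Masks are cleaned by a morphological opening (3×3 square, configurable),
which removes sub-element speckle and is idempotent. Only the most
responsive ROI — largest mean event-locked peak ΔF/F, ties to the lowest
label — is kept for analysis. Labels are contiguous 1..K, background 0;
coordinates are row-major, 0-based, pixel-centered.

## ΔF/F metrics

Traces (per-frame ROI means) are smoothed with a cubic Savitzky–Golay
filter, default window 11 frames (~0.85 s at 13 Hz — well below the
indicator decay so peaks survive). Peak response per stimulus event:

    ΔF/F = (F_t − F_b) / F_b

with F_b the mean over [onset − 1 s, onset) and F_t the maximum over
(onset, onset + 5 s]; the onset frame belongs to neither window. Windows
are mapped to frames by nearest-frame rounding (13 and 65 frames at
13 Hz); events whose windows leave the trace raise an error, as does a
non-positive baseline. The maximum is taken on the smoothed trace —
smoothing after the max would not undo the upward bias of a max statistic,
so the order is fixed. ΔF/F is invariant to trace rescaling but not to
additive offsets; the exact offset relation is asserted in tests.

## Tuning curves, EC50, transfer function

A tuning curve is a subjects × conditions matrix with group mean and SEM
(sample SD/√n, n = flies). Per-subject normalization divides each row by
its maximum (excluding non-positive-maximum subjects with a warning); it is
idempotent and makes curves comparable across flies, neurons and behavior.

Intensity–response data are fit with a four-parameter logistic
R(I) = floor + (ceiling − floor)/(1 + exp(−s(I − EC50))), unconstrained,
least squares with multi-start EC50 initialization at the data quartiles.
EC50 is the half-maximal intensity by construction. Flat data
(ceiling ≈ floor) and EC50 estimates outside the data span ± one span are
flagged, never silently reported.

The transfer function between two neurons' tuning curves is the
element-wise ratio of group means with first-order error propagation,

    SEM_i = |ratio_i| · √((SEM_num/μ_num)² + (SEM_den/μ_den)²),

assuming independent samples (the curves come from different flies and
genotypes). Conditions with a near-zero denominator are dropped with a
warning. Tests confirm the first-order formula tracks a
bootstrap-over-subjects SEM within 20% at realistic noise.

## Statistics

- **Permutation correlation test**: Pearson r between two condition-mean
  curves; the null permutes the condition labels of one curve. With n
  conditions the test enumerates all n! orders when n! ≤ 5×10⁵ (exact,
  seed-independent; the identity order counts itself, so p ≥ 1/n!);
  otherwise seeded Monte Carlo with the add-one correction
  p = (1 + hits)/(1 + n_perm), default 10,000 draws. Default one-sided
  (positive r) for tuning–behavior correlations.
- **Meng's z** (Meng–Rosenthal–Rubin) compares two dependent correlations
  sharing a criterion; the predictor–predictor correlation r_x is an
  explicit input (taken as the correlation between the two neural curves
  on the shared IPI grid when run through the report pipeline). The
  implementation is validated against its closed-form independent-Fisher-z
  limit and by a trivariate-normal null simulation (z ≈ N(0,1), 5%
  type-I rate).
- **Wilcoxon** rank-sum and signed-rank delegate to scipy: exact
  enumeration for tie-free samples up to combined n = 20, tie-corrected
  normal approximation beyond; zero paired differences are dropped, and
  all-zero differences return p = 1 by convention. A Holm correction
  helper exists but is off by default, matching panel-wise testing.

## Synthetic data generator

The generator emulates the study's data-generating process:

- **Tuning models.** vPN1-like responses are a saturating Hill curve of
  IPI (defaults r_max = 1, K = 20 ms, h = 2.5: about a third of maximum at
  15 ms, a shoulder near 35 ms, saturation above). pC1-like and behavioral
  responses are band-pass Gaussians (center 50 ms, width 15 ms, baseline
  0.05: strong at 35–65 ms, attenuated at both extremes). These defaults
  were chosen so the planted curves reproduce the qualitative regimes the
  pipeline is meant to detect — including a transfer function (band-pass /
  low-pass) attenuated below 25 ms and above 75 ms relative to 35 ms.
- **Indicator kernel.** A double exponential
  (1 − e^(−t/τ_rise))·e^(−t/τ_decay), peak-normalized, τ_rise = 0.08 s,
  τ_decay = 0.6 s — order-of-magnitude GCaMP6m kinetics, configurable.
- **Movies.** Gaussian-blob somata (SD 2.5–3 px, peak 100 over baseline
  20) on 48×48–128×128 fields at 13 Hz. Within a blob's 3σ support, pixel
  fluorescence is (baseline + blob)·(1 + ΔF/F(t)), so the pipeline's
  measured peak ΔF/F equals the planted amplitude exactly in the
  noise-free case. Noise is Gaussian with SD ∝ √intensity (shot-noise
  like), equal to `noise_sd` at background. The ground-truth ROI *extent*
  used for recovery scoring is the blob's ~28.5%-of-peak contour — the
  asymptotic 2-means decision boundary derived in `synth.py` — because a
  Gaussian blob has no sharper well-defined extent for intensity-based
  segmentation.
- **Tuning tables.** Per-subject responses tuning(IPI)·gain_j + noise,
  with lognormal gain jitter (log-SD 0.2) across subjects; this
  heterogeneity is what motivates per-fly max normalization.
- **Chaining counts.** Per 3-s sample, count ~ Binomial(6, p) with
  p = p_sil + (p_max − p_sil)·w(IPI)·logistic(s·(dB − EC50)); planted
  EC50 = 70.6 dB, slope 0.5/dB, p_max = 0.85, p_sil = 0.02. After song
  offset the above-silence drive decays exponentially (τ = 30 s), so
  chaining persists and fades. Fly–fly dependence within a chain is
  ignored — a documented simplification, adequate for mean-level recovery
  but not for count overdispersion.

What passing recovery tests on these data do **not** show: robustness to
motion artifacts, bleaching, neuropil contamination, non-Gaussian soma
shapes, or correlated behavioral counts — none of which the generator
emulates (motion correction and bleach correction are out of scope).

## Problem sizes and numerical choices

The test suite runs its recovery checks at deliberately modest sizes chosen
as representative of the method's operating regime: 48×48 movies of ~960
frames with two planted somata, 6–12 subjects per dataset, 9-point IPI
grids, 20-seed Monte-Carlo medians, and a 100-seed regime check for the
tuning–behavior permutation test (Monte-Carlo p with 2,000 draws per
seed). Deterministic seeds flow from the ground-truth object or the test;
k-means uses seeded multi-start (n_init = 10), so masks are bit-identical
across reruns. Ties in most-responsive-ROI selection break to the lowest
label; permutation p-value comparisons use a 10⁻¹² tolerance when counting
tail events to make exhaustive enumeration robust to float rounding.

## Known limitations

- The permutation test treats condition means as the unit of exchange;
  subject-level resampling is out of scope.
- The EC50 fit reports the 4PL midpoint; if the true response is not
  logistic in dB the estimate is a fitted summary, not a threshold.
- The transfer-function SEM assumes independent numerator and denominator
  samples; shared-subject designs would need the covariance term.
- Chain detection from video is upstream of this package; it consumes
  counts.
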