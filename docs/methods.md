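# Methods

This note records the models, conventions and numerical choices behind
`dfssmvep`, and what the synthetic-data experiments do and do not
demonstrate.

## Stimulus coding

A monitor refreshing at `Rr` frames/s can only reverse a reciprocal motion
on frame boundaries, so a motion frequency `f` is realised by sampling a
50%-duty square wave at frame instants: frame `i` holds +1 iff
`frac(f·i/Rr) < 1/2` (the `scipy.signal.square` convention, half-open on
the phase interval `[0, π)`, frame origin `i = 0`).  The half-open
convention matters: the closed variant "+1 when `sin θ ≥ 0`" lands the
exact zero `sin π = 0` on a frame whenever `Rr/(2f)` is an integer and
produces lopsided 7/5 half-cycles where 6/6 is intended.  Frequencies not
dividing `Rr` yield asymmetric half-cycles naturally from the sampling; no
extra rounding is applied.  The perceptual bound `f ≤ Rr/k` (at least `k`
frames per half-cycle) is exposed with `k` configurable, default 3 — at
60 Hz that admits the 5–9.5 Hz frequencies used throughout.

The coding algorithm pairs each of `N ≥ 5` targets with one base frequency
and one midpoint, staggered (`a = f₁, f₃, …, f_N, f₂` against
`b = g_{N−1}, g₁, …, g_{N−2}, g_N`) so that any two targets share at most
one adjacent frequency.  "Adjacent" is implemented as the stated relation:
`gᵢ` is adjacent to its flanking `fᵢ, fᵢ₊₁`, and the out-of-band `g_N` to
`f_N` alone.  An alternative reading — neighbourhood in the sorted union
of all 2N frequencies — validates the same worked plan; the audit
implements the stated relation only.  The audit is report-only (counts per
target pair, offenders listed) so deliberately bad plans can be examined.
For `N < 5` the coder refuses: the staggering needs at least five slots,
and extrapolating it would silently change the adjacency guarantee.
Frequency comparisons use an absolute tolerance of 1e-9 Hz.

## Preprocessing

Band-pass: Chebyshev type-I, order 4, 0.5 dB passband ripple, 2–40 Hz,
applied forward–backward (`sosfiltfilt`, even-reflection padding) for zero
net phase.  Order and ripple are engineering defaults — low enough ripple
not to distort evoked amplitudes, sharp enough to crush DC and 60 Hz line
components (the two-pass magnitude response doubles both ripple and
attenuation); both are keyword-configurable.  Trials shorter than three
times the filter's edge-padding length are rejected rather than filtered
badly.  Epochs are half-open `[start, start+length)` in samples, counts
rounded down, 0-based.  No artifact rejection or re-referencing is
performed.

## Decoding

The first canonical correlation between the channels-by-samples matrix `X`
and a reference matrix `Y` is computed by Cholesky-whitening the two
auto-covariances and taking the leading singular value of the whitened
cross-covariance.  Both auto-covariances receive a ridge of
`1e-10 · trace/dim`: large enough that rank-deficient cases (constant
channels, duplicated reference rows, very short windows) stay well-posed,
small enough that ρ's invariance under invertible channel mixing — a
defining property of CCA — survives to ~1e-11.  A larger ridge would
perturb ρ at its own order and erode that invariance.  Only the first
canonical pair is used.

Reference time runs `t = 1/fs … m/fs` (1-based sample times).  The choice
is observationally irrelevant — shifting `t` by any constant leaves every
score unchanged because the sin/cos pair spans the same subspace — but is
fixed for reproducibility and tested.

Harmonic count: default `N_h = 2`, which for 5–9.5 Hz stimulation keeps
fundamentals, second harmonics (10–19 Hz) and sum frequencies
(13.5–15.5 Hz) inside the 2–40 Hz passband.  `select_harmonics` offers the
empirical route: a harmonic counts as present when its Welch-PSD peak
exceeds the local noise floor (median within ±5 Hz, peak bins excluded) by
a configurable factor, default 3.

BCCA scores each target by the mean ρ_a of three correlations (against
y₁, y₂ and the combined y_c with the sum-frequency pair; only the sum
term is added — no difference or cross terms).  It is applied to the
band-pass-filtered multi-channel trial directly, with no spatial-filtering
front end.  Ties in the argmax go to the lowest target index and are
logged.  When plain CCA is used on dual-frequency data (`decode_trials`
with `method="cca"`), the per-target candidate defaults to the target's
secondary (rotation) frequency: a deliberate single-frequency baseline
that exposes the failure mode BCCA is designed to fix — trials where only
one of the two evoked peaks is prominent.

Welch PSD defaults: Hamming window, `L = fs` samples (1 s), 50% overlap,
periodograms normalised by the window power `P0 = mean w²(n)` (scipy's
`density` scaling).  Tests that must resolve 0.5 Hz-spaced midpoints use
`L = 2·fs` so those frequencies fall on the grid.

## Evaluation

ITR follows the standard K-choice formula with `0·log₂0 ≡ 0`.  `T` is the
caller-supplied selection time, default the epoch window alone, with an
optional `rest_time` added — the reference operating points
(σ = 0.925 → 30.6 bits/min, σ = 0.8438 → 23.73, σ = 0.8188 → 21.89 at
K = 5) are all consistent with `T = 3.5 s` and no rest term.  Note the
bracket's minimum is exactly at chance σ = 1/K, where the rate is zero;
it is never negative (below-chance accuracies are logged, not clamped).

Per-class indices come in two flavours of "precision": the usual
TP/(TP+FP), and a per-class accuracy (TP+TN)/total; both are reported
under those names.  Indices with a zero denominator (a class never
present) are NaN and logged, never silently 0.  A useful identity: the
per-class accuracies average to `(2σ + K − 2)/K ≥ σ`, which the property
tests verify.

## Synthetic data generator

The generator is the package's test fixture for decoder behaviour; no
claim is made that it reproduces real EEG beyond the features listed
here.  Per trial, the evoked component is

    Σ_h decay^(h−1) · sin(2π h f₁ t + φ) + β · Σ_h decay^(h−1) · sin(2π h f₂ t + φ′)

with `N_h,signal = 2` harmonics, decay 0.5, independent uniform phases per
component per trial, and optional sum-frequency term (default amplitude 0,
since the strength of a genuine f₁+f₂ component in real recordings is not
established).  β (`amplitude_imbalance`, default 1) attenuates the
secondary frequency to emulate trials where one peak dominates.

Background noise mixes, per channel: pink noise `1/f^α` (α = 1) with a
1 Hz spectral knee (real EEG spectra flatten at low frequency; without the
knee most noise power would sit below the 2 Hz passband edge and the
nominal SNR would be misleading), a 20% white (sensor) fraction, and a
10 Hz alpha sinusoid with shared phase and per-channel amplitude jitter
(relative amplitude 0.5) — alpha is the dominant structured interferer at
parieto-occipital sites.  Channels share a common noise source with
correlation 0.6 plus independent components, reflecting volume conduction;
spatially coherent noise is what keeps a multi-channel decoder from
averaging the background away, and without it the low-SNR behaviour of
CCA is unrealistically good.  Noise is normalised to unit average channel
power and the evoked component scaled so evoked/noise power on the
average channel equals `snr_db` (default 0 dB; `−inf` gives pure noise).

Datasets follow the protocol shape subjects × sessions × targets ×
trials (default 10×2×5×4 = 400).  Per subject, multiplicative channel
gains are drawn once (lognormal, σ = 0.2) and the SNR jittered by
N(0, 2 dB).  A single global seed expands to one counter-based substream
per trial (`default_rng([seed, stream, subject, session, target, trial])`),
so any individual trial is reproducible in isolation and identical
seed+config is bit-identical.

What passing tests show: the decoder chain is correct on signals whose
generative structure matches its reference model, degrades monotonically
with SNR, and reaches chance when the evoked component is masked.  What
they do not show: robustness to non-linear, non-stationary real EEG,
inter-subject variability beyond gain/SNR jitter, or artifacts (blinks,
EMG) — none of which the generator emulates.

## Problem sizes and tolerances

The test suite runs the full 400-trial default protocol for recovery
checks (≥95% at +10 dB; within a 3σ binomial band of 20% chance at
−20 dB), 200-trial datasets for the imbalance ordering (β = 0.25) and the
five-level SNR monotonicity sweep (+10, 0, −5, −10, −20 dB, common random
substreams), and 50 seeds for the dual-peak spectral signature of the
(8, 6.5) Hz target.  The CCA grid-search oracle uses 4000 unit-vector
angles on 2×2 instances (quantisation error ≪ the 1e-3 comparison
tolerance).  Mixing-invariance tests draw invertible matrices with
condition number ≤ 4 (orthogonal × diagonal × orthogonal); for
near-singular mixings no finite-precision CCA is invariant at 1e-9.

## Known limitations

- The generator's evoked model is linear and phase-random; it cannot probe
  non-linear detection methods.
- EDF support is read-only (via MNE); there is no EDF writer.
- The decoder is synchronous: trial onsets are assumed known; no
  asynchronous/online operation.
- Spatial filtering front-ends (e.g. maximum-contrast combination) and
  supervised classifiers on the bifold feature vector are out of scope.
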