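# Methods

This note documents the models, parameters and numerical choices behind
`eegduo`: what the synthetic sessions emulate, how each analysis stage is
defined, and where the design was genuinely open.

## 1. Synthetic paired sessions

A session is a pair of 14-channel, 128 Hz recordings — a laboratory-grade
system ("HQ") and a portable low-cost system ("LC") — sharing identical
neural content and differing only in acquisition properties.

**Neural content.**

* *Evoked responses.* Each ERP component is a Gaussian-windowed half-wave,
  `polarity * amplitude * exp(-(t - latency)^2 / (2 width^2))`, scaled per
  channel by a frontal-dominant weight map (F3/F4 = 1.0 down to F7/F8 =
  0.5).  The Gaussian shape makes the ground-truth peak latency exactly
  the template latency, which is what recovery tests need.  Defaults:

  | component | polarity | latency (ms) | amplitude (μV) | width (ms) |
  |---|---|---|---|---|
  | N1 | − | 109 | 5.0 | 15 |
  | P1 | + | 164 | 6.0 | 18 |
  | N2 | − | 256 | 4.5 | 30 |

  Latencies are the group means reported for the HQ system in this
  paradigm; amplitudes and widths are typical frontal visual-ERP values
  (the source study prints no single-subject waveform parameters).  The
  Go/NoGo template multiplies the NoGo N2 by 1.6 (response-inhibition
  effect); the semantic-task template has N1 at 132 ms and P1 at 193 ms
  and no condition effect.

* *Alpha oscillation.* A narrowband 8–12 Hz carrier (band-limited white
  noise normalised to unit Hilbert envelope; three normalise/band-limit
  iterations leave ≥95% of power in band) is multiplied by a long-range
  correlated envelope: fractional Gaussian noise with Hurst exponent `H`
  (spectral synthesis, power ∝ f^(1−2H)), low-passed at half the band
  width (an oscillation confined to a 4 Hz band cannot physically carry
  faster envelope fluctuations), then mapped affinely to
  `mean * (1 + 0.3 z)` and floored at 5% of the mean.  The floor is ~3 sd
  away, so the scaling exponent of the envelope is preserved; DFA on the
  generated envelope recovers `H` to within ±0.07 at 300 s.  A
  fixed-frequency sinusoidal carrier is deliberately avoided: with an
  exactly periodic trial schedule it stays phase-locked to stimulus onsets
  and never averages out of ERPs, which real (phase-drifting) alpha does.
  Channel weights are occipital-dominant (O1/O2 = 1.0, P7/P8 = 0.5).

* *Background noise.* Per system and channel: white Gaussian noise
  (sd 15 μV) plus 1/f-shaped noise (spectral exponent 1, sd 5 μV).  This
  "moderate SNR" puts the single-trial evoked peak ~10 dB below the
  background, typical of scalp EEG.

**Acquisition model.**

* *Band-pass.* Both systems band-pass 0.5–40 Hz at acquisition
  (zero-phase order-4 Butterworth in the simulation).
* *Marker delay.* The LC system's event markers are written
  `marker_delay_ms` **before** the corresponding response appears in its
  stream (the marker comes from the stimulus computer; the signal arrives
  over a wireless link).  The delay is applied to the marker positions,
  not by shifting the signal, so both recordings carry identical signal
  arrays apart from noise.  An optional per-trial jitter (`jitter_sd_ms`,
  default 0) is exposed for sensitivity analysis; the delay of the real
  headset is reported as constant.
* *Clock drift.* Stimulus-clock onset times are stretched by
  `1 + 50 ppm` before mapping to samples.  Without this, an exactly
  periodic 1 s trial schedule pins every onset to a single phase of the
  7.8 ms sample grid and an injected 82 ms delay quantises to 78.1 ms;
  with drift — as with real asynchronous clocks — onsets sweep through
  all phases and the injected delay is preserved in expectation.

**Schedules.** Go/NoGo: nine blocks of 90 trials, exact 70/30 Go/NoGo
counts per block in seeded random order, 1 s trials (200 ms stimulus),
5 s lead-in.  Semantic: 108 single-condition trials in six blocks, 2 s
trials.  Exact per-block counts (not i.i.d. draws) keep small simulations
deterministic in composition.

## 2. Preprocessing

Common-average re-referencing of the continuous signal; epoching over the
half-open window `[onset−200 ms, onset+800 ms)` with the onset sample at
t = 0 and ms→samples by `round(ms/1000*fs)`; baseline subtraction of the
mean over [−200, 0] ms; automatic rejection of trials with any sample
beyond ±100 μV (Go/NoGo) or ±80 μV (semantic).  ERP analysis then
re-references epochs to the mean of P7/P8 (mastoid proxies).  The
rejection threshold is applied on average-referenced epochs, before the
P7/P8 re-reference; the order is configurable.

## 3. ERP measurement

N1 and P1 are detected on the average of all conditions pooled (trial
counts, not condition means, weight the average); N2 on the NoGo−Go
difference wave.  Search windows are per task and system:

| task | system | N1 | P1 | N2 |
|---|---|---|---|---|
| Go/NoGo | HQ | 80–150 | 130–200 | 200–300 |
| Go/NoGo | LC | 175–245 | 240–310 | 290–390 |
| semantic | HQ | 100–170 | 160–230 | — |
| semantic | LC | 170–250 | 240–310 | — |

A peak is the largest interior local extremum of matching polarity; both
neighbours must lie inside the waveform (boundary clipping can never pose
as a peak), equal-amplitude ties resolve to the earliest, and a
wrong-signed extremum counts as not found.  Two estimator refinements are
used by the pipeline (both standard practice, both off-by-default at the
low-level `detect_peak`/`average_erp` layer):

* average waveforms are low-passed at 20 Hz (zero-phase) before peak
  picking, and
* the latency/amplitude are refined by a 3-point parabolic fit at the
  extremum, giving sub-sample latencies.

The pipeline additionally measures peaks on the *denoised* condition
averages (section 4): denoising is linear, so this equals averaging the
denoised single trials, and it roughly halves the latency scatter of the
broad N2 at single-session trial counts.  Even so, the N2 latency of one
session pair retains an irreducible sd of ~15 ms — consistent with the
15–30 ms cross-subject latency sds reported for this component — which is
why delay-recovery checks quote a one-sample tolerance on the *mean* over
components and remain stochastic at the margins.

Inter-peak intervals (P1−N1, N2−P1) are latency differences and are
invariant to any constant acquisition delay — the central analytical
argument for correcting rather than discarding delayed recordings.

## 4. Single-trial correction (tcERP)

Trials are decomposed with a **stationary** (undecimated) wavelet
transform, four detail scales plus the approximation, `bior3.3`
(compactly supported B-spline family).  The undecimated transform is a
deliberate choice: with a decimated DWT, two recordings whose evoked
responses are offset by an acquisition delay fall on different phases of
the dyadic grid, and the reconstruction ringing differs systematically
between systems, biasing single-trial latency estimates by ~1–2 samples.
Translation invariance removes that bias.

Coefficient selection (normalise-and-threshold): per cell, score =
|across-trial mean| / (across-trial SEM); cells with score > 3 are kept.
Noise-only cells have mean ≈ 0 and fall below threshold (~0.3% false
selection on pure noise); phase-locked evoked energy survives.  One mask
is selected per system per task from the pooled trials of both conditions
and reused for every condition, and cells with zero variance are kept iff
their mean is non-zero (the noise-free limit).

Per-trial P1 is the largest positive interior local maximum of the
denoised ROI-mean waveform inside the system's single-trial window
(Go/NoGo HQ 130–200 ms, LC 240–310 ms; semantic HQ 100–230 ms).  Each
trial is shifted (edge-value padding, no wraparound) so its P1 lands on a
common target latency; trials with no interior maximum are flagged and
excluded from the time-corrected average.  The target defaults to the
median detected latency of the session, but the pipeline passes the HQ
median to **both** systems — a per-system median cannot remove the
inter-system delay, and a shared target makes tcERPs directly comparable
(residual inter-system peak differences ≤ 1 sample for delays up to
200 ms).

## 5. Resting-state spectra

Welch periodograms (4 s Hann segments, 50% overlap) restricted to
0.5–30 Hz; Parseval-consistent density in μV²/Hz.  Power is averaged
within three four-electrode ROIs (anterior AF3/AF4/F3/F4, central
FC5/FC6/T7/T8, posterior P7/P8/O1/O2; a fourth ROI mentioned once in the
source text conflicts with its own ROI definition and is not
implemented).  The alpha peak is the largest interior local maximum of
the ROI spectrum in 8–12 Hz (monotone spectra yield "not found");
relative beta power sums 15–30 Hz over the 0.5–30 Hz total with half-open
bins, so band partitions of the analysis range sum to exactly 1.

## 6. Long-range temporal correlations

The O1/O2 mean signal is band-passed 8–12 Hz with a zero-phase order-4
Butterworth (forward-backward; effective order 8, passband ripple-free,
≥90% of white-noise output power within 7–13 Hz), and the amplitude
envelope is the modulus of the analytic signal.  DFA (order 1): subtract
the envelope mean, cumulate into a profile, cut into 50%-overlapping
windows per window size τ, remove a least-squares line per window, pool
the RMS residual into F(τ).  The window grid is 20 log-spaced sizes from
1 s to min(280 s, N/4); the exponent is the least-squares slope of
log F vs log τ over the fit range (default: the whole grid).

"Significant power-law scaling" has no canonical test; the implemented
criterion flags a recording when the log-log fit has R² ≥ 0.97 **and**
the exponent exceeds 0.5 by more than `max(2×SE, 0.05)`.  The 0.05 margin
matters because the fit SE (~0.01) understates the realization spread of
the exponent (~0.035 for uncorrelated 300 s envelopes); the margin keeps
the false-positive rate on uncorrelated noise below ~10%.  Both knobs are
configuration.  Note that system noise inside the alpha band dilutes the
measured envelope exponent toward 0.5: a generator exponent of 0.75
yields pipeline estimates around 0.55–0.65 at resting amplitudes, with
the low-amplitude eyes-open condition occasionally falling below the
significance margin — the same "significant in most but not all
recordings" pattern seen in real data.

## 7. Statistics

Wilcoxon signed-rank (zeros dropped; exact null for ≤25 untied pairs,
normal approximation with tie correction otherwise; the z statistic is
always reported from the normal approximation; all-zero differences are a
degenerate case reported as p = 1), Mann–Whitney U (exact for small
untied samples), and Holm–Bonferroni step-down correction (adjusted
p-values monotone, capped at 1).  The condition contrast is a seeded
Monte-Carlo permutation test: per-trial amplitude = mean over the ROI
channels and the half-open test window (N2 windows: HQ 200–300 ms, LC
300–380 ms); observed statistic = NoGo−Go difference of condition means;
null = uniformly re-drawn label assignments;
p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1), so p is never 0.  Trials are
the permutation unit: at single-session scale, trial-level relabelling is
the faithful analogue of the original across-subject permutation of
condition data.

## 8. What the simulations do and do not show

The generator reproduces the features the analyses rely on: shared evoked
content with a constant marker-to-signal delay, a condition-modulated
frontal N2, occipital alpha with tunable envelope correlations, 1/f
background, realistic trial schedules and clock asynchrony.  It does not
simulate ocular or muscle artifacts (rejection stages are exercised with
synthetic spikes instead), volume-conduction topography beyond fixed
channel weights, inter-subject variability, behavioural errors, or the
128-channel original montage (sessions are synthesized directly in the
harmonized 14-channel, 128 Hz state).  Passing tests therefore validate
the *pipeline* — recovery of known ground truth under realistic noise —
not claims about any particular hardware.

## 9. Problem sizes and determinism

Default runs use the study's own sizes: 810-trial Go/NoGo sessions,
108-trial semantic sessions, 300 s resting segments, 1000 permutation
draws, 20-seed envelope ensembles.  The test suite scales some fixtures
down (60-trial sessions, 100 s envelopes) to keep it fast.  Every
stochastic stage takes an explicit seed, seeds derive from a single
session seed via `numpy.random.SeedSequence`, and reruns are
bit-identical; summary files carry a hash of their configuration.
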