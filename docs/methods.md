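# Methods

## The detection model

The observation unit is a stimulus-locked epoch of single-channel scalp
voltage. After preprocessing, each accepted epoch is reduced to the mean
voltage in p = 9 equal contiguous time bins spanning the response window
(default 100–550 ms post-stimulus, bracketing the neonatal P1 search span of
100–500 ms). Binning is a linear reduction, so the mean of binned epochs
equals the binned average waveform; under the no-response null hypothesis
every bin mean is zero.

With x_i ∈ R⁹ the binned epochs, x̄ their mean and S their unbiased sample
covariance, the one-sample Hotelling statistic is T² = N x̄ᵀ S⁻¹ x̄, and
(N − p) / (p (N − 1)) · T² follows F(p, N − p) exactly when the epochs are
i.i.d. multivariate normal — which holds for any stationary Gaussian noise
process, however strongly correlated across bins, because the rows are
independent. This exactness is what makes the p-values trustworthy at the
small-N end of the sequential schedule. For p = 1 the statistic reduces to
the squared one-sample t statistic (verified to 1e−9 against the t-test).

The sequential rule evaluates T² at every accepted-epoch count from
N_min = 50 to the cap N_max = 150: present immediately if p < 0.001
(stage "early"); otherwise at the cap, present iff p < 0.05 (stage
"final"). Fewer than 50 accepted epochs yields no verdict ("insufficient").
The early-stage tests are highly dependent (each adds one epoch), so the
overall null detection rate is only slightly above the final-stage level:
Monte Carlo calibration at 10,000 null runs puts it near 0.055 (≈ 0.05 final
+ ≈ 0.005–0.01 early spend), inside the accepted [0.04, 0.065] band. The
early-stage cadence (default: every accepted epoch) is configurable;
coarser cadences reduce the early alpha spend.

Covariance uses the N − 1 estimator, which is what ties the statistic to
the F reference; a singular covariance (e.g. constant bins) raises a
dedicated error rather than returning a spurious p-value.

## Residual noise and quality control

Residual noise is the RMS over samples of the standard error of the mean:
rn = √(mean_t(var(x_t)/N)), computed within the analysis window. For
independent noise of per-sample RMS σ it scales as σ/√N. Tiers: good
(rn ≤ 3.2 μV), slightly compromised (3.2 < rn ≤ 3.6), poor (rn > 3.6);
boundaries are inclusive on the lower tier. A poor recording invalidates a
present verdict. The gate is applied to the residual noise of the *final*
average (all accepted epochs up to the cap), not of the prefix at an early
statistical stop: stopping the test early does not excuse a noisy
recording, and a quiet recording is not penalised for having detected the
response quickly.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass, default
0.2–30 Hz — a conventional cortical-response band; the hardware filter
description in the source protocol is not interpretable as digital corner
frequencies, so the band is fully configurable and never asserted in tests.
Artifact rejection removes epochs whose absolute amplitude exceeds 150 μV
(peak-to-peak mode available); survivors are untouched and keep their
order. All-rejected inputs propagate as an explicit empty result.

## The staircase

The protocol starts at 80 dB HL (pathway-integrity check), probes 30, and
descends 30 → 15 → 5 → 0 while verdicts are present; the first absent
verdict at any descending level switches to a +5 dB ascent that stops at
the first present verdict — or at a level already known present, which is
never retested. The threshold is the lowest present intensity with an
absent verdict 5 dB below (0 dB HL needs no verdict below it). Absence at
80 dB HL reports "not reached (>80 dB HL)" rather than extrapolating. The
generalisation of the published descent/ascent branches to *any* descending
level is the minimal completion consistent with all stated branches; with a
noiseless monotone responder the procedure recovers every grid threshold
exactly (verified exhaustively for t ∈ {0, 5, …, 80}), never tests a level
twice, and never leaves the grid. Under noisy verdicts the reported
threshold is a property of the realized trace, not a truth claim; a
re-testing flag for doubtful levels is deliberately not enabled by default.

## P1 measurement

P1 is the highest positive local peak in 100–500 ms, amplitude
baseline-to-peak against the pre-stimulus mean (the single-peak neonatal
morphology has no canonical trough for a peak-to-trough reference). Before
peak location the average is low-pass smoothed at 10 Hz (zero phase).
Rationale: the P1 bump has ≈ 3 Hz bandwidth, so the smoothing attenuates it
by < 0.1%, while averaged noise occupying the full 0.2–30 Hz analysis band
otherwise dominates the location of the maximum — without smoothing the
peak latency can wander tens of ms even at residual noise well under 1 μV.
Ties between equally high peaks resolve to the earliest; peaks must exceed
0.1% of the waveform scale (a numerical guard against filtering ripple).
The latency–intensity description is an OLS line of latency on intensity;
its physiological sign is negative.

## The simulator

Each epoch is template + noise (+ artifact). The template is a positive
Gaussian bump — the minimal shape consistent with a "marked positive peak"
— with half-width-at-half-maximum 60 ms, centred at
lat(I) = lat₈₀ + slope · (80 − I) with slope default 1 ms/dB (the
latency–intensity relation is qualitative in the source material, so tests
assert monotonicity and sign, never the slope value). Amplitude is 0 below
the subject's true threshold and grows linearly in dB above it, anchored to
the subject's 80 dB HL value (growth exponent configurable). Because
amplitude is exactly 0 *at* threshold, a perfectly performing detector
estimates t + 5, and {t, t + 5} is the accuracy target for recovery checks.

Noise is Gaussian, band-limited to the analysis passband (0.2–30 Hz) and
rescaled — via the exact RMS gain of the finite-length zero-phase filtering
operator — so its per-sample RMS equals the subject's `noise_rms`; a pink
(1/f) option is available. Band-limited noise at a fixed per-sample RMS
concentrates power at low frequencies, which makes it the conservative
choice for waveform-level tasks (peak picking) while leaving the Hotelling
detector its full power, since T² whitens across bins. Artifacts are
±200 μV square pulses of 100 ms at random onsets with per-epoch probability
`artifact_rate` (default 0.02), sign-balanced so they do not bias the mean.

Epoch window −100 to +600 ms at 1000 Hz sampling. Hierarchical seeding
(cohort seed → per-subject → per-epoch-set via `SeedSequence.spawn`) makes
any subset reproducible in isolation.

Cohort defaults encode the published neonatal normative rows (`caep.norms`):
thresholds normal (per-frequency mean/SD), truncated to [0, 80] and rounded
to the 5 dB grid; amplitude anchors positive truncated normal; latency
anchors normal clipped to [100, 500] ms. Default noise_rms is 25 μV
(residual ≈ 2 μV at 150 epochs — a typical good recording) and the nominal
stimulus timing is a 40 ms tone burst (10 ms cosine rise/fall, 30 ms
plateau) at one stimulus per 1.125 s; the source protocol prints the
inter-stimulus interval as "1.125 ms" alongside a ~1 s stimulus period,
which is physically impossible for a 40 ms tone, so it is read as 1.125 s
(configurable).

What the simulator does *not* model: real EEG nonstationarity and
state-dependent noise (sleep stages, movement bursts), non-Gaussian
artifact morphology, electrode drift, multichannel structure, and any
acoustic calibration (dB HL is metadata). Passing tests therefore
demonstrate the statistical machinery and protocol logic under the stated
noise model, not clinical performance on recorded neonates.

## Study-scale choices in the tests

The validation suite runs at desk scale: null calibration uses 10,000
Monte-Carlo runs; end-to-end threshold recovery uses 100 staircases with
thresholds and latencies drawn from the population, amplitude anchors fixed
at the normative means and 2.5 μV epoch noise — a "high SNR" condition in
which every suprathreshold response is reliably detectable, so the residual
recovery errors are the staircase's own: the 5 dB quantisation and the
stopping rule's ≈ 5% per-level false-positive rate at subthreshold levels
(which occasionally ends a trace one step low). With heterogeneous
amplitude anchors, subjects drawn with anchors ≲ 3 μV have near-threshold
responses of ≲ 0.2 μV that no detector could find at these epoch counts;
that regime is a property of the generative model, not of the detector, and
is excluded from the recovery condition on purpose.

P1 parameter recovery is checked at residual noise ≤ 1 μV, where recovered
latency is within ±10 ms (in practice within ~2 ms after the 10 Hz
smoothing) and amplitude within ±15%.

## Known limitations

- The p-value exactness argument assumes Gaussian epochs; heavy-tailed
  residual artifacts that survive rejection inflate the false-positive rate.
- The sequential early stage spends extra alpha that depends on the test
  cadence; the implementation reports stagewise behaviour rather than
  claiming one nominal level.
- Ear laterality and other demographic metadata are carried but never used
  computationally.
- Behavioral-threshold correction offsets reported elsewhere for adults are
  not applied; the package reports electrophysiological thresholds only.
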