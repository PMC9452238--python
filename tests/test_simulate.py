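"""Simulator: intensity laws, determinism, noise scaling, cohort statistics."""
import numpy as np
import pytest

from caep.containers import FREQUENCIES_HZ, StimulusConfig
from caep.exceptions import DomainError
from caep.preprocess import residual_noise
from caep.simulate import (
    DEFAULT_HALF_WIDTH_MS,
    PopulationModel,
    SubjectModel,
    p1_amplitude,
    p1_latency,
    p1_template,
    simulate_cohort,
    simulate_epoch_set,
)


class TestIntensityLaws:
    def test_latency_at_80_equals_anchor(self, subject):
        assert p1_latency(80, subject, 1000) == pytest.approx(225.54)

    def test_latency_linear_in_intensity(self, subject):
        # slope 1.0 ms/dB: 50 dB below the anchor adds 50 ms
        assert p1_latency(30, subject, 1000) == pytest.approx(275.54)

    def test_zero_slope_keeps_latency_constant(self, subject):
        subject.latency_slope = 0.0
        lats = {p1_latency(i, subject, 1000) for i in range(0, 85, 5)}
        assert lats == {225.54}

    def test_latency_non_increasing_amplitude_non_decreasing(self, subject):
        grid = list(range(0, 85, 5))
        lats = [p1_latency(i, subject, 1000) for i in grid]
        amps = [p1_amplitude(i, subject, 1000) for i in grid]
        assert all(a >= b for a, b in zip(lats, lats[1:]))
        assert all(a <= b for a, b in zip(amps, amps[1:]))

    def test_amplitude_zero_below_threshold(self, subject):
        assert p1_amplitude(20, subject, 1000) == 0.0
        assert p1_amplitude(0, subject, 1000) == 0.0

    def test_amplitude_anchor_at_80(self, subject):
        assert p1_amplitude(80, subject, 1000) == pytest.approx(7.36)

    def test_amplitude_linear_interpolation(self):
        # threshold 30: halfway (55 dB) gives half the 80 dB anchor
        s = SubjectModel("x", {1000: 30.0}, {1000: 7.36}, {1000: 225.54})
        assert p1_amplitude(55, s, 1000) == pytest.approx(3.68)

    @pytest.mark.parametrize("intensity", [-5, 85, 100])
    def test_intensity_domain_errors(self, subject, intensity):
        with pytest.raises(DomainError):
            p1_latency(intensity, subject, 1000)
        with pytest.raises(DomainError):
            p1_amplitude(intensity, subject, 1000)


class TestEpochSets:
    def test_determinism_bit_identical(self, subject, stimulus):
        a = simulate_epoch_set(subject, stimulus, 20, seed=7)
        b = simulate_epoch_set(subject, stimulus, 20, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_different_seeds_differ(self, subject, stimulus):
        a = simulate_epoch_set(subject, stimulus, 20, seed=7)
        b = simulate_epoch_set(subject, stimulus, 20, seed=8)
        assert not np.array_equal(a.data, b.data)

    def test_nonpositive_epoch_count_rejected(self, subject, stimulus):
        with pytest.raises(DomainError):
            simulate_epoch_set(subject, stimulus, 0, seed=1)

    def test_window_and_shape(self, subject, stimulus):
        es = simulate_epoch_set(subject, stimulus, 5, seed=1)
        assert es.data.shape == (5, 700)
        assert es.t_start_ms == -100.0
        assert es.t_end_ms == 600.0

    def test_subthreshold_average_is_zero_mean(self, subject):
        """Below threshold the expected average waveform is 0 everywhere:
        per-sample deviations stay within 3 SE at the nominal exceedance
        rate.  Band-limited noise leaves few effective degrees of freedom
        per epoch, so many seeds are needed for a calibrated check."""
        stim = StimulusConfig(frequency_hz=1000, intensity_dbhl=10)
        means = [
            simulate_epoch_set(subject, stim, 30, seed=s).data.mean(axis=0)
            for s in range(200)
        ]
        grand = np.mean(means, axis=0)
        se = np.std(means, axis=0, ddof=1) / np.sqrt(len(means))
        assert np.mean(np.abs(grand) > 3 * se) <= 0.01

    def test_suprathreshold_average_recovers_template(self, subject, stimulus):
        es0 = simulate_epoch_set(subject, stimulus, 1, seed=0)
        template = p1_template(es0.times(), 225.54, 7.36, DEFAULT_HALF_WIDTH_MS)
        means = [
            simulate_epoch_set(subject, stimulus, 30, seed=s).data.mean(axis=0)
            for s in range(200)
        ]
        grand = np.mean(means, axis=0)
        se = np.std(means, axis=0, ddof=1) / np.sqrt(len(means))
        assert np.mean(np.abs(grand - template) > 3 * se) <= 0.01

    @pytest.mark.parametrize("n_epochs", [50, 100, 150])
    def test_residual_noise_scales_as_sigma_over_sqrt_n(self, subject, stimulus, n_epochs):
        sigma = subject.noise_rms
        rns = [
            residual_noise(simulate_epoch_set(subject, stimulus, n_epochs, seed=s))
            for s in range(8)
        ]
        assert np.mean(rns) == pytest.approx(sigma / np.sqrt(n_epochs), rel=0.10)

    def test_artifacts_injected_at_requested_rate(self, subject, stimulus):
        subject.artifact_rate = 0.5
        es = simulate_epoch_set(subject, stimulus, 200, seed=3)
        big = (np.abs(es.data).max(axis=1) > 150).sum()
        assert 60 <= big <= 140  # ~binomial(200, 0.5)


class TestCohort:
    def test_determinism(self):
        a = simulate_cohort(5, seed=11)
        b = simulate_cohort(5, seed=11)
        for sa, sb in zip(a, b):
            assert sa.true_threshold_dbhl == sb.true_threshold_dbhl
            assert sa.p1_latency_80 == sb.p1_latency_80

    def test_zero_variance_population_gives_the_means(self):
        pop = PopulationModel(
            threshold_sd={f: 0.0 for f in FREQUENCIES_HZ},
            amplitude_sd={f: 0.0 for f in FREQUENCIES_HZ},
            latency_sd={f: 0.0 for f in FREQUENCIES_HZ},
        )
        (s,) = simulate_cohort(1, pop, seed=0)
        assert s.true_threshold_dbhl[1000] == 25.0  # mean on the 5 dB grid
        assert s.p1_amplitude_80[1000] == pytest.approx(7.36)
        assert s.p1_latency_80[1000] == pytest.approx(225.54)

    def test_thresholds_on_grid_and_in_range(self):
        for s in simulate_cohort(30, seed=2):
            for t in s.true_threshold_dbhl.values():
                assert t % 5 == 0 and 0 <= t <= 80

    def test_cohort_mean_threshold_consistent_with_norms(self):
        """39 draws at defaults: 1000 Hz mean threshold within 2 SE of 25 dB HL."""
        cohort = simulate_cohort(39, seed=4)
        thr = np.array([s.true_threshold_dbhl[1000] for s in cohort])
        se = 9.03 / np.sqrt(39)
        assert abs(thr.mean() - 25.0) < 2 * se + 1.0  # +1 dB slack for grid rounding

    def test_invalid_population_rejected(self):
        with pytest.raises(DomainError):
            PopulationModel(threshold_sd={f: -1.0 for f in FREQUENCIES_HZ})


class TestSubjectValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"true_threshold_dbhl": {1000: 90.0}},
            {"p1_amplitude_80": {1000: -1.0}},
            {"p1_latency_80": {1000: 600.0}},
            {"latency_slope": -0.5},
            {"noise_rms": 0.0},
            {"artifact_rate": 1.0},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        base = dict(
            subject_id="b",
            true_threshold_dbhl={1000: 25.0},
            p1_amplitude_80={1000: 7.0},
            p1_latency_80={1000: 225.0},
        )
        base.update(kwargs)
        with pytest.raises(DomainError):
            SubjectModel(**base)
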