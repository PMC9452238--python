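"""Detection: binning, Hotelling's T2, and the sequential stopping rule."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from caep.containers import EpochSet
from caep.detect import (
    BinnedEpochs,
    DetectionConfig,
    bin_epochs,
    hotelling_t2,
    sequential_detect,
    sequential_test,
)
from caep.exceptions import (
    DegenerateCovarianceError,
    DomainError,
    InsufficientEpochsError,
)
from caep.simulate import simulate_epoch_set


def make_set(data, fs=1000.0, t_start=-100.0):
    return EpochSet(data=np.atleast_2d(data), fs=fs, t_start_ms=t_start)


class TestBinning:
    def test_constant_epoch_gives_constant_bins(self):
        es = make_set(np.full((3, 700), 2.5))
        b = bin_epochs(es, (100.0, 550.0), 9)
        assert b.data.shape == (3, 9)
        assert np.allclose(b.data, 2.5)

    def test_linear_ramp_matches_brute_force(self, rng):
        """Bin means of arbitrary data equal brute-force per-bin averages."""
        data = np.vstack([np.linspace(0, 1, 700), rng.normal(size=700)])
        es = make_set(data)
        b = bin_epochs(es, (100.0, 550.0), 9)
        t = es.times()
        for j in range(9):
            lo, hi = 100.0 + 50.0 * j, 100.0 + 50.0 * (j + 1)
            mask = (t >= lo) & (t < hi)  # half-open bins
            expected = data[:, mask].mean(axis=1)
            assert np.allclose(b.data[:, j], expected, atol=1e-12)

    def test_single_bin_is_window_mean(self, rng):
        data = rng.normal(size=(4, 700))
        es = make_set(data)
        b = bin_epochs(es, (100.0, 550.0), 1)
        t = es.times()
        mask = (t >= 100.0) & (t < 550.0)
        assert np.allclose(b.data[:, 0], data[:, mask].mean(axis=1))

    def test_window_outside_epoch_errors(self):
        es = make_set(np.zeros((2, 700)))
        with pytest.raises(DomainError):
            bin_epochs(es, (100.0, 700.0), 9)


class TestHotellingT2:
    def test_zero_mean_vector_gives_zero_statistic(self, rng):
        x = rng.normal(size=(20, 5))
        x -= x.mean(axis=0)  # exactly zero bin means, nonzero covariance
        t2, f, p = hotelling_t2(BinnedEpochs(x, (100.0, 550.0)))
        assert t2 == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_one_bin_equals_squared_t_test(self):
        """p=1: T2 on {1,2,3} is 12.0 and matches the one-sample t-test."""
        data = np.array([[1.0], [2.0], [3.0]])
        t2, f, p = hotelling_t2(BinnedEpochs(data, (0.0, 1.0)))
        assert t2 == pytest.approx(12.0)
        t_res = stats.ttest_1samp(data[:, 0], 0.0)
        assert t2 == pytest.approx(t_res.statistic**2)
        assert p == pytest.approx(t_res.pvalue, rel=1e-12)

    @given(st.integers(0, 10_000))
    def test_one_bin_t2_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2.0), size=(n, 1))
        t2, _, p = hotelling_t2(BinnedEpochs(x, (0.0, 1.0)))
        t_res = stats.ttest_1samp(x[:, 0], 0.0)
        assert t2 == pytest.approx(t_res.statistic**2, rel=1e-9)
        assert p == pytest.approx(t_res.pvalue, rel=1e-9)

    @given(st.integers(0, 10_000))
    def test_scale_invariance(self, seed):
        """T2 is unchanged by any common rescaling of all epochs."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0.3, 1.0, size=(25, 6))
        scale = float(rng.uniform(0.01, 100.0))
        t2a, _, _ = hotelling_t2(BinnedEpochs(x, (0.0, 1.0)))
        t2b, _, _ = hotelling_t2(BinnedEpochs(scale * x, (0.0, 1.0)))
        assert t2a == pytest.approx(t2b, rel=1e-9)

    def test_too_few_epochs(self, rng):
        with pytest.raises(InsufficientEpochsError):
            hotelling_t2(BinnedEpochs(rng.normal(size=(9, 9)), (0.0, 1.0)))

    def test_singular_covariance(self):
        x = np.ones((12, 3))  # zero variance in every bin
        with pytest.raises(DegenerateCovarianceError):
            hotelling_t2(BinnedEpochs(x, (0.0, 1.0)))


class TestSequentialRule:
    def test_strong_response_detected_early(self, subject, stimulus):
        from caep.pipeline import detect_response

        subject.noise_rms = 20.0
        raw = simulate_epoch_set(subject, stimulus, 180, seed=5)
        res = detect_response(raw)
        assert res.present
        assert res.stage == "early"
        assert 50 <= res.n_epochs <= 149
        assert res.p_value < 0.001

    def test_prefix_statistics_match_direct_evaluation(self, rng):
        """The cumulative-moment implementation agrees with hotelling_t2."""
        x = rng.normal(0.2, 1.0, size=(150, 9))
        b = BinnedEpochs(x, (100.0, 550.0))
        res = sequential_test(b, DetectionConfig(alpha_early=0.0))  # never stop early
        direct_t2, _, direct_p = hotelling_t2(b)
        assert res.t2 == pytest.approx(direct_t2, rel=1e-9)
        assert res.p_value == pytest.approx(direct_p, rel=1e-9)
        assert res.n_epochs == 150 and res.stage == "final"

    def test_early_stop_at_first_crossing(self, rng):
        x = rng.normal(0.0, 1.0, size=(150, 9))
        x[:, :] += 0.0
        cfg = DetectionConfig()
        res = sequential_test(BinnedEpochs(x, (100.0, 550.0)), cfg)
        if res.stage == "early":
            # re-evaluate the prefix directly: it must cross alpha_early
            t2, _, p = hotelling_t2(BinnedEpochs(x[: res.n_epochs], (100.0, 550.0)))
            assert p < cfg.alpha_early

    def test_below_minimum_is_insufficient(self, rng):
        x = rng.normal(size=(40, 9))
        res = sequential_test(BinnedEpochs(x, (100.0, 550.0)))
        assert res.stage == "insufficient" and not res.present

    def test_exhausted_between_min_and_max_is_insufficient(self, rng):
        x = rng.normal(size=(90, 9))
        res = sequential_test(BinnedEpochs(x, (100.0, 550.0)))
        assert res.stage in ("early", "insufficient")

    def test_poor_quality_blocks_present_verdict(self, subject, stimulus):
        """Residual noise above 3.6 uV refuses a present verdict."""
        subject.noise_rms = 4.0 * np.sqrt(150)  # residual ~4 uV at the cap
        raw = simulate_epoch_set(
            subject, stimulus, 150, seed=2, noise_band_hz=None
        )  # unfiltered noise so the pipeline filter cannot remove it
        res = sequential_detect(raw)
        assert res.residual_noise > 3.6
        assert res.quality.value == "poor"
        assert not res.present

    def test_detection_power_monotone_in_amplitude(self, subject):
        """Power is non-decreasing along an amplitude grid at fixed noise."""
        from caep.containers import StimulusConfig
        from caep.pipeline import detect_response
        from caep.simulate import SubjectModel

        rates = []
        for amp in (0.05, 0.3, 2.0):
            sub = SubjectModel(
                "a", {1000: 0.0}, {1000: amp}, {1000: 225.54},
                noise_rms=25.0, artifact_rate=0.0,
            )
            stim = StimulusConfig(frequency_hz=1000, intensity_dbhl=80)
            hits = sum(
                detect_response(simulate_epoch_set(sub, stim, 150, seed=s)).present
                for s in range(12)
            )
            rates.append(hits)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 12  # 2 uV against 2 uV residual noise is certain
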