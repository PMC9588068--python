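import numpy as np
import pytest
from scipy import signal

from pitchcomp.core import FoTrajectory
from pitchcomp.modulation import (
    band_sos,
    batch_trajectory_sds,
    center_and_fill,
    extract_component,
    filter_bank_centers,
    modulation_spectrum,
    trajectory_sds,
    upsample_double,
    variability_difference,
    variability_index,
)
from pitchcomp.synthetic import simulate_trajectory
from conftest import make_traj


def sine_traj(freq, amp=20.0, duration=10.0, rate=100.0):
    t = np.arange(0, duration, 1 / rate)
    return amp * np.sin(2 * np.pi * freq * t)


class TestCenterAndFill:
    def test_missing_becomes_zero(self):
        out = center_and_fill(make_traj([10, 10, None]))
        assert np.allclose(out, [0, 0, 0])

    def test_zero_centering(self):
        assert np.allclose(center_and_fill(make_traj([0, 20])), [-10, 10])

    def test_voiced_mean_zero_property(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            values = rng.normal(1200, 50, 100)
            values[rng.random(100) < 0.2] = np.nan
            traj = make_traj(values)
            out = center_and_fill(traj)
            assert abs(out[traj.voiced].mean()) < 1e-9

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            center_and_fill(make_traj([None, None]))


class TestUpsampleDouble:
    def test_midpoints(self):
        out = upsample_double(np.array([0.0, 2.0]))
        assert np.allclose(out, [0.0, 1.0, 2.0, 2.0])

    def test_constant_stays_constant(self):
        assert np.allclose(upsample_double(np.full(10, 3.3)), 3.3)

    def test_sinusoid_rms_preserved(self):
        x = sine_traj(3.0)
        up = upsample_double(x)
        assert len(up) == 2 * len(x)
        assert np.std(up) == pytest.approx(np.std(x), rel=0.01)


class TestExtractComponent:
    def test_2hz_passes_slow_blocked_by_fast(self):
        x = sine_traj(2.0, amp=20.0)
        target = 20.0 / np.sqrt(2)
        assert np.std(extract_component(x, 100, "slow")) == pytest.approx(target, rel=0.05)
        assert np.std(extract_component(x, 100, "fast")) < 0.05 * np.std(x)

    def test_10hz_passes_fast(self):
        x = sine_traj(10.0, amp=20.0)
        assert np.std(extract_component(x, 100, "fast")) == pytest.approx(20 / np.sqrt(2), rel=0.05)

    def test_zero_in_zero_out(self):
        assert np.allclose(extract_component(np.zeros(100), 100, "slow"), 0.0)

    def test_zero_phase_no_peak_shift(self):
        # a burst's peak must stay put under zero-phase filtering
        t = np.arange(0, 10, 0.01)
        burst = np.exp(-0.5 * ((t - 5) / 0.5) ** 2) * np.sin(2 * np.pi * 2 * t)
        out = extract_component(burst, 100, "slow")
        assert abs(int(np.argmax(np.abs(out))) - int(np.argmax(np.abs(burst)))) <= 1

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            extract_component(np.zeros(5), 100, "slow")


class TestFilterBank:
    def test_28_quarter_octave_centers(self):
        centers = filter_bank_centers()
        assert len(centers) == 28
        assert np.allclose(centers, 0.4 * 2 ** (np.arange(28) / 4))
        assert centers[-1] <= 50.0
        assert np.all(np.diff(centers) > 0)

    def test_2hz_probe_peaks_at_nearest_band(self):
        x = upsample_double(sine_traj(2.0, amp=20.0))
        spec = modulation_spectrum(x, rate=200.0)
        assert spec.peak_frequency in (pytest.approx(1.902, abs=0.01), pytest.approx(2.263, abs=0.01))
        assert spec.band_rms.max() == pytest.approx(20 / np.sqrt(2), rel=0.25)
        far = np.abs(np.log2(spec.center_frequencies / 2.0)) >= 2.0
        assert spec.band_rms[far].max() < 0.07 * spec.band_rms.max()

    def test_band_rms_matches_frequency_response_oracle(self):
        """Band RMS of a pure tone equals |H(f)|^2 * A/sqrt(2) from the
        filter's own frequency response (squared: forward + backward pass)."""
        freq, amp, rate = 2.0, 20.0, 200.0
        x = upsample_double(sine_traj(freq, amp=amp))
        spec = modulation_spectrum(x, rate=rate)
        checked = 0
        for fc, rms in zip(spec.center_frequencies, spec.band_rms):
            w, h = signal.sosfreqz(band_sos(fc, rate), worN=[2 * np.pi * freq / rate])
            expected = np.abs(h[0]) ** 2 * amp / np.sqrt(2)
            if expected < 0.05 * amp / np.sqrt(2):
                continue  # strongly attenuated bands are dominated by edge transients
            assert rms == pytest.approx(expected, rel=0.25)
            checked += 1
        assert checked >= 3

    def test_white_noise_band_rms_grows_with_bandwidth(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(4000)
        spec = modulation_spectrum(x, rate=200.0)
        # bandwidth ~ fc, so band RMS should trend as sqrt(fc): check the
        # regression slope of log RMS on log fc is near 0.5
        slope = np.polyfit(np.log(spec.center_frequencies), np.log(spec.band_rms), 1)[0]
        assert 0.3 < slope < 0.7

    def test_zero_input_zero_spectrum(self):
        spec = modulation_spectrum(np.zeros(800), rate=200.0)
        assert np.allclose(spec.band_rms, 0.0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            modulation_spectrum(np.zeros(100), rate=200.0)


class TestVariabilityIndex:
    def test_constant_trajectories_zero(self):
        trajs = [make_traj(np.full(200, 1200.0)) for _ in range(3)]
        v = variability_index(trajs)
        assert v.whole == v.slow == v.fast == 0.0
        assert v.n_trials == 3

    def test_pure_2hz_sinusoid(self):
        traj = make_traj(1200 + sine_traj(2.0, amp=10.0, duration=2.0))
        v = variability_index([traj])
        assert v.whole == pytest.approx(10 / np.sqrt(2), rel=0.06)
        assert v.slow == pytest.approx(v.whole, rel=0.1)
        assert v.fast < 0.05 * v.whole

    def test_generator_magnitudes_recovered(self, noisy_subject):
        trajs = [simulate_trajectory(noisy_subject, seed=s) for s in range(10)]
        v = variability_index(trajs)
        assert v.slow == pytest.approx(13.0, rel=0.10)
        assert v.fast == pytest.approx(3.5, rel=0.10)
        assert v.whole == pytest.approx(np.hypot(13.0, 3.5), rel=0.10)

    def test_quadrature_decomposition(self, noisy_subject):
        trajs = [simulate_trajectory(noisy_subject, seed=100 + s) for s in range(10)]
        v = variability_index(trajs)
        assert v.whole**2 == pytest.approx(v.slow**2 + v.fast**2, rel=0.15)

    def test_batch_matches_single(self, noisy_subject):
        trajs = [simulate_trajectory(noisy_subject, seed=s) for s in range(5)]
        trajs[2].values[30:40] = np.nan
        batch = batch_trajectory_sds(trajs)
        single = np.array([trajectory_sds(t) for t in trajs])
        assert np.allclose(batch, single, equal_nan=True)

    def test_no_trials_raises(self):
        with pytest.raises(ValueError):
            variability_index([])


class TestVariabilityDifference:
    def test_identical_pairs_zero(self, noisy_subject):
        t = simulate_trajectory(noisy_subject, seed=0)
        for component in ("whole", "slow", "fast"):
            assert variability_difference([(t, t)], component) == 0.0
        assert np.allclose(variability_difference([(t, t)], "subbands"), 0.0)

    def test_compensation_ramp_adds_slow_variability(self, noisy_subject):
        pairs = []
        for s in range(8):
            first = simulate_trajectory(noisy_subject, seed=s)
            second = simulate_trajectory(
                noisy_subject, shift=100.0, vocalization_index=2, seed=1000 + s
            )
            pairs.append((first, second))
        d_slow = variability_difference(pairs, "slow")
        d_fast = variability_difference(pairs, "fast")
        assert d_slow > 2.0
        assert abs(d_fast) < 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            variability_difference([], "slow")
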