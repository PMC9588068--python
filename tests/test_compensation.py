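import numpy as np
import pandas as pd
import pytest

from pitchcomp.compensation import (
    baseline_align,
    detrend_cohort,
    exclude_noncompensators,
    fit_compensation_ratio,
    percent_compensation,
    plateau_mean,
)
from pitchcomp.synthetic import make_trial_design, simulate_participant
from pitchcomp.workflow import participant_indices
from conftest import make_traj


def result_with_ratio(ratio, pid="X"):
    per_trial = pd.DataFrame({"shift_cents": [0.0, 100.0], "plateau_mean": [0.0, -ratio * 100]})
    return fit_compensation_ratio(per_trial, participant_id=pid)


class TestDetrend:
    def test_identical_trials_become_zero(self):
        trials = [make_traj(np.full(200, 7.0)) for _ in range(5)]
        out = detrend_cohort(trials)
        for t in out:
            assert np.allclose(t.values, 0.0)

    def test_common_ramp_removed_constants_centered(self):
        ramp = np.linspace(0, 30, 200)
        consts = [-4.0, 1.0, 3.0]
        trials = [make_traj(ramp + c) for c in consts]
        out = detrend_cohort(trials)
        for t, c in zip(out, consts):
            assert np.allclose(t.values, c - np.mean(consts), atol=1e-12)

    def test_pointwise_mean_zero_after_detrend(self):
        rng = np.random.default_rng(5)
        trials = [make_traj(rng.normal(0, 10, 200)) for _ in range(6)]
        out = detrend_cohort(trials)
        stack = np.stack([t.values for t in out])
        assert np.allclose(stack.mean(axis=0), 0.0, atol=1e-12)

    def test_unequal_lengths(self):
        long = make_traj(np.full(200, 2.0))
        short = make_traj(np.full(100, 4.0))
        out = detrend_cohort([long, short])
        assert np.allclose(out[0].values[:100], -1.0)
        assert np.allclose(out[0].values[100:], 0.0)  # only the long trial contributes

    def test_single_trial_raises(self):
        with pytest.raises(ValueError):
            detrend_cohort([make_traj(np.zeros(200))])


class TestBaselineAlign:
    def test_constant_becomes_zero(self):
        out = baseline_align(make_traj(np.full(200, 7.0)))
        assert np.allclose(out.values, 0.0)

    def test_subtracts_window_mean(self):
        values = np.zeros(200)
        values[5:15] = 3.2
        out = baseline_align(make_traj(values))
        assert out.values[0] == pytest.approx(-3.2)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        traj = make_traj(rng.normal(0, 10, 200))
        once = baseline_align(traj)
        twice = baseline_align(once)
        assert np.allclose(once.values, twice.values)

    def test_missing_baseline_raises(self):
        values = np.full(200, 1.0)
        values[5:15] = np.nan
        with pytest.raises(ValueError):
            baseline_align(make_traj(values))


class TestPlateauMean:
    def test_flat_response(self):
        assert plateau_mean(make_traj(np.full(200, -40.0))) == pytest.approx(-40.0)

    def test_ramp_gives_midpoint(self):
        values = np.zeros(200)
        values[80:120] = np.linspace(0, 10, 40)
        assert plateau_mean(make_traj(values)) == pytest.approx(5.0, abs=0.2)

    def test_under_half_voiced_flagged(self):
        values = np.full(200, 5.0)
        values[80:101] = np.nan  # 21 of 40 plateau samples missing
        assert np.isnan(plateau_mean(make_traj(values)))


class TestRatioFit:
    def test_exact_linear_responder(self):
        shifts = np.array([0, 25, -25, 50, -50, 100, -100], float)
        per_trial = pd.DataFrame({"shift_cents": shifts, "plateau_mean": -0.4 * shifts})
        res = fit_compensation_ratio(per_trial)
        assert res.ratio == pytest.approx(0.4, abs=1e-12)
        assert res.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_ols_sampling_distribution(self):
        rng = np.random.default_rng(0)
        shifts = np.repeat([0, 25, -25, 50, -50, 100, -100], 10).astype(float)
        ratios = []
        for _ in range(200):
            plateau = -0.4 * shifts + rng.normal(0, 5, len(shifts))
            res = fit_compensation_ratio(pd.DataFrame({"shift_cents": shifts, "plateau_mean": plateau}))
            ratios.append(res.ratio)
        assert np.mean(ratios) == pytest.approx(0.4, abs=0.02)

    def test_flat_responder(self):
        per_trial = pd.DataFrame({"shift_cents": [-100.0, 0.0, 100.0], "plateau_mean": [1.0, 1.0, 1.0]})
        assert fit_compensation_ratio(per_trial).ratio == pytest.approx(0.0, abs=1e-12)

    def test_ratio_invariant_to_constant_offset(self):
        shifts = np.array([0, 25, -25, 50, -50, 100, -100], float)
        base = pd.DataFrame({"shift_cents": shifts, "plateau_mean": -0.3 * shifts})
        shifted = base.assign(plateau_mean=base["plateau_mean"] + 17.3)
        assert fit_compensation_ratio(base).ratio == pytest.approx(
            fit_compensation_ratio(shifted).ratio
        )

    def test_single_shift_value_raises(self):
        with pytest.raises(ValueError):
            fit_compensation_ratio(
                pd.DataFrame({"shift_cents": [50.0, 50.0], "plateau_mean": [1.0, 2.0]})
            )


class TestPercentCompensation:
    def test_perfect_linear_responder(self):
        shifts = np.array([25, -25, 50, -50, 100, -100], float)
        per_trial = pd.DataFrame({"shift_cents": shifts, "plateau_mean": -0.4 * shifts})
        for m in (25, 50, 100):
            assert percent_compensation(per_trial, m) == pytest.approx(40.0)

    def test_zero_responder(self):
        per_trial = pd.DataFrame({"shift_cents": [100.0, -100.0], "plateau_mean": [0.0, 0.0]})
        assert percent_compensation(per_trial, 100) == 0.0

    def test_saturating_gain_ordering(self, design_a):
        from pitchcomp.synthetic import SubjectParams

        subj = SubjectParams("S02", sigma_slow=6.0, sigma_fast=2.0, gain=0.5,
                             gain_100=0.3, base_fo=150.0)
        recs = simulate_participant(subj, design_a, seed=10, vowels=("a",))
        idx = participant_indices(recs, vowel="a")
        pct = idx["percent_compensation"]
        assert pct[100.0] < pct[50.0]

    def test_missing_magnitude_raises(self):
        per_trial = pd.DataFrame({"shift_cents": [25.0], "plateau_mean": [1.0]})
        with pytest.raises(ValueError):
            percent_compensation(per_trial, 100)


class TestExclusion:
    def test_negative_ratios_excluded(self):
        results = [result_with_ratio(r, str(i)) for i, r in enumerate([0.4, -0.1, 0.2])]
        kept = exclude_noncompensators(results)
        assert [r.ratio for r in kept] == pytest.approx([0.4, 0.2])

    def test_all_positive_all_kept(self):
        results = [result_with_ratio(r) for r in (0.1, 0.2)]
        assert len(exclude_noncompensators(results)) == 2

    def test_all_negative_warns(self):
        results = [result_with_ratio(-0.2)]
        with pytest.warns(UserWarning):
            assert exclude_noncompensators(results) == []


class TestFullPipeline:
    def test_noise_free_gain_recovered_exactly(self, clean_subject, design_a):
        recs = simulate_participant(clean_subject, design_a, seed=0, vowels=("a",))
        idx = participant_indices(recs, vowel="a")
        assert abs(idx["compensation"].ratio - 0.4) < 1e-9

    def test_trial_order_invariance(self, noisy_subject, design_a):
        recs = simulate_participant(noisy_subject, design_a, seed=2, vowels=("a",))
        forward = participant_indices(recs, vowel="a")
        reverse = participant_indices(list(reversed(recs)), vowel="a")
        assert forward["compensation"].ratio == pytest.approx(reverse["compensation"].ratio)
        assert forward["variability"].slow == pytest.approx(reverse["variability"].slow)
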