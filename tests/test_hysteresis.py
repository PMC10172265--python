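"""Double-Boltzmann evaluation, branch splitting and loop fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinecreep import (
    DegenerateLoopError,
    HysteresisParams,
    MomentRomLoop,
    curve_from_params,
    eval_boltzmann,
    fit_hysteresis,
    r_squared,
    random_loop_params,
    split_branches,
)
from spinecreep.hysteresis import sample_loop


class TestEvalBoltzmann:
    def test_zero_slopes_give_midpoint(self):
        # both logistic terms equal 1/2
        assert eval_boltzmann(-5, 9, 0, 1, 0, -2, 3.3) == pytest.approx((-5 + 9) / 2)

    def test_asymptotes_are_A_and_B(self):
        assert eval_boltzmann(-5, 5, 1, 0, 1, 0, -1e6) == pytest.approx(-5, abs=1e-12)
        assert eval_boltzmann(-5, 5, 1, 0, 1, 0, 1e6) == pytest.approx(5, abs=1e-12)

    def test_hand_computed_value(self):
        # direct arithmetic: 5 - 10/(1 + e^7.5)
        expected = 5.0 - 10.0 / (1.0 + np.exp(7.5))
        assert eval_boltzmann(-5, 5, 1, 0, 1, 0, 7.5) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(4.99447, abs=1e-5)

    def test_extreme_exponent_is_clamped_not_overflowing(self):
        with np.errstate(over="raise"):
            v = eval_boltzmann(-5, 5, 50, 0, 50, 0, 7.5)
        assert np.isfinite(v)

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_nonfinite_input_rejected(self, bad):
        with pytest.raises(ValueError):
            eval_boltzmann(bad, 5, 1, 0, 1, 0, 0.0)
        with pytest.raises(ValueError):
            eval_boltzmann(-5, 5, 1, 0, 1, 0, bad)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounded_between_A_and_B_for_positive_slopes(self, seed):
        rng = np.random.default_rng(seed)
        p = random_loop_params(rng, slope_range=(0.5, 3.0), center_inner=1.5)
        m = np.linspace(-7.5, 7.5, 201)
        for branch in ("upper", "lower"):
            v = eval_boltzmann(p.A, p.B, *p.branch(branch), m)
            assert np.all(v >= p.A - 1e-9) and np.all(v <= p.B + 1e-9)


class TestSplitBranches:
    def test_recovers_constructed_branches(self, base_params):
        loop = sample_loop(base_params, 50)
        (mu, ru), (ml, rl) = split_branches(loop)
        # sample_loop traverses the lower branch rising, upper falling
        assert mu.size == ml.size == 50
        expected_upper = eval_boltzmann(base_params.A, base_params.B,
                                        *base_params.branch("upper"), mu)
        np.testing.assert_allclose(ru, expected_upper, atol=1e-12)

    def test_reversed_acquisition_order_gives_same_assignment(self, base_params):
        loop = sample_loop(base_params, 50)
        rev = MomentRomLoop(loop.moment[::-1], loop.rom[::-1])
        (mu1, ru1), _ = split_branches(loop)
        (mu2, ru2), _ = split_branches(rev)
        order1, order2 = np.argsort(mu1), np.argsort(mu2)
        np.testing.assert_allclose(ru1[order1], ru2[order2], atol=1e-12)

    def test_coincident_branches_tie_broken_by_acquisition_order(self):
        m = np.concatenate([np.linspace(-7.5, 7.5, 20), np.linspace(7.5, -7.5, 20)])
        r = np.interp(m, [-7.5, 7.5], [-5, 5])  # identical up and down
        (mu, ru), _ = split_branches(MomentRomLoop(m, r))
        # the first-traversed (rising) sweep becomes the upper branch
        assert np.all(np.diff(mu) >= 0)

    def test_single_sweep_is_degenerate(self):
        m = np.linspace(-7.5, 7.5, 30)
        with pytest.raises(DegenerateLoopError):
            MomentRomLoop(m, np.linspace(-5, 5, 30))


class TestRSquared:
    def test_exact_prediction(self):
        assert r_squared([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # SS_res = 1, SS_tot = 2
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_sums(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.normal(size=20)
        pred = obs + rng.normal(scale=0.3, size=20)
        ss_res = sum((o - p) ** 2 for o, p in zip(obs, pred))
        ss_tot = sum((o - obs.mean()) ** 2 for o in obs)
        assert r_squared(obs, pred) == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)


class TestFitHysteresis:
    def test_noiseless_recovery_of_shape_parameters(self, rng):
        for _ in range(5):
            p = random_loop_params(rng)
            res = fit_hysteresis(sample_loop(p, 100))
            assert res.converged and res.accepted
            assert res.r2_total >= 0.999
            truth, est = p.to_vector()[2:], res.params.to_vector()[2:]
            assert np.max(np.abs(est - truth) / np.abs(truth)) < 1e-3

    def test_noisy_loops_pass_the_quality_gate(self, rng):
        p = random_loop_params(rng)
        res = fit_hysteresis(sample_loop(p, 100, noise_sigma=0.05, rng=rng), 0.985)
        assert res.accepted and res.r2_total >= 0.985

    def test_flat_loop_is_degenerate(self):
        m = np.concatenate([np.linspace(-7.5, 7.5, 20), np.linspace(7.5, -7.5, 20)])
        loop = MomentRomLoop(m, np.zeros(40) + 3.0)
        with pytest.raises(DegenerateLoopError):
            fit_hysteresis(loop)

    def test_invalid_threshold_rejected(self, base_params):
        with pytest.raises(ValueError):
            fit_hysteresis(sample_loop(base_params, 50), r2_threshold=0.0)

    def test_A_B_fixed_at_sampled_extrema(self, base_params, rng):
        loop = sample_loop(base_params, 80, noise_sigma=0.02, rng=rng)
        res = fit_hysteresis(loop)
        assert res.params.A == loop.rom.min()
        assert res.params.B == loop.rom.max()

    def test_idempotent_on_own_output_curves(self, rng):
        # refitting the fitted curve reproduces the same curve essentially
        # exactly; the parameters move only by the asymptote-tail effect
        for _ in range(3):
            p = random_loop_params(rng)
            res1 = fit_hysteresis(sample_loop(p, 100))
            res2 = fit_hysteresis(sample_loop(res1.params, 100))
            v1, v2 = res1.params.to_vector(), res2.params.to_vector()
            assert np.max(np.abs(v2 - v1) / np.abs(v1)) < 2e-3
            grid = np.linspace(-7.5, 7.5, 101)
            c1 = curve_from_params(res1.params, grid)
            c2 = curve_from_params(res2.params, grid)
            span = res1.params.B - res1.params.A
            for branch in ("upper", "lower"):
                assert np.max(np.abs(c1[branch] - c2[branch])) / span < 1e-6


class TestCurveFromParams:
    def test_round_trip_with_fit(self, rng):
        p = random_loop_params(rng)
        res = fit_hysteresis(sample_loop(p, 100))
        grid = np.linspace(-7.5, 7.5, 60)
        curves = curve_from_params(res.params, grid)
        truth = curve_from_params(p, grid)
        for branch in ("upper", "lower"):
            np.testing.assert_allclose(curves[branch], truth[branch], atol=5e-3)

    def test_empty_grid(self, base_params):
        out = curve_from_params(base_params, [])
        assert out["upper"].size == 0 and out["lower"].size == 0

    def test_single_point_symmetric_params(self):
        p = HysteresisParams(-4, 4, 1, 0, 1, 0, 1, 0, 1, 0)
        out = curve_from_params(p, [0.0])
        # both logistic terms are 1/2 at m = 0: value is (A+B)/2 = 0
        assert out["upper"][0] == pytest.approx(0.0, abs=1e-12)

    def test_grid_outside_protocol_range_rejected(self, base_params):
        with pytest.raises(ValueError):
            curve_from_params(base_params, [9.0])
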