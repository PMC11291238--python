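"""Moment matching, tornado analysis, PSA and the CEAC."""

import numpy as np
import pytest

from nsclc_cea import (
    ParameterSpec,
    PSADraws,
    apply_overrides,
    ceac,
    icer,
    moment_match,
    one_way_sa,
    probability_cost_effective,
    run_arm,
    run_psa,
)


def _base_deltas(reference):
    out_i = run_arm(reference.intervention, reference.inputs)[1]
    out_c = run_arm(reference.comparator, reference.inputs)[1]
    return out_i.total_cost - out_c.total_cost, out_i.total_qalys - out_c.total_qalys


class TestMomentMatch:
    def test_beta_recovers_mean_and_sd(self):
        spec = ParameterSpec("inputs.u_pfs", 0.804, 0.724, 0.884, "beta")
        p = moment_match(spec)
        mean = p["shape1"] / (p["shape1"] + p["shape2"])
        var = (
            p["shape1"] * p["shape2"]
            / ((p["shape1"] + p["shape2"]) ** 2 * (p["shape1"] + p["shape2"] + 1))
        )
        sigma = (0.884 - 0.724) / 3.92
        assert mean == pytest.approx(0.804, abs=1e-9)
        assert np.sqrt(var) == pytest.approx(sigma, abs=1e-9)
        assert sigma == pytest.approx(0.04082, abs=1e-5)

    def test_gamma_recovers_mean_and_sd(self):
        spec = ParameterSpec("inputs.bsc_cost_per_cycle", 2467.0, 1973.65, 2960.47, "gamma")
        p = moment_match(spec)
        sigma = (2960.47 - 1973.65) / 3.92
        assert p["shape"] * p["scale"] == pytest.approx(2467.0, abs=1e-9)
        assert np.sqrt(p["shape"]) * p["scale"] == pytest.approx(sigma, abs=1e-9)
        assert sigma == pytest.approx(251.74, abs=0.01)

    def test_zero_width_range_degenerates(self):
        spec = ParameterSpec("inputs.u_pd", 0.3, 0.3, 0.3, "beta")
        assert moment_match(spec)["point"] == 0.3

    def test_infeasible_beta_moments_rejected(self):
        spec = ParameterSpec("inputs.u_pd", 0.5, -3.0, 4.0, "beta")
        with pytest.raises(ValueError, match="infeasible"):
            moment_match(spec)

    def test_fixed_has_no_distribution(self):
        spec = ParameterSpec("inputs.annual_discount_rate", 0.05, 0.0, 0.08, "fixed")
        with pytest.raises(ValueError):
            moment_match(spec)


class TestApplyOverrides:
    def test_unknown_parameter_id(self, reference):
        with pytest.raises(KeyError):
            apply_overrides(reference.inputs, reference.arms, {"inputs.nope": 1.0})

    def test_override_is_pure(self, reference):
        inputs2, arms2 = apply_overrides(
            reference.inputs, reference.arms, {"inputs.u_pfs": 0.9}
        )
        assert inputs2.u_pfs == 0.9
        assert reference.inputs.u_pfs == 0.804
        assert arms2[0] is reference.arms[0]

    def test_shared_ae_disutility(self, reference):
        _, arms2 = apply_overrides(
            reference.inputs, reference.arms, {"ae.neutropenia.disutility": -0.25}
        )
        for arm in arms2:
            ae = next(a for a in arm.ae_profile if a.name == "neutropenia")
            assert ae.disutility == 0.25


class TestOneWaySA:
    def test_degenerate_range_zero_swing(self, reference):
        spec = ParameterSpec("inputs.bsc_cost_per_cycle", 2467.0, 2467.0, 2467.0, "fixed")
        entries = one_way_sa(reference.inputs, reference.arms, [spec])
        assert entries[0].swing == 0.0

    def test_order_invariance(self, reference):
        specs = list(reference.parameters)
        fwd = one_way_sa(reference.inputs, reference.arms, specs)
        rev = one_way_sa(reference.inputs, reference.arms, specs[::-1])
        assert [e.parameter for e in fwd] == [e.parameter for e in rev]

    def test_sorted_by_descending_swing(self, reference):
        entries = one_way_sa(reference.inputs, reference.arms, reference.parameters)
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)

    def test_discount_rate_bounds_bracket_base(self, reference):
        spec = next(p for p in reference.parameters if p.id == "inputs.annual_discount_rate")
        entries = one_way_sa(reference.inputs, reference.arms, [spec])
        base = _base_deltas(reference)
        base_icer = base[0] / base[1]
        lo, hi = sorted([entries[0].icer_at_low, entries[0].icer_at_high])
        assert lo <= base_icer <= hi


class TestRunPSA:
    def test_all_fixed_equals_base_case(self, reference):
        specs = [
            ParameterSpec(p.id, p.base, p.low, p.high, "fixed") for p in reference.parameters
        ]
        draws = run_psa(reference.inputs, reference.arms, specs, n_draws=5, seed=1)
        dc, de = _base_deltas(reference)
        assert np.allclose(draws.delta_cost, dc)
        assert np.allclose(draws.delta_qalys, de)

    def test_seed_contract(self, reference):
        a = run_psa(reference.inputs, reference.arms, reference.parameters, 200, seed=5)
        b = run_psa(reference.inputs, reference.arms, reference.parameters, 200, seed=5)
        c = run_psa(reference.inputs, reference.arms, reference.parameters, 200, seed=6)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qalys, b.delta_qalys)
        assert not np.array_equal(a.delta_cost, c.delta_cost)
        # different seeds agree in distribution
        assert a.delta_cost.mean() == pytest.approx(c.delta_cost.mean(), rel=0.05)

    def test_scatter_means_near_base_deltas(self, reference):
        """Second-order sampling is centred on the deterministic base case."""
        draws = run_psa(reference.inputs, reference.arms, reference.parameters, 2000, seed=3)
        dc, de = _base_deltas(reference)
        assert draws.delta_cost.mean() == pytest.approx(dc, rel=0.05)
        assert draws.delta_qalys.mean() == pytest.approx(de, rel=0.05)

    def test_sampled_parameter_means_converge(self, reference):
        """Each sampled parameter's PSA mean sits within 3 MC standard errors."""
        rng = np.random.default_rng(11)
        n = 5000
        for p in reference.parameters:
            if p.psa_family == "fixed" or p.high == p.low:
                continue
            pars = moment_match(p)
            sign = -1.0 if p.base < 0 else 1.0
            if p.psa_family == "beta":
                x = sign * rng.beta(pars["shape1"], pars["shape2"], size=n)
            else:
                x = sign * rng.gamma(pars["shape"], pars["scale"], size=n)
            se = x.std() / np.sqrt(n)
            assert abs(x.mean() - p.base) < 3 * se + 1e-12, p.id


class TestCEAC:
    def test_single_draw_nmb_sign(self):
        draws = PSADraws(1, 0, np.array([1.0]), np.array([1.0]))
        curve = ceac(draws, np.array([0.5, 2.0]))
        assert curve.prob_cost_effective[0] == 0.0
        assert curve.prob_cost_effective[1] == 1.0

    def test_matches_brute_force_counting(self, reference):
        draws = run_psa(reference.inputs, reference.arms, reference.parameters, 300, seed=8)
        grid = np.array([50_000.0, 257_016.0, 500_000.0])
        curve = ceac(draws, grid)
        for wtp, prob in zip(grid, curve.prob_cost_effective):
            count = sum(
                1
                for dc, de in zip(draws.delta_cost, draws.delta_qalys)
                if wtp * de - dc > 0
            )
            assert prob == count / draws.n_draws
            assert probability_cost_effective(draws, wtp) == prob

    def test_monotone_when_effect_positive(self, reference):
        draws = run_psa(reference.inputs, reference.arms, reference.parameters, 500, seed=2)
        assert np.all(draws.delta_qalys > 0)
        curve = ceac(draws)
        assert np.all(np.diff(curve.prob_cost_effective) >= 0)

    def test_bad_grid_rejected(self, reference):
        draws = PSADraws(1, 0, np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            ceac(draws, np.array([2.0, 1.0]))
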