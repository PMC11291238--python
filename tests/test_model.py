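"""Cohort trace, transition-matrix equivalence, accumulation and ICER."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nsclc_cea import (
    AdverseEvent,
    ArmSpec,
    CEOutcome,
    EconomicInputs,
    ParametricFit,
    accumulate,
    dosing_cost,
    icer,
    loglogistic,
    occupancy,
    propagate,
    run_arm,
    survival_at,
    transition_matrix_view,
)

CYCLE_MONTHS = 21.0 / 30.4375


def _flat_arm(**kwargs):
    defaults = dict(
        name="x",
        os_fit=loglogistic(17.43252, 1.48925),
        pfs_fit=loglogistic(4.84787, 1.42274),
        drug_cost_per_cycle=0.0,
    )
    defaults.update(kwargs)
    return ArmSpec(**defaults)


class TestOccupancy:
    def test_initial_state(self, reference):
        for arm in reference.arms:
            trace = occupancy(arm.os_fit, arm.pfs_fit, reference.inputs)
            assert (trace.pfs[0], trace.pd[0], trace.dead[0]) == (1.0, 0.0, 0.0)

    def test_degenerate_curves_stay_in_pfs(self):
        # a log-logistic with a huge scale is survival ~ 1 over the horizon
        fit = loglogistic(1e12, 1.5)
        trace = occupancy(fit, fit, EconomicInputs())
        assert np.allclose(trace.pfs, 1.0, atol=1e-9)
        assert np.allclose(trace.dead, 0.0, atol=1e-9)

    def test_rows_sum_to_one_and_dead_monotone(self, reference):
        for arm in reference.arms:
            trace = occupancy(arm.os_fit, arm.pfs_fit, reference.inputs)
            assert np.max(np.abs(trace.pfs + trace.pd + trace.dead - 1.0)) <= 1e-9
            assert np.all(np.diff(trace.dead) >= -1e-12)

    def test_cycle30_matches_direct_formula(self, reference):
        arm = reference.intervention
        trace = occupancy(arm.os_fit, arm.pfs_fit, reference.inputs)
        t = 30 * CYCLE_MONTHS
        s_os = survival_at(arm.os_fit, t)
        s_pfs = survival_at(arm.pfs_fit, t)
        assert trace.pfs[30] == pytest.approx(min(s_pfs, s_os), abs=1e-12)
        assert trace.dead[30] == pytest.approx(1 - s_os, abs=1e-12)
        assert trace.pd[30] == pytest.approx(s_os - min(s_pfs, s_os), abs=1e-12)


class TestTransitionMatrixView:
    def test_constant_curves_self_transition(self):
        fit = loglogistic(1e12, 1.5)
        tm = transition_matrix_view(fit, fit, EconomicInputs())
        assert np.allclose(tm["pfs_to_pfs"], 1.0, atol=1e-9)
        assert np.allclose(tm["pd_to_pd"], 1.0, atol=1e-9)

    def test_rows_stochastic(self, reference):
        arm = reference.comparator
        tm = transition_matrix_view(arm.os_fit, arm.pfs_fit, reference.inputs)
        pfs_out = tm["pfs_to_pfs"] + tm["pfs_to_pd"] + tm["pfs_to_dead"]
        pd_out = tm["pd_to_pd"] + tm["pd_to_dead"]
        assert np.allclose(pfs_out, 1.0, atol=1e-9)
        assert np.allclose(pd_out, 1.0, atol=1e-9)

    def test_propagation_reproduces_occupancy(self, reference):
        """Markov propagation through the per-cycle matrices == partitioned trace."""
        for arm in reference.arms:
            tm = transition_matrix_view(arm.os_fit, arm.pfs_fit, reference.inputs)
            direct = occupancy(arm.os_fit, arm.pfs_fit, reference.inputs)
            prop = propagate(tm, reference.inputs)
            for a, b in ((prop.pfs, direct.pfs), (prop.pd, direct.pd), (prop.dead, direct.dead)):
                assert np.max(np.abs(a - b)) <= 1e-9


class TestAccumulate:
    def test_zero_costs_and_utilities(self):
        inputs = EconomicInputs(bsc_cost_per_cycle=0.0, severe_ae_cost=0.0, u_pfs=1e-9, u_pd=0.0)
        arm = _flat_arm()
        trace = occupancy(arm.os_fit, arm.pfs_fit, inputs)
        out = accumulate(trace, arm, inputs)
        assert out.total_cost == 0.0
        assert out.total_qalys == pytest.approx(0.0, abs=1e-6)

    def test_horizon_identity(self):
        """Everyone in PFS with utility 1 and no discounting: 208 cycles of 21 days."""
        inputs = EconomicInputs(
            annual_discount_rate=0.0, bsc_cost_per_cycle=0.0, severe_ae_cost=0.0,
            u_pfs=1.0, u_pd=0.5,
        )
        fit = loglogistic(1e12, 1.5)
        arm = _flat_arm(os_fit=fit, pfs_fit=fit)
        trace = occupancy(fit, fit, inputs)
        out = accumulate(trace, arm, inputs)
        assert out.total_qalys == pytest.approx(208 * 21 / 365.25, rel=1e-9)

    def test_discount_monotonicity(self, reference):
        """Raising the discount rate never raises cost or QALY totals."""
        for arm in reference.arms:
            prev_cost, prev_q = np.inf, np.inf
            for r in (0.0, 0.03, 0.05, 0.08):
                inputs = dataclasses.replace(reference.inputs, annual_discount_rate=r)
                _, out = run_arm(arm, inputs)
                assert out.total_cost <= prev_cost + 1e-9
                assert out.total_qalys <= prev_q + 1e-12
                prev_cost, prev_q = out.total_cost, out.total_qalys

    def test_exponential_life_years_bounded_by_closed_form(self):
        """Undiscounted truncated life-years stay below the 1/rate limit."""
        rate = 0.05  # per month
        fit = ParametricFit("exponential", {"rate": rate})
        inputs = EconomicInputs(annual_discount_rate=0.0)
        trace = occupancy(fit, fit, inputs)
        alive = trace.pfs + trace.pd
        life_years = float(np.sum(alive[1:]) * inputs.cycle_years)
        bound_years = (1.0 / rate) * 30.4375 / 365.25
        assert life_years < bound_years

    def test_ae_burden_applied_once(self, reference):
        arm = _flat_arm(
            ae_profile=(AdverseEvent("neutropenia", incidence=0.5, disutility=0.2),),
        )
        inputs = reference.inputs
        trace = occupancy(arm.os_fit, arm.pfs_fit, inputs)
        base = accumulate(trace, dataclasses.replace(arm, ae_profile=()), inputs)
        with_ae = accumulate(trace, arm, inputs)
        disc1 = (1.05) ** (-(21 / 365.25))
        assert with_ae.total_cost - base.total_cost == pytest.approx(0.5 * 2534.0 * disc1)
        assert base.total_qalys - with_ae.total_qalys == pytest.approx(
            0.5 * 0.2 * (21 / 365.25) * disc1
        )

    def test_bsc_scope_toggle(self, reference):
        arm = reference.comparator
        inputs_all = dataclasses.replace(reference.inputs, bsc_scope="all_alive")
        inputs_pd = dataclasses.replace(reference.inputs, bsc_scope="pd_only")
        _, out_all = run_arm(arm, inputs_all)
        _, out_pd = run_arm(arm, inputs_pd)
        assert out_all.total_cost > out_pd.total_cost
        assert out_all.total_qalys == out_pd.total_qalys


class TestICER:
    def test_simple_ratio(self):
        res = icer(CEOutcome("a", 100.0, 0.5), CEOutcome("b", 0.0, 0.0))
        assert res.icer == pytest.approx(200.0)
        assert res.label == "icer"

    def test_dominant(self):
        res = icer(CEOutcome("a", 90.0, 1.1), CEOutcome("b", 100.0, 1.0))
        assert res.label == "dominant"
        assert res.icer is None

    def test_dominated(self):
        res = icer(CEOutcome("a", 110.0, 0.9), CEOutcome("b", 100.0, 1.0))
        assert res.label == "dominated"

    def test_degenerate_zero_effect(self):
        res = icer(CEOutcome("a", 100.0, 1.0), CEOutcome("b", 90.0, 1.0))
        assert res.label == "dominated-degenerate"

    @given(
        dc=st.floats(-1e5, 1e5, allow_nan=False),
        de=st.floats(0.01, 5.0, allow_nan=False),
    )
    def test_ratio_identity(self, dc, de):
        res = icer(CEOutcome("a", dc, 1.0 + de), CEOutcome("b", 0.0, 1.0))
        if dc <= 0:
            assert res.label == "dominant"
        else:
            assert res.icer == pytest.approx(dc / de)


class TestDosingCost:
    def test_bsa_based_dose(self):
        # 65 CNY / 20 mg at 75 mg/m^2 x 1.72 m^2 = 129 mg
        assert dosing_cost(65.0, 20.0, per_m2_mg=75.0) == pytest.approx(419.25, abs=1e-9)

    def test_upper_price(self):
        assert dosing_cost(139.28, 20.0, per_m2_mg=75.0) == pytest.approx(898.356, abs=1e-9)

    def test_flat_dose_and_zero(self):
        assert dosing_cost(1377.5, 100.0, flat_mg=200.0) == pytest.approx(2755.0)
        assert dosing_cost(10.0, 10.0, flat_mg=0.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dosing_cost(-5.0, 20.0, flat_mg=10.0)
        with pytest.raises(ValueError):
            dosing_cost(5.0, 20.0)
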