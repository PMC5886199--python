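"""Unit tests of the flow equations, auxiliary updates and the integrator.

Hand-computed expected values come from evaluating the documented
closed-form flow equations on paper (the "spreadsheet" oracle); they are
frozen here as literals.
"""

import dataclasses

import numpy as np
import pytest

from p4psim.core import (
    AuxiliaryState,
    StockState,
    compute_flows,
    integrate,
    integrate_basic,
    p4p_bonus,
    step,
    update_gaming,
    update_motivation,
)
from p4psim.params import InvariantError, ModelParams, P4PParams, RateParams


def baseline_aux(rates: RateParams) -> AuxiliaryState:
    return AuxiliaryState(bonus=0.0, motivation=rates.motivation_baseline, gaming=0.0)


class TestComputeFlows:
    def test_null_rates_give_null_flows(self, null_rates, p4p_off):
        state = StockState(0.3, -0.2, 0.7)
        flows = compute_flows(state, baseline_aux(null_rates), 0.1, null_rates, p4p_off)
        assert (flows.revenue_in, flows.bonus_in, flows.conversion,
                flows.depletion, flows.volume_net) == (0, 0, 0, 0, 0)

    def test_gaming_increases_quality_depletion(self, base_params):
        """Extensive gaming depletes service quality faster than none."""
        rates, p4p = base_params.rates, base_params.p4p
        state = StockState(0.0, 0.0, 0.0)
        lo = compute_flows(state, AuxiliaryState(0.0, 1.0, 0.0), 0.0, rates, p4p)
        hi = compute_flows(state, AuxiliaryState(0.0, 1.0, 1.0), 0.0, rates, p4p)
        assert hi.depletion > lo.depletion

    def test_flow_values_match_hand_evaluation(self, base_params):
        """Closed forms at (R,Q,V)=(0,0,-0.5), baseline aux, packaged params.

        revenue_in = 0.125*(1 + 0.25*(-0.5))        = 0.109375
        conversion = 0.5*1*(0+1)/2                  = 0.25
        depletion  = 0.25*1*(-0.5+1)/2              = 0.0625
        volume_net = 0.09*1*(0 - (-0.5))            = 0.045
        """
        rates, p4p = base_params.rates, base_params.p4p
        state = StockState(0.0, 0.0, -0.5)
        flows = compute_flows(state, baseline_aux(rates), 0.0, rates, p4p)
        assert flows.revenue_in == pytest.approx(0.109375)
        assert flows.bonus_in == 0.0
        assert flows.conversion == pytest.approx(0.25)
        assert flows.depletion == pytest.approx(0.0625)
        assert flows.volume_net == pytest.approx(0.045)

    def test_cld_sign_constraints(self, base_params):
        """Each causal arrow has the sign the loop diagram prescribes."""
        rates = dataclasses.replace(base_params.rates)
        p4p = dataclasses.replace(base_params.p4p, enabled=True)
        aux = baseline_aux(rates)
        s0 = StockState(0.0, 0.0, 0.0)
        f0 = compute_flows(s0, aux, 0.0, rates, p4p)
        # revenue inflow strictly increasing in V
        f_v = compute_flows(StockState(0.0, 0.0, 0.5), aux, 0.0, rates, p4p)
        assert f_v.revenue_in > f0.revenue_in
        # conversion strictly increasing in R and in E
        f_r = compute_flows(StockState(0.5, 0.0, 0.0), aux, 0.0, rates, p4p)
        assert f_r.conversion > f0.conversion
        f_e = compute_flows(s0, AuxiliaryState(0.0, 2.0, 0.0), 0.0, rates, p4p)
        assert f_e.conversion > f0.conversion
        # depletion strictly increasing in V and in G
        assert f_v.depletion > f0.depletion
        f_g = compute_flows(s0, AuxiliaryState(0.0, 1.0, 0.5), 0.0, rates, p4p)
        assert f_g.depletion > f0.depletion
        # net recruitment strictly increasing in delayed Q, and in E while
        # the recruitment component is active (delayed Q above V)
        f_q = compute_flows(s0, aux, 0.5, rates, p4p)
        assert f_q.volume_net > f0.volume_net
        f_qe = compute_flows(s0, AuxiliaryState(0.0, 2.0, 0.0), 0.5, rates, p4p)
        assert f_qe.volume_net > f_q.volume_net

    def test_out_of_bound_input_names_field(self, base_params):
        with pytest.raises(InvariantError, match="delayed_quality"):
            compute_flows(StockState(0, 0, 0), baseline_aux(base_params.rates),
                          1.5, base_params.rates, base_params.p4p)
        with pytest.raises(InvariantError, match="volume"):
            StockState(0.0, 0.0, -1.2)
        with pytest.raises(InvariantError, match="gaming"):
            AuxiliaryState(0.0, 1.0, 1.4)


class TestBonus:
    def test_disabled_scheme_pays_nothing(self):
        p4p = P4PParams(enabled=False, bonus_rate=1.0)
        assert p4p_bonus(0.9, p4p, 0.0) == 0.0

    def test_never_negative_below_baseline(self):
        """Facilities are never penalised for sub-baseline volume."""
        p4p = P4PParams(enabled=True, bonus_rate=1.0, volume_base=-0.5)
        for v in (-1.0, -0.8, -0.5):
            assert p4p_bonus(v, p4p, 0.0) == 0.0

    def test_linear_above_baseline(self):
        p4p = P4PParams(enabled=True, bonus_rate=1.0, volume_base=-0.5,
                        gaming_inflation=0.0)
        assert p4p_bonus(-0.3, p4p, 0.0) == pytest.approx(0.2)

    def test_gaming_inflates_the_claim(self):
        p4p = P4PParams(enabled=True, bonus_rate=1.0, volume_base=-0.5,
                        gaming_inflation=0.5)
        assert p4p_bonus(-0.3, p4p, 1.0) == pytest.approx(0.3)


class TestMotivation:
    def test_baseline_without_bonus_or_gaming(self, base_params):
        """Some motivation exists irrespective of the intervention."""
        rates, p4p = base_params.rates, base_params.p4p
        assert update_motivation(0.0, 0.0, rates, p4p) == rates.motivation_baseline

    def test_zero_gain_ignores_bonus(self, base_params):
        p4p = dataclasses.replace(base_params.p4p, motivation_gain=0.0)
        assert update_motivation(5.0, 0.0, base_params.rates, p4p) == 1.0

    def test_non_negativity_clamp(self):
        rates = RateParams(0.1, 0.1, 0.1, 0.1, motivation_baseline=1.0)
        p4p = P4PParams(motivation_gain=0.5, gaming_motivation_loss=2.0)
        # 1 + 0.5*0.4 - 2*0.8^2 = 1 + 0.2 - 1.28 < 0  -> clamped
        assert update_motivation(0.4, 0.8, rates, p4p) == 0.0


class TestGaming:
    def test_no_feedback_leaves_gaming_unchanged(self):
        p4p = P4PParams(gaming_feedback=0.0)
        assert update_gaming(0.3, 5.0, p4p, 0.25) == 0.3

    def test_saturation_at_capacity(self):
        p4p = P4PParams(gaming_feedback=5.0)
        assert update_gaming(1.0, 10.0, p4p, 1.0) == 1.0
        capped = P4PParams(gaming_feedback=5.0, gaming_max=0.4)
        assert update_gaming(0.4, 10.0, capped, 1.0) == 0.4

    def test_reinforcement_update_value(self):
        # G' = 0.5 + 1*0.2*1*(1-0.5) = 0.6
        p4p = P4PParams(gaming_feedback=0.2)
        assert update_gaming(0.5, 1.0, p4p, 1.0) == pytest.approx(0.6)

    def test_monotone_in_bonus(self):
        p4p = P4PParams(gaming_feedback=0.5)
        g1 = update_gaming(0.2, 0.1, p4p, 0.25)
        g2 = update_gaming(0.2, 0.4, p4p, 0.25)
        assert g2 > g1

    def test_non_positive_dt_rejected(self):
        with pytest.raises(InvariantError, match="dt"):
            update_gaming(0.2, 0.1, P4PParams(), 0.0)


class TestStep:
    def test_zero_flows_are_stationary(self, null_rates, p4p_off):
        state = StockState(0.2, -0.4, 0.6)
        aux = baseline_aux(null_rates)
        new_state, _ = step(state, aux, -0.4, 0.6, null_rates, p4p_off, 0.25)
        assert new_state == state

    def test_gating_pins_quality_at_upper_bound(self):
        """A net quality inflow into Q = +1 contributes nothing."""
        rates = RateParams(r_revenue=0.1, r_conversion=1.0, r_depletion=0.0,
                           r_volume=0.0, r_attrition=0.0)
        state = StockState(0.5, 1.0, 0.0)
        new_state, _ = step(state, baseline_aux(rates), 1.0, 0.0, rates,
                            P4PParams(), 0.25)
        assert new_state.quality == 1.0

    def test_single_euler_step_matches_hand_computation(self, base_params):
        """From the packaged initial state (-0.5, 0, -0.5), dt = 0.25:

        dR = 0.125*(1+0.25*(-0.5)) - 0.5*(-0.5+1)/2   = -0.015625
        dQ = 0.125 - 0.25*(-0.5+1)/2                  = +0.0625
        dV = 0.09*(0-(-0.5))                          = +0.045
        """
        rates, p4p = base_params.rates, base_params.p4p
        state = StockState(*base_params.initial)
        new_state, _ = step(state, baseline_aux(rates), 0.0, -0.5, rates, p4p, 0.25)
        assert new_state.revenue == pytest.approx(-0.50390625)
        assert new_state.quality == pytest.approx(0.015625)
        assert new_state.volume == pytest.approx(-0.48875)

    def test_invalid_dt(self, base_params):
        state = StockState(0, 0, 0)
        with pytest.raises(InvariantError, match="dt"):
            step(state, baseline_aux(base_params.rates), 0.0, 0.0,
                 base_params.rates, base_params.p4p, -0.1)


class TestIntegrate:
    def test_grid_and_shapes(self, base_params):
        traj = integrate(base_params, horizon=10.0, dt=0.5)
        assert len(traj.times) == 21
        assert traj.times[0] == 0.0 and traj.times[-1] == 10.0
        steps = np.diff(traj.times)
        assert np.allclose(steps, 0.5)
        for arr in (traj.revenue, traj.quality, traj.volume, traj.bonus,
                    traj.motivation, traj.gaming):
            assert len(arr) == 21

    def test_bit_reproducible(self, base_params):
        a = integrate(base_params, horizon=50.0, dt=0.25)
        b = integrate(base_params, horizon=50.0, dt=0.25)
        for name in ("revenue", "quality", "volume", "bonus", "motivation", "gaming"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_p4p_off_reduces_bitwise_to_basic_model(self, base_params):
        """Disabling the intervention reduces the model, bitwise, to basic
        facility operations with the P4P machinery removed."""
        full = integrate(base_params, horizon=100.0, dt=0.25)
        basic = integrate_basic(base_params, horizon=100.0, dt=0.25)
        assert np.array_equal(full.revenue, basic.revenue)
        assert np.array_equal(full.quality, basic.quality)
        assert np.array_equal(full.volume, basic.volume)
        assert np.all(full.bonus == 0.0) and np.all(full.gaming == 0.0)

    def test_invalid_arguments(self, base_params):
        with pytest.raises(InvariantError, match="horizon"):
            integrate(base_params, horizon=0.0)
        with pytest.raises(InvariantError, match="dt"):
            integrate(base_params, horizon=10.0, dt=0.0)

    def test_history_padding_delays_bonus_onset(self, base_params):
        """Before t = tau the bonus reads the (pre-simulation) initial volume."""
        params = base_params.with_overrides({"enabled": True})
        traj = integrate(params, horizon=20.0, dt=0.25)
        tau = params.p4p.total_bonus_delay
        assert np.all(traj.bonus[traj.times <= tau] == 0.0)
        assert traj.bonus[-1] > 0.0
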