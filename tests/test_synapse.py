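"""Tests of the synaptic kernels, NMDA gate and Tsodyks-Markram plasticity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neocolumn.synapse import (
    DualExpAccumulator,
    Receptor,
    STPParams,
    STPState,
    SynapseParams,
    kernel_peak_time,
    kernel_sum_on_grid,
    nmda_gate,
    stp_fixed_point,
    stp_on_spike,
    synaptic_current,
)

AMPA = SynapseParams(receptor=Receptor.AMPA, g_max=1.0, E_rev=0.0,
                     tau_on=0.2, tau_off=2.0, tau_D=1.0)
STP = STPParams(U=0.25, tau_facil=500.0, tau_rec=300.0)


def hand_stp_sequence(spike_times, params):
    """Independent step-by-step evaluation of the plasticity recursion."""
    out = []
    u = R = None
    for i, t in enumerate(spike_times):
        if i == 0:
            u, R = params.U, 1.0 - params.U
        else:
            dt = t - spike_times[i - 1]
            ef = math.exp(-dt / params.tau_facil)
            er = math.exp(-dt / params.tau_rec)
            u = u * ef + params.U * (1 - u * ef)
            R = R * (1 - u) * er + 1 - er
        out.append((u, R, u * R))
    return out


class TestNMDAGate:
    @pytest.mark.parametrize("receptor", [Receptor.AMPA, Receptor.GABAA])
    @pytest.mark.parametrize("V", [-120.0, -60.0, 0.0, 40.0])
    def test_gate_is_unity_for_non_nmda(self, receptor, V):
        assert nmda_gate(V, receptor) == 1.0

    def test_gate_closes_under_hyperpolarization(self):
        assert nmda_gate(-1e4, Receptor.NMDA) == pytest.approx(0.0, abs=1e-12)

    def test_gate_at_zero_millivolts(self):
        assert nmda_gate(0.0, Receptor.NMDA) == pytest.approx(1.08 / 1.19, rel=1e-12)

    def test_gate_formula_pointwise(self):
        V = np.linspace(-100, 40, 29)
        expected = 1.08 / (1 + 0.19 * np.exp(-0.064 * V))
        assert np.allclose(nmda_gate(V, "NMDA"), expected, rtol=1e-14)


class TestSTP:
    def test_first_spike_state(self):
        state, a = stp_on_spike(STPState(), 10.0, STP)
        assert (state.u, state.R) == (0.25, 0.75)
        assert a == pytest.approx(0.1875)

    def test_full_recovery_at_long_intervals(self):
        state, _ = stp_on_spike(STPState(), 0.0, STP)
        state, a = stp_on_spike(state, 1e7, STP)
        assert state.u == pytest.approx(STP.U, abs=1e-9)
        assert state.R == pytest.approx(1.0, abs=1e-9)
        assert a == pytest.approx(STP.U, abs=1e-8)

    def test_second_spike_hand_value(self):
        # one facilitation time constant later: u2 = U/e + U(1 - U/e)
        state, _ = stp_on_spike(STPState(), 0.0, STP)
        state, _ = stp_on_spike(state, 500.0, STP)
        u2 = 0.25 * math.exp(-1) + 0.25 * (1 - 0.25 * math.exp(-1))
        assert state.u == pytest.approx(u2, rel=1e-12)
        assert u2 == pytest.approx(0.3190, abs=5e-4)
        er = math.exp(-500.0 / 300.0)
        R2 = 0.75 * (1 - u2) * er + 1 - er
        assert state.R == pytest.approx(R2, rel=1e-12)

    def test_random_trains_match_hand_recursion(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            times = np.cumsum(rng.uniform(1, 80, size=12))
            expected = hand_stp_sequence(times, STP)
            state = STPState()
            for t, (u, R, a_exp) in zip(times, expected):
                state, a = stp_on_spike(state, float(t), STP)
                assert a == pytest.approx(a_exp, abs=1e-12)

    def test_out_of_order_spike_rejected(self):
        state, _ = stp_on_spike(STPState(), 10.0, STP)
        with pytest.raises(ValueError, match="order"):
            stp_on_spike(state, 5.0, STP)

    def test_pure_depression_limit(self):
        # vanishing facilitation time constant: u stays at U on every spike
        params = STPParams(U=0.25, tau_facil=1e-9, tau_rec=300.0)
        state = STPState()
        for t in (0.0, 10.0, 20.0, 30.0):
            state, _ = stp_on_spike(state, t, params)
            assert state.u == pytest.approx(params.U, abs=1e-12)

    def test_instant_recovery_limit(self):
        # vanishing recovery time constant: resources replenish fully
        params = STPParams(U=0.25, tau_facil=500.0, tau_rec=1e-9)
        state, _ = stp_on_spike(STPState(), 0.0, params)
        state, _ = stp_on_spike(state, 10.0, params)
        assert state.R == pytest.approx(1.0, abs=1e-12)

    def test_periodic_train_converges_to_fixed_point(self):
        isi = 20.0
        u_star, R_star = stp_fixed_point(STP, isi)
        state = STPState()
        gaps = []
        for n in range(150):
            state, _ = stp_on_spike(state, n * isi, STP)
            gaps.append(abs(state.u - u_star) + abs(state.R - R_star))
        assert gaps[-1] < 1e-12
        # geometric convergence: the error contracts by a fixed factor
        ratios = [g2 / g1 for g1, g2 in zip(gaps[1:10], gaps[2:11]) if g1 > 1e-14]
        assert max(ratios) < 0.95

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.5, 200.0), min_size=1, max_size=30))
    def test_efficiency_bounded(self, gaps):
        state = STPState()
        t = 0.0
        for g in gaps:
            t += g
            state, a = stp_on_spike(state, t, STP)
            assert 0.0 < a < 1.0
            assert 0.0 <= state.u <= 1.0
            assert 0.0 <= state.R <= 1.0


class TestSynapticCurrent:
    def test_no_events_no_current(self):
        assert synaptic_current([], AMPA, V=-60.0, t=100.0) == 0.0

    def test_kernel_zero_at_delayed_onset(self):
        assert synaptic_current([(10.0, 1.0)], AMPA, V=-60.0, t=10.0 + AMPA.tau_D) == 0.0

    def test_matches_closed_form_on_grid(self):
        ts = np.arange(0.0, 30.0, 0.1)
        for t in ts:
            got = synaptic_current([(5.0, 1.0)], AMPA, V=-60.0, t=float(t))
            s = t - 5.0 - AMPA.tau_D
            kern = (math.exp(-s / AMPA.tau_off) - math.exp(-s / AMPA.tau_on)) if s >= 0 else 0.0
            expected = AMPA.g_max * kern * (-60.0 - AMPA.E_rev)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_sign_convention(self):
        # the returned value is subtracted from the drive: an excitatory
        # synapse below its reversal potential returns a negative number
        # (depolarizing), an inhibitory one above reversal a positive number
        gaba = SynapseParams(receptor=Receptor.GABAA, g_max=1.0, E_rev=-70.0,
                             tau_on=0.5, tau_off=8.0, tau_D=0.0)
        assert synaptic_current([(0.0, 1.0)], AMPA, V=-60.0, t=3.0) < 0
        assert synaptic_current([(0.0, 1.0)], gaba, V=-50.0, t=3.0) > 0

    def test_kernel_peak_time_closed_form(self):
        t_star = kernel_peak_time(AMPA)
        grid = np.arange(AMPA.tau_D, 20.0, 1e-4)
        vals = [synaptic_current([(0.0, 1.0)], AMPA, V=-60.0, t=float(t)) for t in grid]
        t_num = grid[int(np.argmin(vals))]  # most negative = conductance peak
        assert t_star == pytest.approx(t_num, abs=1e-3)


class TestAccumulator:
    def test_accumulator_equals_direct_sum(self):
        rng = np.random.default_rng(11)
        dt, n_steps = 0.05, 2000
        ev_steps = np.sort(rng.integers(0, n_steps, size=25))
        weights = rng.uniform(0.1, 2.0, size=25)
        got = kernel_sum_on_grid(ev_steps, weights, AMPA.tau_on, AMPA.tau_off, dt, n_steps)
        t = np.arange(n_steps + 1) * dt
        expected = np.zeros_like(t)
        for k, w in zip(ev_steps, weights):
            s = t - k * dt
            m = s > 0
            expected[m] += w * (np.exp(-s[m] / AMPA.tau_off) - np.exp(-s[m] / AMPA.tau_on))
        assert np.max(np.abs(got - expected)) < 1e-9

    def test_single_event_stepwise(self):
        acc = DualExpAccumulator(0.5, 8.0, dt=0.1)
        assert acc.step(1.0) == pytest.approx(
            math.exp(-0.1 / 8.0) - math.exp(-0.1 / 0.5), rel=1e-12
        )
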