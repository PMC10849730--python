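"""Single-neuron Hodgkin-Huxley model: gating kinetics, currents, calcium,
spike detection, and resting/spiking behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alnet import neurons
from alnet.neurons import (ChannelSpec, GatingState, CalciumState,
                           LN_PASSIVE, PN_PASSIVE, channels_for_role,
                           detect_spikes, gating_rates, initial_state,
                           integrate_single_neuron, intrinsic_current,
                           membrane_derivative, calcium_derivative)

ALL_CHANNELS = [(role, c) for role in ("PN", "LN")
                for c in channels_for_role(role)]


@pytest.mark.parametrize("role,channel", ALL_CHANNELS,
                         ids=[f"{r}-{c.name}" for r, c in ALL_CHANNELS])
def test_gating_rates_are_valid_over_voltage_range(role, channel):
    """x_inf in [0,1] and tau > 0 for all gates across -120..60 mV."""
    for v in np.linspace(-120, 60, 181):
        inf, tau = gating_rates(v, channel, "activation")
        assert 0.0 <= inf <= 1.0 and tau > 0.0
        if channel.N > 0:
            inf, tau = gating_rates(v, channel, "inactivation")
            assert 0.0 <= inf <= 1.0 and tau > 0.0


def test_inactivation_request_on_gateless_channel_raises():
    k = next(c for c in channels_for_role("PN") if c.name == "K")
    with pytest.raises(ValueError):
        gating_rates(-60.0, k, "inactivation")


def test_gate_fixed_point_and_closed_form_relaxation():
    """At fixed V, m stays at m_inf; from m=0 it follows
    m(t) = m_inf (1 - exp(-t/tau)), verified against tiny-step Euler."""
    na = channels_for_role("PN")[0]
    V = -55.0
    m_inf, tau = gating_rates(V, na, "activation")
    # fixed point
    m = m_inf
    dt = 1e-3
    for _ in range(1000):
        m += dt * (m_inf - m) / tau
    assert m == pytest.approx(m_inf, abs=1e-12)
    # relaxation from zero vs closed form
    m, t = 0.0, 0.0
    for _ in range(2000):
        m += dt * (m_inf - m) / tau
        t += dt
    assert m == pytest.approx(m_inf * (1 - np.exp(-t / tau)), rel=1e-3)


def test_intrinsic_current_form_and_zeros():
    na = channels_for_role("PN")[0]
    g = GatingState(m=0.5, h=0.8)
    # reversal potential
    assert intrinsic_current(na, g, na.E) == 0.0
    # closed gate
    assert intrinsic_current(na, GatingState(m=0.0, h=1.0), -20.0) == 0.0
    # explicit product
    v = -20.0
    assert intrinsic_current(na, g, v) == pytest.approx(
        na.gmax * 0.5 ** 3 * 0.8 * (v - na.E))


def test_printed_maximal_conductances():
    pn = {c.name: c.gmax for c in channels_for_role("PN")}
    ln = {c.name: c.gmax for c in channels_for_role("LN")}
    assert pn == {"Na": 90.0, "K": 10.0, "A": 10.0, "T": 2.0, "h": 0.02}
    assert ln == {"Na": 100.0, "K": 10.0, "T": 1.75}


def test_printed_passive_parameters():
    assert (PN_PASSIVE.Cm, PN_PASSIVE.gL, PN_PASSIVE.gKL) == (2.9e-4, 0.01, 0.012)
    assert (LN_PASSIVE.Cm, LN_PASSIVE.gL, LN_PASSIVE.gKL) == (1.43e-4, 0.05, 0.018)
    assert PN_PASSIVE.EL == LN_PASSIVE.EL == -70.0
    assert PN_PASSIVE.EKL == LN_PASSIVE.EKL == -95.0


def test_membrane_derivative_rest_and_two_leak_steady_state():
    """dV/dt = 0 at the common reversal when all currents vanish, and with
    only the two leaks active V relaxes to their conductance-weighted mean
    (closed form vs tiny-step integration)."""
    st0 = initial_state("PN", V=-70.0)
    passive = neurons.PassiveParams(Cm=2.9e-4, gL=0.01, gKL=0.012,
                                    EL=-70.0, EKL=-70.0, area=2.9e-4)
    zeroed = [ChannelSpec(c.name, 0.0, c.E, c.M, c.N)
              for c in channels_for_role("PN")]
    assert membrane_derivative(st0, passive, zeroed) == pytest.approx(0.0)

    passive2 = PN_PASSIVE
    v_target = (passive2.gL * passive2.EL + passive2.gKL * passive2.EKL) \
        / (passive2.gL + passive2.gKL)
    s = initial_state("PN", V=-60.0)
    v, dt = s.V, 0.05
    for _ in range(200000):
        s.V = v
        v += dt * membrane_derivative(s, passive2, zeroed)
    assert v == pytest.approx(v_target, abs=1e-3)


def test_membrane_derivative_rejects_wrong_channel_set():
    s = initial_state("PN")
    with pytest.raises(ValueError):
        membrane_derivative(s, PN_PASSIVE, channels_for_role("LN"))


def test_calcium_fixed_point_and_printed_parameters():
    cal = CalciumState()
    assert (cal.Ca_inf, cal.A_ca, cal.tau_ca) == (2.4e-4, 5.2e-5, 5.0)
    assert calcium_derivative(cal, 0.0) == 0.0
    # constant I_T: steady state Ca = Ca_inf - A*tau*I_T, vs integration
    I_T = -0.5
    target = cal.Ca_inf - cal.A_ca * cal.tau_ca * I_T
    ca, dt = cal.Ca_inf, 1e-3
    for _ in range(50000):
        cal.Ca = ca
        ca += dt * calcium_derivative(cal, I_T)
    assert ca == pytest.approx(target, rel=1e-4)


class TestDetectSpikes:
    dt = 0.1

    def test_flat_trace_has_no_spikes(self):
        assert detect_spikes(np.full(1000, -70.0), self.dt) == []

    def test_single_excursion_yields_one_spike(self):
        v = np.concatenate([np.full(50, -70.0), np.linspace(-70, 30, 20),
                            np.linspace(30, -70, 20), np.full(50, -70.0)])
        assert len(detect_spikes(v, self.dt)) == 1

    def test_empty_trace(self):
        assert detect_spikes([], self.dt) == []

    @given(st.integers(min_value=1, max_value=12),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_k_separated_excursions_give_k_spikes(self, k, seed):
        """Synthetic trace with k well-separated excursions, checked
        against a brute-force enumeration of upward crossings."""
        rng = np.random.default_rng(seed)
        segs = [np.full(30, -70.0)]
        for _ in range(k):
            peak = rng.uniform(10, 40)
            segs += [np.linspace(-70, peak, 12), np.linspace(peak, -70, 12),
                     np.full(30, -70.0)]
        v = np.concatenate(segs)
        brute = sum(1 for i in range(1, len(v))
                    if v[i] >= 0.0 > v[i - 1])
        found = detect_spikes(v, self.dt)
        assert len(found) == brute == k


def test_rest_is_stable_and_silent():
    """With zero input both cell types settle to a stationary subthreshold
    resting potential and never spike."""
    for role in ("PN", "LN"):
        t, v = integrate_single_neuron(role, 0.0, 1000.0, 0.04)
        assert detect_spikes(v, 0.04) == []
        assert abs(v[-1] - v[-250]) < 0.05          # stationary within 10 ms
        assert v[-1] < -60.0


def test_strong_step_elicits_repetitive_spiking():
    for role, amp in (("PN", 1.5e-3), ("LN", 3e-4)):
        t, v = integrate_single_neuron(role, amp, 400.0, 0.04)
        assert len(detect_spikes(v, 0.04)) >= 5


def test_gating_variables_remain_in_unit_interval_during_spiking():
    """The relaxation ODE dm/dt=(m_inf - m)/tau keeps m in [0,1] along any
    voltage trajectory because m_inf is; checked with the exact
    piecewise-exponential solution along a spiking trajectory."""
    t, v = integrate_single_neuron("PN", 1.5e-3, 100.0, 0.04)
    na = channels_for_role("PN")[0]
    m = gating_rates(v[0], na, "activation")[0]
    for vi in v:
        inf, tau = gating_rates(vi, na, "activation")
        m = inf + (m - inf) * np.exp(-0.04 / tau)
        assert 0.0 <= m <= 1.0
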