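"""Odor construction: pulse envelope, percept profiles, blends, sensor
features, odor classes, composed input currents."""

import numpy as np
import pytest

from alnet import network, stimuli
from alnet.stimuli import (Odor, Percept, PulseSpec, SensorFeatureTriple,
                           StimulusParams, blend_to_odor, compose_odor_input,
                           make_odor_class, percept_profile, pulse_envelope,
                           sensor_features_to_pulse)


class TestPulseEnvelope:
    spec = PulseSpec()

    def test_printed_time_constants(self):
        assert (self.spec.tau_rise, self.spec.tau_decay,
                self.spec.duration) == (66.7, 200.0, 500.0)

    def test_zero_at_onset_and_decayed_after(self):
        assert pulse_envelope(0.0, self.spec) == 0.0
        assert pulse_envelope(-50.0, self.spec) == 0.0
        assert pulse_envelope(self.spec.duration + 5 * self.spec.tau_decay,
                              self.spec) < 0.01

    def test_unit_peak_by_dense_grid_search(self):
        t = np.linspace(0, 3000, 300001)
        env = pulse_envelope(t, self.spec)
        assert abs(env.max() - 1.0) < 1e-6
        assert np.all(env >= 0) and np.all(env <= 1 + 1e-12)

    def test_rise_and_decay_shape(self):
        # monotone rise during the pulse, monotone decay after
        t_rise = np.linspace(0, 500, 501)
        t_fall = np.linspace(500, 1500, 501)
        assert np.all(np.diff(pulse_envelope(t_rise, self.spec)) >= 0)
        assert np.all(np.diff(pulse_envelope(t_fall, self.spec)) <= 0)


class TestPerceptProfile:
    percept = Percept(1, (0, 15))
    odor = Odor("x", {1}, {1: 0.372})

    def test_peak_at_center_symmetry_and_monotonicity(self):
        prof = percept_profile(self.odor, self.percept)
        assert prof.max() == pytest.approx(1.0)
        assert np.argmax(prof) == 7            # block center
        assert np.allclose(prof, prof[::-1])   # symmetric
        assert np.all(np.diff(prof[:8]) > 0)   # monotone toward center
        assert np.all(np.diff(prof[7:]) < 0)

    def test_inactive_percept_rejected(self):
        with pytest.raises(ValueError):
            percept_profile(self.odor, Percept(2, (15, 30)))

    def test_width_controls_spread(self):
        wide = percept_profile(Odor("w", {1}, {1: 0.8}), self.percept)
        narrow = percept_profile(Odor("n", {1}, {1: 0.2}), self.percept)
        assert wide.sum() > narrow.sum()


def test_blend_to_odor_maps_proportion_to_width():
    odor = blend_to_odor([0.372, 0.0, 0.25], "PH1", valence="rewarded")
    assert odor.active_percepts == {1, 3}
    assert odor.widths[1] == pytest.approx(0.372)
    assert 2 not in odor.widths
    # the final percept stays inactive even for a full 6-component blend
    full = blend_to_odor([0.2, 0.2, 0.2, 0.2, 0.1, 0.1], "PH2")
    assert 7 not in full.active_percepts
    with pytest.raises(ValueError):
        blend_to_odor([1.2], "bad")
    # equivariance: permuting equal proportions permutes widths
    a = blend_to_odor([0.3, 0.7], "a")
    b = blend_to_odor([0.7, 0.3], "b")
    assert a.widths[1] == b.widths[2] and a.widths[2] == b.widths[1]


def test_sensor_features_to_pulse_proportionality():
    t = SensorFeatureTriple(dR=2.0, ema_max=0.02, ema_min=0.005)
    p = sensor_features_to_pulse(t)
    assert p.tau_rise == pytest.approx(1 / 0.02)
    assert p.tau_decay == pytest.approx(1 / 0.005)
    assert p.amplitude == pytest.approx(2.0)
    double = sensor_features_to_pulse(
        SensorFeatureTriple(dR=4.0, ema_max=0.04, ema_min=0.005))
    assert double.amplitude == pytest.approx(2 * p.amplitude)
    assert double.tau_rise == pytest.approx(p.tau_rise / 2)
    same = sensor_features_to_pulse(t)
    assert same == p
    with pytest.raises(ValueError):
        SensorFeatureTriple(dR=1.0, ema_max=0.0, ema_min=0.1)


def test_make_odor_class_layout_and_determinism():
    a = make_odor_class({1, 2, 3}, "rewarded", "A", n_odors=10, seed=4)
    b = make_odor_class({5, 6, 7}, "habituated", "B", n_odors=10, seed=5)
    assert len(a) == 10
    assert all(o.active_percepts == {1, 2, 3} for o in a)
    assert all(w > 0 for o in a for w in o.widths.values())
    assert a[0].active_percepts.isdisjoint(b[0].active_percepts)
    again = make_odor_class({1, 2, 3}, "rewarded", "A", n_odors=10, seed=4)
    assert [o.widths for o in again] == [o.widths for o in a]
    widths = [tuple(sorted(o.widths.values())) for o in a]
    assert len(set(widths)) == len(widths)      # odors differ
    with pytest.raises(ValueError):
        make_odor_class(set(), "rewarded", "E")


class TestComposeOdorInput:
    net = network.build_reduced_network(0, n_glomeruli=4)
    odor = make_odor_class({1, 2, 3}, "rewarded", "A", 1, seed=0)[0]
    kw = dict(pulse=PulseSpec(), duration=400.0, odor_onset=100.0, dt=0.5)

    def test_zero_everything_gives_zero_input(self):
        silent = Odor("none", {1}, {1: 0.3})
        silent = stimuli.Odor("none", frozenset(), {}, "neutral")
        I = compose_odor_input(silent, self.net, noise_sd=0.0, seed=0,
                               **self.kw)
        assert np.all(I == 0)

    def test_symmetric_neurons_receive_identical_noiseless_input(self):
        I = compose_odor_input(self.odor, self.net, noise_sd=0.0, seed=0,
                               **self.kw)
        blocks = self.net.pn_percept_blocks(7)
        a, b = blocks[0]            # first active percept block
        prof = I[a:b, :].max(axis=1)
        assert np.allclose(prof, prof[::-1], rtol=1e-12)

    def test_noise_time_average_obeys_clt_bound(self):
        sd = 2e-4
        I = compose_odor_input(stimuli.Odor("none", frozenset(), {}),
                               self.net, noise_sd=sd, seed=3, **self.kw)
        n_blocks = 400  # 1 ms hold blocks over 400 ms
        bound = 3 * sd / np.sqrt(n_blocks)
        assert np.all(np.abs(I.mean(axis=1)) < bound * 1.5)

    def test_deterministic_given_seed(self):
        a = compose_odor_input(self.odor, self.net, noise_sd=1e-4, seed=9,
                               **self.kw)
        b = compose_odor_input(self.odor, self.net, noise_sd=1e-4, seed=9,
                               **self.kw)
        c = compose_odor_input(self.odor, self.net, noise_sd=1e-4, seed=10,
                               **self.kw)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_multipolar_lns_receive_scaled_global_drive(self):
        params = StimulusParams()
        drive = stimuli.network_drive(self.odor, self.net, 7, params)
        multi = drive[self.net.n_pn + self.net.n_uni:]
        uni = drive[self.net.n_pn:self.net.n_pn + self.net.n_uni]
        assert np.allclose(multi, params.multipolar_gain * uni.mean())
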