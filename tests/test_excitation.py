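"""Voltage spread, activation function and induced current."""
import numpy as np
import pytest

from cisim import cochlea, excitation as ex, fitting, sound_coding as sc


class TestVoltage:
    def test_point_source_value(self):
        # 1 mA at 1 mm in a 3 Ohm*m medium
        u = ex.RHO_EXT_OHM_M * 1e-3 / (4 * np.pi * 1e-3)
        assert u == pytest.approx(0.2387, abs=1e-4)

    def test_zero_current_zero_voltage(self, tiny_interface):
        u = ex.voltage_at_nodes(np.zeros(16), tiny_interface)
        assert np.all(u == 0)

    def test_inverse_distance(self, tiny_interface):
        cur = np.zeros(16)
        cur[0] = 1000.0
        u1 = ex.voltage_at_nodes(cur, tiny_interface)
        d = tiny_interface.distances_mm()[:, :, 0]
        assert np.allclose(u1 * d, u1[0, 0] * d[0, 0])


class TestActivationFunction:
    def test_internal_resistance_value(self):
        assert ex.axon_internal_resistance() / 1e6 == pytest.approx(63.66, abs=0.01)

    def test_uniform_voltage_gives_zero(self):
        a = ex.activation_function(np.full(10, 3.3), 1.0)
        assert np.allclose(a, 0.0)

    def test_toy_hand_value(self):
        a = ex.activation_function(np.array([1.0, 0.0, 0.0]), 1.0)
        assert a[1] == pytest.approx(1.0)

    def test_terminal_nodes_excluded(self):
        a = ex.activation_function(np.array([5.0, 1.0, 0.2, 4.0]), 2.0)
        assert a[0] == 0.0 and a[-1] == 0.0

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            ex.activation_function(np.array([1.0, 2.0]), 1.0)


class TestDegenerationEffect:
    def test_max_activation_non_increasing_with_alpha(self, tiny_interface):
        prev = None
        for alpha in (0, 5, 10, 15, 20):
            itf = cochlea.apply_degeneration(tiny_interface, alpha, 0, seed=0)
            m = ex.ExcitationModel(itf)
            strength = m.fiber_electrode_strength()
            if prev is not None:
                assert np.all(strength <= prev + 1e-18)
            prev = strength

    def test_degenerated_nodes_carry_no_activation(self, degenerated_interface):
        m = ex.ExcitationModel(degenerated_interface)
        for f in (0, 40, 90):
            al = degenerated_interface.alpha[f]
            assert np.all(m.unit_activation[f, :al + 1, :] == 0)


class TestInducedCurrent:
    def _one_pulse(self, channel, cu, steer=0.5):
        ev = np.zeros(1, dtype=sc.EVENT_DTYPE)
        ev["onset_us"], ev["channel"] = 0.0, channel
        ev["electrode_apical"], ev["electrode_basal"] = channel, channel + 1
        ev["steering"], ev["amplitude_cu"], ev["phase_us"] = steer, cu, 18.0
        return sc.Electrodogram(ev, 72.0)

    def test_linear_in_amplitude(self, tiny_model):
        t1 = ex.induced_current(self._one_pulse(8, 50), tiny_model)
        t2 = ex.induced_current(self._one_pulse(8, 100), tiny_model)
        m = np.abs(t1.currents_a).max(axis=1) > 0
        np.testing.assert_allclose(t2.currents_a[m], 2 * t1.currents_a[m],
                                   rtol=1e-9)

    def test_spatial_decay_with_distance(self, tiny_model):
        trace = ex.induced_current(self._one_pulse(8, 100), tiny_model)
        peak = np.abs(trace.currents_a).max(axis=1)
        d = tiny_model.interface.distances_mm()[:, :, 7].min(axis=1)
        near = peak[np.argsort(d)[:10]].mean()
        far = peak[np.argsort(d)[-10:]].mean()
        assert near > 10 * far

    def test_opposite_sign_channels_cancel(self, tiny_model):
        # where two simultaneous channels have opposite-sign activation at a
        # fiber's dominant node, the combined |I| falls below the stronger
        # channel alone (electrical-interaction attenuation)
        ev = np.zeros(2, dtype=sc.EVENT_DTYPE)
        for i, ch in enumerate((6, 11)):
            ev[i]["onset_us"], ev[i]["channel"] = 0.0, ch
            ev[i]["electrode_apical"], ev[i]["electrode_basal"] = ch, ch + 1
            ev[i]["steering"], ev[i]["amplitude_cu"], ev[i]["phase_us"] = 0.5, 100, 18.0
        both = ex.induced_current(sc.Electrodogram(ev, 72.0), tiny_model,
                                  keep_a_max=True)
        p_both = np.abs(both.currents_a).max(axis=1)
        amp_a = sc.cu_to_microamps(100, 18.0) * 1e-6
        pat7 = tiny_model.channel_patterns[5, 4] * amp_a * both.m_c
        pat9 = tiny_model.channel_patterns[10, 4] * amp_a * both.m_c
        p_max_single = np.maximum(np.abs(pat7).max(axis=1), np.abs(pat9).max(axis=1))
        # sign opposition at the combined argmax node
        node = np.abs(pat7 + pat9).argmax(axis=1)
        take = lambda p: np.take_along_axis(p, node[:, None], axis=1)[:, 0]
        opposed = np.sign(take(pat7)) * np.sign(take(pat9)) < 0
        attenuated = p_both < p_max_single - 1e-15
        assert np.any(opposed)
        assert np.any(attenuated & opposed)

    def test_kernel_path_matches_generic_path(self, tiny_model, quiet_params):
        """The fast population path and the generic electrodogram path agree
        on the induced-current drive (checked through identical spike output
        for a deterministic stimulus)."""
        from cisim.anf import simulate_spikes
        from cisim.pipeline import simulate_population, single_channel_schedule
        cu = 300.0
        n_cycles = 20
        eg_events = []
        for k in range(n_cycles):
            eg_events.append((k * 540.0, 8, 8, 9, 0.5, cu, 18.0))
        eg = sc.Electrodogram(np.array(eg_events, dtype=sc.EVENT_DTYPE),
                              n_cycles * 540.0)
        trace = ex.induced_current(eg, tiny_model)
        spk_generic = simulate_spikes(trace, quiet_params, seed=0)
        amp = np.zeros((n_cycles, 15))
        amp[:, 7] = cu
        steer = np.full((n_cycles, 15), 4, dtype=np.int64)
        spk_kernel = simulate_population(tiny_model, single_channel_schedule(8),
                                         amp, steer, quiet_params, seed=0)
        assert np.array_equal(spk_kernel.counts, spk_generic.counts)
        for f in range(spk_kernel.n_fibers):
            np.testing.assert_allclose(spk_kernel.fiber(f), spk_generic.fiber(f),
                                       atol=2e-6)
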