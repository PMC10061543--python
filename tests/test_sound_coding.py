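"""Sound coding: pulse tables, unit conversion, electrodogram invariants."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from cisim import sound_coding as sc


class TestCuToMicroamps:
    @pytest.mark.parametrize("cu,phase,expected", [
        (0, 18, 0.0),                  # linearity through the origin
        (250, 18, 1081.4),             # hand evaluation of the CU law
        (471, 229, 160.1),             # max CU at max phase duration
    ])
    def test_known_values(self, cu, phase, expected):
        assert sc.cu_to_microamps(cu, phase) == pytest.approx(expected, abs=0.05)

    def test_linear_in_cu(self):
        assert sc.cu_to_microamps(200) == pytest.approx(2 * sc.cu_to_microamps(100))

    def test_invalid_phase(self):
        with pytest.raises(ValueError):
            sc.cu_to_microamps(100, 0.0)


class TestPulseTable:
    def test_sequential(self):
        t = sc.build_pulse_table("S")
        assert len(t.groups) == 15
        assert all(len(g) == 1 for g in t.groups)
        assert t.gap_us == 0.0
        assert t.channel_period_us == 540.0
        # ~1852 pps per channel
        assert 1 / (t.channel_period_us * 1e-6) == pytest.approx(1852, abs=1)

    def test_triplet_groups(self):
        t = sc.build_pulse_table("T")
        assert t.groups == ((1, 6, 11), (2, 7, 12), (3, 8, 13), (4, 9, 14),
                            (5, 10, 15))
        assert t.gap_slots == 2
        assert t.gap_us == pytest.approx(2 * t.slot_duration_us)

    def test_paired_contains_6_with_14(self):
        t = sc.build_pulse_table("P")
        group = next(g for g in t.groups if 6 in g)
        assert 14 in group

    @pytest.mark.parametrize("variant", ["S", "P", "T"])
    def test_each_channel_once_and_period(self, variant):
        t = sc.build_pulse_table(variant)
        chans = sorted(ch for g in t.groups for ch in g)
        assert chans == list(range(1, 16))
        active = len(t.groups) * t.slot_duration_us
        assert active + len(t.groups) * t.gap_us == pytest.approx(540.0)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            sc.build_pulse_table("X")


class TestEncode:
    def test_empty_audio(self, flat_map):
        eg = sc.encode(np.zeros(0), 17400.0, flat_map, "S")
        assert len(eg) == 0

    def test_silence_floors_at_t_level(self, flat_map):
        eg = sc.encode(np.zeros(17400), 17400.0, flat_map, "S")
        assert np.all(eg.events["amplitude_cu"] <= flat_map.t_cu.max() + 1e-9)

    def test_tone_maximal_on_matching_band(self, flat_map):
        cfg = sc.CoderConfig()
        edges = cfg.band_edges()
        band = 7
        f0 = np.sqrt(edges[band] * edges[band + 1])
        t = np.arange(17400) / 17400.0
        audio = 0.01 * np.sin(2 * np.pi * f0 * t)
        eg = sc.encode(audio, 17400.0, flat_map, "S", cfg)
        mean_amp = [eg.events["amplitude_cu"][eg.events["channel"] == ch].mean()
                    for ch in range(1, 16)]
        assert int(np.argmax(mean_amp)) == band

    @pytest.mark.parametrize("variant", ["S", "P", "T"])
    def test_per_channel_rate_constant(self, flat_map, variant):
        audio = np.random.default_rng(0).normal(0, 0.003, 17400)
        eg = sc.encode(audio, 17400.0, flat_map, variant)
        for ch in (1, 8, 15):
            onsets = np.sort(eg.events["onset_us"][eg.events["channel"] == ch])
            assert np.allclose(np.diff(onsets), 540.0)

    @pytest.mark.parametrize("variant", ["S", "P", "T"])
    def test_charge_balance(self, flat_map, variant):
        audio = np.random.default_rng(1).normal(0, 0.003, 8700)
        eg = sc.encode(audio, 17400.0, flat_map, variant)
        assert eg.charge_imbalance() < 1e-6

    def test_unfitted_map_rejected(self):
        bad = sc.FittingMap(mcl_cu=np.zeros(15))
        with pytest.raises(RuntimeError):
            sc.encode(np.zeros(1000), 17400.0, bad, "S")


class TestElectrodogram:
    def test_steering_splits_current(self):
        ev = np.zeros(1, dtype=sc.EVENT_DTYPE)
        ev["onset_us"] = 0.0
        ev["channel"] = 3
        ev["electrode_apical"] = 3
        ev["electrode_basal"] = 4
        ev["steering"] = 3 / 8
        ev["amplitude_cu"] = 120
        ev["phase_us"] = 18.0
        eg = sc.Electrodogram(ev, 100.0)
        total = sc.cu_to_microamps(120, 18.0)
        dense = eg.to_dense(1e6)
        # cathodic first: negative current on both pair electrodes
        assert dense[2, 0] == pytest.approx(-total * (1 - 3 / 8))
        assert dense[3, 0] == pytest.approx(-total * (3 / 8))
        # anodic second phase mirrors it
        assert dense[2, 18] == pytest.approx(total * (1 - 3 / 8))
        # pair current conservation
        assert dense[:, 0].sum() == pytest.approx(-total)

    def test_dense_round_trip_duration(self, flat_map):
        audio = np.random.default_rng(2).normal(0, 0.003, 5400 * 2)
        eg = sc.encode(audio, 17400.0, flat_map, "S")
        dense = eg.to_dense(1e6)
        assert dense.shape == (16, int(round(eg.duration_us)))

    @given(cu=hst.floats(1, 471), steer=hst.integers(0, 7))
    @settings(max_examples=25, deadline=None)
    def test_charge_balance_any_pulse(self, cu, steer):
        ev = np.zeros(1, dtype=sc.EVENT_DTYPE)
        ev["onset_us"], ev["channel"] = 0.0, 5
        ev["electrode_apical"], ev["electrode_basal"] = 5, 6
        ev["steering"], ev["amplitude_cu"], ev["phase_us"] = steer / 8, cu, 18.0
        assert sc.Electrodogram(ev, 50.0).charge_imbalance() < 1e-9
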