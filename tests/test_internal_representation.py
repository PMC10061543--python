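"""Internal representation: grouping, binning, filtering, masking, decimation."""
import numpy as np
import pytest

from cisim import internal_representation as ir
from cisim.anf import SpikeActivity


def make_spikes(times_per_fiber, duration=0.5):
    n = len(times_per_fiber)
    width = max((len(t) for t in times_per_fiber), default=1)
    buf = np.zeros((n, max(width, 1)))
    counts = np.zeros(n, dtype=np.int64)
    for f, t in enumerate(times_per_fiber):
        buf[f, :len(t)] = t
        counts[f] = len(t)
    return SpikeActivity(times=buf, counts=counts, duration_s=duration)


class TestGroupFibers:
    def test_partition_and_bounds(self, tiny_interface, tiny_model):
        bank = ir.group_fibers(tiny_interface, tiny_model)
        # disjoint and exhaustive
        all_members = np.sort(np.concatenate(bank.groups))
        assert np.array_equal(all_members, np.arange(tiny_interface.n_fibers))
        assert ir.MIN_GROUPS <= bank.n_groups <= ir.MAX_GROUPS
        # all extents in bounds except possibly the apical-most remainder
        assert np.all(bank.extents_mm[:-1] >= ir.MIN_EXTENT_MM - 1e-9)
        assert np.all(bank.extents_mm <= ir.MAX_EXTENT_MM + 1e-9)

    def test_groups_within_bounds_after_degeneration(self, degenerated_interface):
        from cisim.excitation import ExcitationModel
        bank = ir.group_fibers(degenerated_interface,
                               ExcitationModel(degenerated_interface))
        assert ir.MIN_GROUPS <= bank.n_groups <= ir.MAX_GROUPS


class TestMergeSplitRules:
    """Hand-checkable toy: labels drive runs directly."""

    def _bank_from_labels(self, labels, pos):
        # exercise the run/merge/split machinery through a stub model
        class StubModel:
            def fiber_electrode_strength(self_inner):
                s = np.zeros((len(labels), 16))
                s[np.arange(len(labels)), labels] = 1.0
                return s

        class StubItf:
            bm_position_mm = pos

        return ir.group_fibers(StubItf(), StubModel(),
                               ir.IRConfig(smooth_window=1))

    def test_runs_unchanged_when_in_bounds(self):
        pos = np.arange(40) * 0.1   # 4 mm of BM, ds = 0.1
        labels = np.repeat([3, 4], 20)       # two 2.0 mm runs
        bank = self._bank_from_labels(labels, pos)
        assert bank.n_groups == 2
        assert np.array_equal(bank.groups[0], np.arange(20))

    def test_small_run_merges_toward_apex(self):
        pos = np.arange(45) * 0.1
        labels = np.concatenate([np.repeat(3, 20), np.repeat(4, 5),
                                 np.repeat(5, 20)])   # middle run 0.5 mm
        bank = self._bank_from_labels(labels, pos)
        assert bank.n_groups == 2
        # the 0.5 mm run joined the next (apical) group
        assert np.array_equal(bank.groups[1], np.arange(20, 45))

    def test_oversize_run_split_basal_first(self):
        pos = np.arange(60) * 0.1    # 6.0 mm single run
        labels = np.repeat(7, 60)
        bank = self._bank_from_labels(labels, pos)
        assert bank.n_groups >= 2
        assert bank.extents_mm[0] == pytest.approx(ir.MAX_EXTENT_MM, abs=0.11)
        assert np.all(bank.extents_mm >= ir.MIN_EXTENT_MM - 1e-9)


class TestSpikeGroupActivity:
    def _simple_bank(self):
        return ir.AuditoryFilterBank(groups=[np.array([0, 1]), np.array([2])],
                                     extents_mm=np.array([2.0, 2.0]))

    def test_no_spikes_all_zero(self):
        s = ir.spike_group_activity(make_spikes([[], [], []]), self._simple_bank())
        assert np.all(s == 0)

    def test_count_conservation(self):
        spk = make_spikes([[0.01, 0.02], [0.015], [0.3, 0.31, 0.32]])
        s = ir.spike_group_activity(spk, self._simple_bank())
        assert s.sum() == 6

    def test_same_bin_accumulates(self):
        spk = make_spikes([[0.10001], [0.10005], []])
        s = ir.spike_group_activity(spk, self._simple_bank())
        assert s[0].max() == 2


class TestTemporalFilter:
    def test_zero_in_zero_out(self):
        assert np.all(ir.temporal_filter(np.zeros((3, 100))) == 0)

    def test_impulse_gives_kernel(self):
        x = np.zeros((1, 201))
        x[0, 100] = 1.0
        y = ir.temporal_filter(x)[0]
        k = ir.gaussian_kernel()
        half = len(k) // 2
        np.testing.assert_allclose(y[100 - half:100 + half + 1], k, atol=1e-12)

    def test_dc_preserved(self):
        y = ir.temporal_filter(np.full((1, 500), 3.7))
        assert y[0, 250] == pytest.approx(3.7)


class TestForwardMasking:
    def test_steady_state_equals_input(self):
        x = np.full((1, 5000), 2.0)
        y = ir.forward_masking(x)
        assert y[0, -1] == pytest.approx(2.0, rel=1e-3)

    def test_release_decay_rate(self):
        fs, tau_r = 10_000.0, 50e-3
        x = np.zeros((1, 4000))
        x[0, :500] = 1.0
        y = ir.forward_masking(x, fs=fs, tau_release_s=tau_r)
        k0, k1 = 700, 1700       # 100 ms apart inside the silent tail
        ratio = y[0, k1] / y[0, k0]
        assert ratio == pytest.approx(np.exp(-(k1 - k0) / (fs * tau_r)), rel=0.02)

    def test_output_dominates_input(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(2.0, size=(4, 2000)).astype(float)
        y = ir.forward_masking(x)
        assert np.all(y >= x - 1e-12)


class TestDownsample:
    def test_constant_preserved(self):
        y = ir.downsample_ir(np.full((2, 4000), 1.3))
        assert np.allclose(y, 1.3)

    def test_output_length(self):
        y = ir.downsample_ir(np.zeros((2, 4000)))
        assert y.shape == (2, 40)

    def test_impulse_window_average(self):
        x = np.zeros((1, 1000))
        x[0, 123] = 7.0
        y = ir.downsample_ir(x)
        assert y[0, 1] == pytest.approx(7.0 / 100)
        assert y.sum() == pytest.approx(7.0 / 100)


class TestFullChain:
    def test_non_negative_and_finite(self, tiny_interface, tiny_model):
        ext = ir.InternalRepresentationExtractor(tiny_interface, tiny_model)
        rng = np.random.default_rng(1)
        spikes = make_spikes([np.sort(rng.uniform(0, 0.4, rng.integers(0, 40)))
                              for _ in range(tiny_interface.n_fibers)],
                             duration=0.4)
        out = ext(spikes)
        assert out.shape == (ext.bank.n_groups, 40)
        assert np.all(np.isfinite(out)) and np.all(out >= 0)
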