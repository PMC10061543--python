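"""Virtual fitting: pulse trains, group selection, MCL estimation, M_C."""
import numpy as np
import pytest

from cisim import cochlea, excitation as ex, fitting, sound_coding as sc
from cisim.anf import NeuronParams


class TestFittingPulseTrain:
    def test_pulse_count_and_duration(self):
        eg = fitting.make_fitting_pulse_train(8, 100)
        assert len(eg) == 370                       # floor(200 ms / 540 us)
        assert eg.duration_us == pytest.approx(220_000)

    def test_rate_and_margins(self):
        eg = fitting.make_fitting_pulse_train(3, 50)
        onsets = eg.events["onset_us"]
        assert onsets[0] == pytest.approx(10_000)
        assert np.allclose(np.diff(onsets), 540.0)
        rate = 1e6 / 540.0
        assert rate == pytest.approx(1852, abs=1)

    def test_charge_balanced(self):
        eg = fitting.make_fitting_pulse_train(1, 471)
        assert eg.charge_imbalance() < 1e-6

    @pytest.mark.parametrize("cu", [0, 472])
    def test_cu_out_of_range(self, cu):
        with pytest.raises(ValueError):
            fitting.make_fitting_pulse_train(5, cu)


class TestSelectFittingGroup:
    def test_full_scale_group_size(self):
        assert fitting.scaled_group_size(9001) == 858

    def test_proportional_scaling(self):
        assert fitting.scaled_group_size(10) == 1
        assert fitting.scaled_group_size(901) == 86

    def test_group_size_and_ranking(self, tiny_model):
        grp = fitting.select_fitting_group(8, tiny_model)
        assert len(grp) == fitting.scaled_group_size(tiny_model.interface.n_fibers)
        strength = np.max(np.abs(tiny_model.channel_patterns[7, 4]), axis=1)
        cutoff = np.sort(strength)[::-1][len(grp) - 1]
        assert np.all(strength[grp] >= cutoff)

    def test_group_near_channel_electrodes(self, tiny_interface, tiny_model):
        # apical channel's group sits closer (in insertion angle) to its
        # electrodes than a random group of the same size
        grp = fitting.select_fitting_group(2, tiny_model)
        e_idx = 1    # electrode 2 (0-based)
        d = tiny_interface.distances_mm()[:, :, e_idx].min(axis=1)
        rng = np.random.default_rng(0)
        rand = rng.choice(tiny_interface.n_fibers, size=len(grp), replace=False)
        assert d[grp].mean() < d[rand].mean()


@pytest.fixture(scope="module")
def small_model():
    itf = cochlea.build_geometry(cochlea.CochleaConfig(n_fibers=301))
    itf = cochlea.apply_degeneration(itf, 5, 3, seed=1)
    return ex.ExcitationModel(itf)


class TestEstimateMcl:

    def test_mcl_within_range_and_t_rule(self, small_model):
        mcl = fitting.estimate_mcl(8, small_model, seeds=(0, 1, 2))
        assert 1 <= mcl <= 250
        fmap = sc.FittingMap(mcl_cu=np.full(15, float(mcl)))
        assert np.all(fmap.t_cu == round(0.1 * mcl))
        # 20 dB electric dynamic range
        assert 20 * np.log10(mcl / fmap.t_cu[0]) == pytest.approx(20, abs=0.5)

    def test_probability_monotone_in_cu(self, small_model):
        params = NeuronParams()
        grp = fitting.select_fitting_group(8, small_model)
        seeds = (0, 1, 2, 3, 4)
        probs = [fitting.pulse_response_probability(8, cu, small_model, grp,
                                                    params, ex.MC_DEFAULT, seeds)
                 for cu in (1, 61, 121, 181, 241)]
        assert all(b >= a - 0.02 for a, b in zip(probs, probs[1:]))

    def test_known_threshold_recovered_within_one_step(self, small_model):
        """With noise off the fitting sweep recovers the deterministic
        threshold of the underlying integrate-and-fire group."""
        params = NeuronParams(noise_sd_a=0.0, a_sub=0.0, b_supra_a=0.0)
        grp = fitting.select_fitting_group(8, small_model)
        # exact per-fiber threshold: smallest cu whose single-phase drive
        # crosses v_th on the cathodic circuit within one 18 us phase
        pat = small_model.channel_patterns[7, 4]
        k = np.max(np.abs(pat[grp]), axis=1) * ex.MC_DEFAULT \
            * sc.cu_to_microamps(1, 18.0) * 1e-6        # A per CU
        r = params.tau_m_us * 1e-6 / params.c_cathodic_f
        gain = r * (1 - np.exp(-18.0 / params.tau_m_us))
        cu_threshold = params.v_threshold / (k * gain)
        # analytic criterion: cu where 75% of the group is suprathreshold
        cu_star = np.quantile(cu_threshold, 0.75)
        mcl = fitting.estimate_mcl(8, small_model, params, seeds=(0,))
        assert abs(mcl - cu_star) <= 30 + 2   # one sweep step + rounding

    def test_unreachable_criterion_raises(self, small_model):
        params = NeuronParams(v_threshold=50.0, noise_sd_a=0.0)
        with pytest.raises(fitting.FittingError):
            fitting.estimate_mcl(8, small_model, params, seeds=(0,))


class TestCalibrateMc:
    def test_default_skips_search(self, tiny_model):
        assert fitting.calibrate_mc(tiny_model) == ex.MC_DEFAULT

    def test_idempotent(self, tiny_model):
        m1 = fitting.calibrate_mc(tiny_model)
        assert fitting.calibrate_mc(tiny_model) == m1

    def test_doubling_mc_roughly_halves_required_current(self):
        itf = cochlea.build_geometry(cochlea.CochleaConfig(n_fibers=301))
        model = ex.ExcitationModel(itf)
        params = NeuronParams()
        m1 = fitting.estimate_mcl(8, model, params, m_c=ex.MC_DEFAULT, seeds=(0, 1))
        m2 = fitting.estimate_mcl(8, model, params, m_c=2 * ex.MC_DEFAULT,
                                  seeds=(0, 1))
        assert m2 < m1
        assert m2 == pytest.approx(m1 / 2, rel=0.5)
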