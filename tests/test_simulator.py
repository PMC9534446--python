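import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dendril as dl
from dendril.morphology import locate
from dendril.simulator import gaba_current_split, gclamp_trace


class TestRestingState:
    def test_unstimulated_tree_stays_at_rest(self, graph4):
        rec = dl.run(graph4, (), (), dl.SimConfig(duration=50.0))
        np.testing.assert_allclose(rec.vm, -65.0, atol=1e-9)

    def test_dynamic_chloride_rest_is_stationary(self, graph1):
        cfg = dl.SimConfig(duration=50.0, chloride_mode="dynamic")
        rec = dl.run(graph1, (), (), cfg)
        np.testing.assert_allclose(rec.vm, -65.0, atol=1e-9)
        np.testing.assert_allclose(rec.cl, 7.25, rtol=1e-12)


class TestGclamp:
    def test_zero_sd_gives_constant_mean(self):
        spec = dl.SynapseSpec(noise_sd_fraction=0.0)
        tr = gclamp_trace(spec, 100.0, 0.025)
        np.testing.assert_array_equal(tr, 0.001)

    def test_stationary_statistics(self):
        spec = dl.SynapseSpec()
        tr = gclamp_trace(spec, 10_000.0, 0.025, np.random.default_rng(7))
        assert tr.mean() == pytest.approx(0.001, rel=0.02)
        assert tr.std() == pytest.approx(0.0001, rel=0.10)

    def test_never_negative(self):
        spec = dl.SynapseSpec(noise_sd_fraction=1.0)
        tr = gclamp_trace(spec, 1000.0, 0.025, np.random.default_rng(3))
        assert tr.min() >= 0.0

    def test_same_seed_identical(self):
        spec = dl.SynapseSpec()
        a = gclamp_trace(spec, 100.0, 0.025, np.random.default_rng(11))
        b = gclamp_trace(spec, 100.0, 0.025, np.random.default_rng(11))
        np.testing.assert_array_equal(a, b)


class TestGabaCurrentSplit:
    def test_table_initial_values(self):
        # χ = (EHCO3 − EGABA)/(EHCO3 − ECl) with Table-1 reversals
        chi = (-17.39 + 70.0) / (-17.39 + 78.13)
        i_cl, i_hco3 = gaba_current_split(0.001, -65.0, -78.13, -17.39, -70.0)
        assert i_cl == pytest.approx(chi * 0.001 * (-65.0 + 78.13))
        assert i_hco3 == pytest.approx((1 - chi) * 0.001 * (-65.0 + 17.39))

    def test_egaba_at_ecl_puts_all_current_in_chloride(self):
        i_cl, i_hco3 = gaba_current_split(0.001, -60.0, -78.0, -17.0, -78.0)
        assert i_hco3 == pytest.approx(0.0, abs=1e-15)
        assert i_cl == pytest.approx(0.001 * (-60.0 + 78.0))

    def test_egaba_at_ehco3_puts_all_current_in_bicarbonate(self):
        i_cl, _ = gaba_current_split(0.001, -60.0, -78.0, -17.0, -17.0)
        assert i_cl == pytest.approx(0.0, abs=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        g=st.floats(0.0, 0.01),
        vm=st.floats(-90.0, 0.0),
        e_gaba=st.floats(-77.9, -17.5),
    )
    def test_components_sum_to_total_current(self, g, vm, e_gaba):
        i_cl, i_hco3 = gaba_current_split(g, vm, -78.0, -17.4, e_gaba)
        assert i_cl + i_hco3 == pytest.approx(g * (vm - e_gaba), abs=1e-12)

    def test_degenerate_reversals_rejected(self):
        with pytest.raises(ValueError):
            gaba_current_split(0.001, -65.0, -17.39, -17.39, -17.39)


class TestRun:
    def test_reproducible_with_identical_seed(self, graph1):
        syn = dl.SynapseSpec(branch=0, x=0.4)
        stim = dl.StimulusSpec(branch=0, x=0.3)
        cfg = dl.SimConfig(duration=50.0, seed=42)
        a = dl.run(graph1, (syn,), (stim,), cfg)
        b = dl.run(graph1, (syn,), (stim,), cfg)
        np.testing.assert_array_equal(a.vm, b.vm)
        np.testing.assert_array_equal(a.g_syn, b.g_syn)

    def test_different_seeds_differ(self, graph1):
        syn = dl.SynapseSpec(branch=0, x=0.4)
        a = dl.run(graph1, (syn,), (), dl.SimConfig(duration=50.0, seed=1))
        b = dl.run(graph1, (syn,), (), dl.SimConfig(duration=50.0, seed=2))
        assert not np.array_equal(a.g_syn, b.g_syn)

    def test_stimulus_onset_and_offset_respected(self, graph1):
        stim = dl.StimulusSpec(branch=0, x=0.5, amplitude=0.01, onset=10.0, offset=20.0)
        rec = dl.run(graph1, (), (stim,), dl.SimConfig(duration=160.0, record_dt=1.0))
        c = locate(graph1, 0, 0.5)
        dv = rec.vm[:, c] - rec.v0[c]
        assert abs(dv[rec.times == 10.0][0]) < 1e-9
        assert dv[rec.times == 20.0][0] > 0.1
        assert dv[-1] < 0.02 * dv[rec.times == 20.0][0] + 1e-9

    def test_shunting_synapse_reduces_probe_deflection(self, graph4):
        stim = dl.StimulusSpec(branch=0, x=0.0)
        cfg = dl.SimConfig(duration=150.0)
        rec0 = dl.run(graph4, (), (stim,), cfg)
        syns = [
            dl.SynapseSpec(branch=b, x=0.2, noise_sd_fraction=0.0) for b in range(4)
        ]
        rec1 = dl.run(graph4, syns, (stim,), cfg)
        assert rec1.vm[-1, 0] < rec0.vm[-1, 0]
        assert rec1.vm[-1, 0] > -65.0  # shunting never hyperpolarises below rest

    def test_hyperpolarising_synapse_dips_below_rest(self, graph1):
        syn = dl.SynapseSpec(branch=0, x=0.4, delta_egaba=-5.0, noise_sd_fraction=0.0)
        rec = dl.run(graph1, (syn,), (), dl.SimConfig(duration=150.0))
        assert rec.vm[-1, locate(graph1, 0, 0.4)] < -65.0

    def test_dynamic_run_records_ion_state(self, graph1):
        syn = dl.SynapseSpec(branch=0, x=0.2, reversal_mode="dynamic")
        cfg = dl.SimConfig(duration=50.0, chloride_mode="dynamic", seed=1)
        rec = dl.run(graph1, (syn,), (), cfg)
        assert rec.cl is not None and rec.egaba_profile is not None
        c = rec.syn_comp[0]
        assert rec.cl[-1, c] > rec.cl[0, c]  # chloride loading at the synapse
        assert rec.egaba_at(c, 50.0) > rec.egaba_at(c, 0.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            dl.SimConfig(dt=-0.1)
        with pytest.raises(ValueError):
            dl.StimulusSpec(onset=5.0, offset=1.0)
        with pytest.raises(ValueError):
            dl.SynapseSpec(g_mean=-1.0)
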