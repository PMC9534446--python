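import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dendril as dl
from dendril.chloride import (
    IonState,
    chloride_step,
    cl_from_egaba,
    egaba,
    kcc2_rate,
    nernst,
)


class TestReversalPotentials:
    def test_chloride_nernst_matches_initial_value(self):
        # Table-1 pools: 7.25 / 135 mM at 37 °C
        assert nernst(7.25, 135.0) == pytest.approx(-78.13, abs=0.1)

    def test_bicarbonate_nernst(self):
        assert nernst(12.0, 23.0) == pytest.approx(-17.39, abs=0.05)

    def test_equal_concentrations_give_zero(self):
        assert nernst(10.0, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_initial_egaba_is_minus_70(self):
        assert egaba(7.25) == pytest.approx(-70.0, abs=0.1)

    def test_pure_chloride_limit(self):
        assert egaba(7.25, p_cl=1.0) == pytest.approx(nernst(7.25, 135.0))

    def test_pure_bicarbonate_limit(self):
        assert egaba(7.25, p_cl=0.0) == pytest.approx(nernst(12.0, 23.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nernst(-1.0, 135.0)
        with pytest.raises(ValueError):
            egaba(7.25, p_cl=1.5)

    def test_cl_from_egaba_inverts_ghk(self):
        for target in (-70.0, -65.0, -72.5):
            assert egaba(cl_from_egaba(target)) == pytest.approx(target, abs=1e-9)

    def test_initial_state_has_minus_5_driving_force(self, graph1):
        ion = IonState.for_graph(graph1)
        assert float(ion.e_gaba[0]) - (-65.0) == pytest.approx(-5.0, abs=0.05)


class TestKCC2:
    def test_zero_at_resting_equilibrium(self, graph1):
        ion = IonState.for_graph(graph1)
        np.testing.assert_allclose(kcc2_rate(ion, graph1), 0.0, atol=1e-15)

    def test_extrudes_above_equilibrium(self, graph1):
        ion = IonState.for_graph(graph1)
        ion.cl_i[:] = 8.0
        assert np.all(kcc2_rate(ion, graph1) < 0)

    def test_loads_below_equilibrium(self, graph1):
        ion = IonState.for_graph(graph1)
        ion.cl_i[:] = 6.0
        assert np.all(kcc2_rate(ion, graph1) > 0)

    def test_rate_scales_with_surface_to_volume(self):
        thin = dl.discretise(dl.build_star_tree(1, dl.BranchSpec(radius=0.5)), 0.05)
        thick = dl.discretise(dl.build_star_tree(1, dl.BranchSpec(radius=1.0)), 0.05)
        ion_thin = IonState.for_graph(thin, cl_init=8.0)
        ion_thick = IonState.for_graph(thick, cl_init=8.0)
        r_thin = kcc2_rate(ion_thin, thin)[1]
        r_thick = kcc2_rate(ion_thick, thick)[1]
        assert r_thin == pytest.approx(2 * r_thick, rel=1e-9)


class TestChlorideStep:
    def test_equilibrium_is_a_fixed_point(self, graph1):
        ion = IonState.for_graph(graph1)
        before = ion.cl_i.copy()
        for _ in range(100):
            chloride_step(ion, np.zeros(graph1.n_comp), graph1, 0.025)
        np.testing.assert_allclose(ion.cl_i, before, rtol=1e-12)

    def test_pure_diffusion_conserves_total_chloride(self, graph4, rng):
        ion = IonState.for_graph(graph4)
        ion.cl_i = ion.cl_i + rng.uniform(0.0, 5.0, graph4.n_comp)
        total0 = float(np.sum(ion.cl_i * graph4.volume))
        for _ in range(1000):
            chloride_step(
                ion, np.zeros(graph4.n_comp), graph4, 0.025, pump=False
            )
        total1 = float(np.sum(ion.cl_i * graph4.volume))
        assert abs(total1 - total0) / total0 <= 1e-10

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_diffusion_never_creates_extrema(self, graph1, seed):
        r = np.random.default_rng(seed)
        ion = IonState.for_graph(graph1)
        ion.cl_i = 5.0 + r.uniform(0.0, 10.0, graph1.n_comp)
        lo, hi = ion.cl_i.min(), ion.cl_i.max()
        for _ in range(20):
            chloride_step(ion, np.zeros(graph1.n_comp), graph1, 0.025, pump=False)
            assert ion.cl_i.min() >= lo - 1e-12
            assert ion.cl_i.max() <= hi + 1e-12
            lo, hi = ion.cl_i.min(), ion.cl_i.max()

    def test_constant_influx_without_sinks_grows_monotonically(self, graph1):
        ion = IonState.for_graph(graph1)
        influx = np.zeros(graph1.n_comp)
        influx[50] = 0.01  # nA of outward GABA_A Cl⁻ current
        prev_cl = ion.cl_i[50]
        prev_eg = float(ion.e_gaba[50])
        for _ in range(200):
            chloride_step(ion, influx, graph1, 0.025, pump=False, diffusion=False)
            assert ion.cl_i[50] > prev_cl
            eg = float(ion.e_gaba[50])
            assert eg >= prev_eg
            prev_cl, prev_eg = ion.cl_i[50], eg

    def test_influx_sign_convention(self, graph1):
        # outward-positive current (Vm > ECl) must raise [Cl⁻]i
        ion = IonState.for_graph(graph1)
        influx = np.zeros(graph1.n_comp)
        influx[10] = 0.005
        chloride_step(ion, influx, graph1, 0.025, pump=False, diffusion=False)
        assert ion.cl_i[10] > 7.25

    def test_bad_dt_rejected(self, graph1):
        ion = IonState.for_graph(graph1)
        with pytest.raises(ValueError):
            chloride_step(ion, np.zeros(graph1.n_comp), graph1, 0.0)


class TestIonStateConstruction:
    def test_egaba_init_resolves_concentration(self, graph1):
        ion = IonState.for_graph(graph1, egaba_init=-70.0)
        assert ion.cl_i[0] == pytest.approx(7.25, abs=0.01)

    def test_default_k_out_balances_pump(self, graph1):
        ion = IonState.for_graph(graph1)
        assert ion.k_i * ion.cl_i[0] == pytest.approx(ion.k_o * ion.cl_o, rel=1e-12)

    def test_mutually_exclusive_initialisers(self, graph1):
        with pytest.raises(ValueError):
            IonState.for_graph(graph1, cl_init=7.0, egaba_init=-70.0)
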