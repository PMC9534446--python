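import math

import numpy as np
import pytest

import dendril as dl
from dendril.morphology import (
    BranchSpec,
    SWCError,
    build_star_tree,
    discretise,
    from_swc,
    locate,
    to_swc,
)


class TestBranchSpec:
    def test_default_branch_is_one_space_constant(self):
        spec = BranchSpec()
        assert spec.resolved_length == pytest.approx(707.0, abs=1.0)
        assert spec.electrotonic_length == pytest.approx(1.0, abs=1e-3)

    def test_membrane_time_constant_is_20_ms(self):
        assert BranchSpec().tau_m == pytest.approx(20.0)

    @pytest.mark.parametrize("field", ["radius", "rm", "ra", "cm", "length"])
    def test_non_positive_values_rejected(self, field):
        with pytest.raises(ValueError):
            BranchSpec(**{field: -1.0})


class TestBuildStarTree:
    def test_default_four_branch_tree(self):
        m = build_star_tree(4)
        assert m.n_branches == 4
        assert m.junction_length == pytest.approx(0.01)
        assert all(b.resolved_length == pytest.approx(707.1, abs=0.1) for b in m.branches)

    def test_single_branch_is_valid(self):
        assert build_star_tree(1).n_branches == 1

    def test_sink_is_an_extra_flagged_branch(self):
        sink = BranchSpec(radius=1.0, length=707.0)
        m = build_star_tree(4, sink=sink)
        assert len(m.all_branches) == 5
        g = discretise(m, 0.05)
        assert g.sink_branch == 4
        assert g.n_branches == 5

    def test_zero_branches_rejected(self):
        with pytest.raises(ValueError):
            build_star_tree(0)


class TestDiscretise:
    def test_default_grid_has_100_compartments_per_branch(self, graph4):
        assert np.all(graph4.branch_nseg == 100)
        seg_lengths = graph4.length[graph4.branch_id == 0]
        assert seg_lengths == pytest.approx(7.071, abs=0.01)

    def test_branch_membrane_area_is_cylinder_area(self, graph1):
        spec = BranchSpec()
        expected = 2 * math.pi * (spec.radius * 1e-4) * (spec.resolved_length * 1e-4)
        assert graph1.area[1:].sum() == pytest.approx(expected, rel=1e-12)

    def test_refinement_conserves_area_and_volume(self):
        m = build_star_tree(4, sink=BranchSpec(radius=1.0))
        coarse = discretise(m, 0.02)
        fine = discretise(m, 0.01)
        assert fine.n_comp == 2 * (coarse.n_comp - 1) + 1
        assert fine.total_area() == pytest.approx(coarse.total_area(), rel=1e-12)
        assert fine.total_volume() == pytest.approx(coarse.total_volume(), rel=1e-12)

    def test_compartment_lengths_sum_to_branch_length(self, graph4):
        for b in range(4):
            total = graph4.length[graph4.branch_id == b].sum()
            assert total == pytest.approx(BranchSpec().resolved_length, rel=1e-12)

    def test_graph_is_a_tree(self, graph4):
        # |edges| = |compartments| - 1, single root, all reachable
        assert np.sum(graph4.parent == -1) == 1
        assert np.all(graph4.parent[1:] < np.arange(1, graph4.n_comp))
        assert np.all(graph4.g_axial[1:] > 0)

    def test_leak_conductance_matches_area_over_rm(self, graph1):
        spec = BranchSpec()
        expected = graph1.area / spec.rm * 1e3
        np.testing.assert_allclose(graph1.g_leak, expected)

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            discretise(build_star_tree(1), 0.0)
        with pytest.raises(ValueError):
            discretise(build_star_tree(1), 1.5)


class TestLocate:
    def test_x_zero_maps_to_junction(self, graph4):
        for b in range(4):
            assert locate(graph4, b, 0.0) == 0

    def test_uniform_grid_arithmetic(self, graph4):
        # X = 0.2 on a 100-compartment branch is the 20th from the junction
        assert locate(graph4, 0, 0.2) == graph4.branch_first[0] + 19
        assert graph4.x[locate(graph4, 0, 0.2)] == pytest.approx(0.195)

    def test_x_one_is_the_sealed_tip(self, graph4):
        tip = locate(graph4, 1, 1.0)
        assert tip == graph4.branch_first[1] + 99
        assert graph4.parent[tip] == tip - 1

    def test_out_of_range_rejected(self, graph4):
        with pytest.raises(ValueError):
            locate(graph4, 0, 1.5)
        with pytest.raises(ValueError):
            locate(graph4, 7, 0.1)


class TestSWC:
    def test_round_trip_preserves_geometry(self):
        m = build_star_tree(4, sink=BranchSpec(radius=1.0, length=500.0))
        m2 = from_swc(to_swc(m))
        assert m2.n_branches == 4
        assert m2.sink is not None
        assert m2.sink.radius == pytest.approx(1.0)
        assert m2.sink.length == pytest.approx(500.0, abs=1e-3)
        for b in m2.branches:
            assert b.radius == pytest.approx(0.5)
            assert b.length == pytest.approx(707.107, abs=1e-2)

    def test_document_shape(self):
        doc = to_swc(build_star_tree(4), samples_per_branch=3)
        rows = [l for l in doc.splitlines() if l and not l.startswith("#")]
        assert len(rows) == 1 + 4 * 3
        root = rows[0].split()
        assert root[6] == "-1"

    def test_cycle_raises(self):
        doc = "1 1 0 0 0 1 2\n2 3 5 0 0 1 1\n"
        with pytest.raises(SWCError):
            from_swc(doc)

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(SWCError, match="line 2"):
            from_swc("1 1 0 0 0 1 -1\n2 3 bad 0 0 1 1\n")

    def test_branching_chain_rejected(self):
        doc = (
            "1 1 0 0 0 1 -1\n"
            "2 3 10 0 0 1 1\n"
            "3 3 20 0 0 1 2\n"
            "4 3 20 5 0 1 2\n"
        )
        with pytest.raises(SWCError, match="non-star"):
            from_swc(doc)
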