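"""Reduced-order solver: loss coefficients, network solve, FFR field."""
import numpy as np
import pytest

from conftest import linear_network_oracle, random_tree
from ctffr.errors import SolverError, StructureError
from ctffr.geometry import Lesion, VesselTree, apply_lesions, apply_stenosis, make_segment
from ctffr.hemodynamics import (
    PA_PER_MMHG,
    BloodModel,
    BoundaryParams,
    assign_outlet_resistances,
    ct_ffr,
    ffr_field,
    measure_ffr,
    poiseuille_coefficient,
    solve_steady_flow,
    turbulent_coefficient,
)


class TestPoiseuille:
    def test_uniform_tube_matches_closed_form(self, blood):
        seg = make_segment(10.0, 3.0, 3.0, 5)
        closed = 128 * blood.dynamic_viscosity * 0.010 / (np.pi * 0.003**4)
        closed *= 1e-6 / PA_PER_MMHG
        assert poiseuille_coefficient(seg, blood) == pytest.approx(closed, rel=1e-12)

    def test_r4_scaling(self, blood):
        a1 = poiseuille_coefficient(make_segment(10, 3.0, 3.0, 9), blood)
        a2 = poiseuille_coefficient(make_segment(10, 1.5, 1.5, 9), blood)
        assert a2 / a1 == pytest.approx(16.0, rel=1e-12)

    def test_linear_in_length(self, blood):
        a1 = poiseuille_coefficient(make_segment(10, 3.0, 3.0, 11), blood)
        a2 = poiseuille_coefficient(make_segment(20, 3.0, 3.0, 21), blood)
        assert a2 / a1 == pytest.approx(2.0, rel=1e-12)


class TestTurbulentCoefficient:
    def test_zero_for_unnarrowed_lumen(self, blood):
        seg = make_segment(30.0, 3.0, 3.0)
        assert turbulent_coefficient(seg, Lesion("segment", 5, 20, 0.0), blood, 1.0) == 0.0

    def test_monotone_in_degree(self, blood):
        vals = []
        for deg in (10.0, 30.0, 50.0, 70.0, 90.0):
            lesion = Lesion("segment", 5, 20, deg)
            seg = apply_stenosis(make_segment(30.0, 3.0, 3.0), lesion)
            vals.append(turbulent_coefficient(seg, lesion, blood, 1.0))
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_matches_hand_formula(self, blood):
        # d_ref = 3 mm, 50% stenosis, K_t = 1, rho = 1060: direct evaluation
        lesion = Lesion("segment", 5, 20, 50.0)
        seg = apply_stenosis(make_segment(30.0, 3.0, 3.0), lesion, "rectangular")
        a_throat = np.pi * (0.75e-3) ** 2
        a_ref = np.pi * (1.5e-3) ** 2
        expected = 0.5 * 1060.0 * (1 / a_throat - 1 / a_ref) ** 2 * 1e-12 / PA_PER_MMHG
        assert turbulent_coefficient(seg, lesion, blood, 1.0) == pytest.approx(
            expected, rel=1e-12
        )


class TestOutletResistances:
    def test_equal_diameters_equal_resistances(self, params, bifurcation_tree):
        res = assign_outlet_resistances(bifurcation_tree, params)
        assert res["l"] == res["r"]

    def test_k_zero_ignores_diameter(self, params):
        t = make_segment(20, 3.4, 3.0, segment_id="t", is_outlet=False)
        a = make_segment(25, 3.0, 2.8, segment_id="a", parent_id="t")
        b = make_segment(25, 2.0, 1.4, segment_id="b", parent_id="t")
        tree = VesselTree.from_segments([t, a, b], "LAD")
        res = assign_outlet_resistances(tree, params.with_values(diameter_exponent=0.0))
        expected = params.outlet_resistance_scale / params.hyperemia_factor
        assert res["a"] == res["b"] == pytest.approx(expected)

    def test_power_law_ratio(self, params):
        # outlet at twice the reference diameter, k = 2.7
        t = make_segment(20, 6.5, 6.2, segment_id="t", is_outlet=False)
        a = make_segment(25, 3.1, 3.0, segment_id="a", parent_id="t")
        b = make_segment(25, 6.2, 6.0, segment_id="b", parent_id="t")
        tree = VesselTree.from_segments([t, a, b], "LAD")
        res = assign_outlet_resistances(tree, params)
        assert res["b"] / res["a"] == pytest.approx(2.0 ** (-2.7), rel=1e-12)


class TestSolver:
    def test_single_tube_matches_two_resistor_analytic(self, tube_tree, params, blood):
        a = poiseuille_coefficient(tube_tree.segments["s0"], blood)
        r_out = assign_outlet_resistances(tube_tree, params)["s0"]
        sol = solve_steady_flow(tube_tree, params, blood)
        q_expected = params.aortic_pressure / (a + r_out)
        assert sol.segment_flows["s0"] == pytest.approx(q_expected, rel=1e-8)
        assert sol.junction_pressures["s0"] == pytest.approx(
            params.aortic_pressure * r_out / (a + r_out), rel=1e-8
        )

    def test_lossless_limit_flat_pressure(self, tube_tree, params):
        thin = BloodModel(density=1060.0, dynamic_viscosity=1e-10)
        sol = solve_steady_flow(tube_tree, params.with_values(turbulent_loss_coefficient=0.0), thin)
        assert sol.junction_pressures["s0"] == pytest.approx(params.aortic_pressure, rel=1e-6)

    def test_symmetric_bifurcation_splits_evenly(self, bifurcation_tree, params, blood):
        sol = solve_steady_flow(bifurcation_tree, params, blood)
        assert sol.segment_flows["l"] == pytest.approx(sol.segment_flows["r"], rel=1e-14)

    def test_mass_conservation_at_junctions(self, stenosed_vessel, params, blood):
        tree, _ = stenosed_vessel
        sol = solve_steady_flow(tree, params, blood)
        q_in = sol.segment_flows["prox"]
        q_out = sol.segment_flows["dist"] + sol.segment_flows["side"]
        assert abs(q_in - q_out) <= 1e-9 * q_in

    def test_matches_linear_network_oracle_on_random_trees(self, params, blood):
        rng = np.random.default_rng(42)
        lin = params.with_values(turbulent_loss_coefficient=0.0)
        for _ in range(25):
            tree = random_tree(rng, max_segments=50)
            sol = solve_steady_flow(tree, lin, blood)
            p_oracle, q_oracle = linear_network_oracle(tree, lin, blood)
            for sid in tree.segments:
                assert sol.junction_pressures[sid] == pytest.approx(
                    p_oracle[sid], rel=1e-8
                )
                assert sol.segment_flows[sid] == pytest.approx(q_oracle[sid], rel=1e-8)

    def test_result_independent_of_segment_enumeration(self, params, blood):
        rng = np.random.default_rng(7)
        tree = random_tree(rng, max_segments=20)
        sol = solve_steady_flow(tree, params, blood)
        items = list(tree.segments.items())
        perm = np.random.default_rng(1).permutation(len(items))
        shuffled = VesselTree({items[i][0]: items[i][1] for i in perm},
                              tree.root_id, tree.vessel_label)
        sol2 = solve_steady_flow(shuffled, params, blood)
        for sid in tree.segments:
            assert abs(sol.junction_pressures[sid] - sol2.junction_pressures[sid]) < 1e-10

    def test_no_outlet_is_structure_error(self, params, blood):
        seg = make_segment(10, 3, 3, segment_id="s", is_outlet=True)
        tree = VesselTree.from_segments([seg], "LAD")
        tree.segments["s"].is_outlet = False  # force a degenerate network
        with pytest.raises(StructureError):
            from ctffr.hemodynamics import compile_network
            compile_network(tree, blood)


class TestFFR:
    def test_ostium_is_unity_and_bounded(self, stenosed_vessel, params, blood):
        tree, _ = stenosed_vessel
        field = ffr_field(solve_steady_flow(tree, params, blood))
        assert field["ostium"] == 1.0
        vals = np.array(list(field.values()))
        assert np.all(vals > 0) and np.all(vals <= 1.0)

    def test_non_increasing_downstream(self, stenosed_vessel, params, blood):
        tree, _ = stenosed_vessel
        sol = solve_steady_flow(tree, params, blood)
        for sid, seg in tree.segments.items():
            prof = sol.sample_pressures[sid]
            assert np.all(np.diff(prof) <= 1e-12)
            upstream = (
                params.aortic_pressure if seg.parent_id is None
                else sol.junction_pressures[seg.parent_id]
            )
            assert prof[0] <= upstream + 1e-12

    def test_analytic_tube_distal_ffr(self, tube_tree, params, blood):
        a = poiseuille_coefficient(tube_tree.segments["s0"], blood)
        r_out = assign_outlet_resistances(tube_tree, params)["s0"]
        sol = solve_steady_flow(tube_tree, params, blood)
        assert sol.ffr_at("s0", 10.0) == pytest.approx(r_out / (a + r_out), rel=1e-8)

    def test_strictly_decreasing_in_degree(self, params, blood):
        trunk = make_segment(40.0, 3.2, 2.95, segment_id="prox", is_outlet=False)
        dist = make_segment(35.0, 2.8, 2.2, segment_id="dist", parent_id="prox")
        side = make_segment(25.0, 2.2, 1.9, segment_id="side", parent_id="prox")
        base = VesselTree.from_segments([trunk, dist, side], "LAD")
        values = []
        for deg in (30.0, 45.0, 60.0, 75.0, 88.0):
            lesion = Lesion("prox", 10.0, 18.0, deg)
            values.append(ct_ffr(apply_lesions(base, [lesion]), lesion, params, blood))
        assert all(v2 < v1 for v1, v2 in zip(values, values[1:]))

    def test_refuses_unconverged_solution(self, stenosed_vessel, params, blood):
        tree, _ = stenosed_vessel
        sol = solve_steady_flow(tree, params, blood)
        sol.converged = False
        with pytest.raises(SolverError):
            ffr_field(sol)


class TestMeasureFFR:
    def test_probe_beyond_vessel_end_clips(self, stenosed_vessel, params, blood):
        tree, lesion = stenosed_vessel
        sol = solve_steady_flow(tree, params, blood)
        m = measure_ffr(tree, sol, lesion, offset=500.0)
        assert m.clipped
        assert m.value == pytest.approx(sol.ffr_at(m.segment_id, m.arc_location))

    def test_lossless_limit_is_unity(self, stenosed_vessel, params):
        tree, lesion = stenosed_vessel
        thin = BloodModel(density=1060.0, dynamic_viscosity=1e-10)
        sol = solve_steady_flow(
            tree, params.with_values(turbulent_loss_coefficient=0.0), thin
        )
        m = measure_ffr(tree, sol, lesion, offset=25.0)
        assert m.value == pytest.approx(1.0, abs=1e-6)

    def test_interpolates_between_bracketing_samples(self, params, blood):
        # coarse tube so the probe falls strictly between two samples
        seg = make_segment(40.0, 3.0, 3.0, 5, segment_id="s0")
        tree = VesselTree.from_segments([seg], "LAD")
        lesion = Lesion("s0", 0.0, 5.0, 0.0)
        sol = solve_steady_flow(tree, params, blood)
        m = measure_ffr(tree, sol, lesion, offset=10.0)  # probe at arc 15 mm
        prof = sol.sample_pressures["s0"] / params.aortic_pressure
        lo, hi = prof[1], prof[2]  # samples at 10 and 20 mm
        expected = lo + (hi - lo) * 0.5
        assert m.value == pytest.approx(expected, rel=1e-12)

    def test_offset_default_mirrors_distal_measurement(self, stenosed_vessel, params, blood):
        tree, lesion = stenosed_vessel
        sol = solve_steady_flow(tree, params, blood)
        m = measure_ffr(tree, sol, lesion)
        # lesion ends at 28 mm on a 40 mm trunk: probe continues 13 mm into
        # the main (largest-calibre) child
        assert m.segment_id == "dist"
        assert m.arc_location == pytest.approx(13.0)
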