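"""Reduced-order network solver: both boundary modes against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffrtree import (
    FluidProps,
    SegmentLossLaw,
    StenosisSpec,
    build_loss_laws,
    solve_given_outlet_flows,
    solve_given_outlet_pressures,
)
from ffrtree.synthetic import TreeGenSpec, generate_tree

from conftest import (
    make_y_tree,
    oracle_linear_network,
    oracle_path_drop,
    three_outlet_tree,
)


class TestLossLaws:
    def test_poiseuille_resistance_value(self, fluid):
        tree = make_y_tree(r_root=2e-3, length_factor=25.0)  # root length 0.05 m
        laws = build_loss_laws(tree, fluid)
        # 8 μ l / (π r⁴) = 8·0.0035·0.05 / (π·(2e-3)⁴), frozen by hand
        assert laws["root"].viscous_resistance == pytest.approx(2.7852115e7, rel=1e-7)

    def test_no_stenosis_means_no_quadratic_loss(self, fluid):
        laws = build_loss_laws(make_y_tree(), fluid)
        assert all(l.turbulent_coeff == 0.0 for l in laws.values())

    def test_stenosis_loss_vanishes_continuously(self, fluid):
        coeffs = []
        for ratio in (0.5, 0.9, 0.999):
            tree = make_y_tree(stenosis_left=StenosisSpec(area_ratio=ratio))
            coeffs.append(build_loss_laws(tree, fluid)["a"].turbulent_coeff)
        assert coeffs[0] > coeffs[1] > coeffs[2]
        assert coeffs[2] < 1e-4 * coeffs[0]

    def test_loss_law_strictly_increasing(self):
        law = SegmentLossLaw(viscous_resistance=1e9, turbulent_coeff=1e14)
        qs = np.linspace(-1e-5, 1e-5, 101)
        dps = [law.dp(q) for q in qs]
        assert np.all(np.diff(dps) > 0)


class TestOutletFlowMode:
    def test_symmetric_tree_equal_pressures(self, fluid, y_tree):
        laws = build_loss_laws(y_tree, fluid)
        st_ = solve_given_outlet_flows(y_tree, laws, 1e4, [3e-6, 3e-6])
        assert st_.outlet_pressures[0] == pytest.approx(st_.outlet_pressures[1], rel=1e-14)

    def test_zero_flow_uniform_pressure(self, fluid, y_tree):
        laws = build_loss_laws(y_tree, fluid)
        st_ = solve_given_outlet_flows(y_tree, laws, 1e4, [0.0, 0.0])
        assert np.all(st_.outlet_pressures == 1e4)
        assert st_.inlet_flow == 0.0

    def test_path_sum_oracle(self, fluid):
        """Outlet pressures equal inlet minus an independent per-path summation."""
        tree = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.5))
        laws = build_loss_laws(tree, fluid)
        q = np.array([2e-6, 1e-6, 3e-6])
        st_ = solve_given_outlet_flows(tree, laws, 1.2e4, q)
        for i, o in enumerate(tree.outlets):
            expected = 1.2e4 - oracle_path_drop(tree, fluid, o, q)
            assert st_.outlet_pressures[i] == pytest.approx(expected, rel=1e-12)

    def test_pressure_decreases_along_paths(self, fluid):
        tree = three_outlet_tree()
        laws = build_loss_laws(tree, fluid)
        st_ = solve_given_outlet_flows(tree, laws, 1.2e4, [2e-6, 1e-6, 3e-6])
        for o in tree.outlets:
            path = tree.path_from_root(o.segment_id)
            ps = [1.2e4] + [st_.nodal_pressures[sid] for sid in path]
            assert np.all(np.diff(ps) < 0)

    def test_monotonic_response_to_flow_increase(self, fluid):
        tree = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.6))
        laws = build_loss_laws(tree, fluid)
        base = solve_given_outlet_flows(tree, laws, 1.2e4, [2e-6, 1e-6, 3e-6])
        more = solve_given_outlet_flows(tree, laws, 1.2e4, [2.5e-6, 1e-6, 3e-6])
        assert more.outlet_pressures[0] < base.outlet_pressures[0]

    def test_stenosis_lowers_distal_pressure(self, fluid):
        q = [2e-6, 1e-6, 3e-6]
        open_t = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.8))
        tight_t = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.4))
        p_open = solve_given_outlet_flows(
            open_t, build_loss_laws(open_t, fluid), 1.2e4, q
        ).outlet_pressures
        p_tight = solve_given_outlet_flows(
            tight_t, build_loss_laws(tight_t, fluid), 1.2e4, q
        ).outlet_pressures
        # outlets 1 and 2 sit below the stenosed branch
        assert p_tight[0] < p_open[0] and p_tight[1] < p_open[1]


class TestOutletPressureMode:
    def test_linear_agrees_with_sparse_network_solve(self, fluid):
        tree = three_outlet_tree()  # no stenosis → purely linear
        laws = build_loss_laws(tree, fluid)
        p_out = np.array([1.19e4, 1.18e4, 1.195e4])
        q_in = 6e-6
        st_ = solve_given_outlet_pressures(tree, laws, q_in, p_out)
        p_in_ref, q_ref = oracle_linear_network(tree, fluid, q_in, p_out)
        assert st_.inlet_pressure == pytest.approx(p_in_ref, rel=1e-10)
        np.testing.assert_allclose(st_.outlet_flows, q_ref, rtol=1e-10)

    def test_symmetric_tree_splits_flow_evenly(self, fluid, y_tree):
        laws = build_loss_laws(y_tree, fluid)
        st_ = solve_given_outlet_pressures(y_tree, laws, 6e-6, [1.19e4, 1.19e4])
        np.testing.assert_allclose(st_.outlet_flows, [3e-6, 3e-6], rtol=1e-10)

    def test_round_trip_self_consistency(self, fluid):
        """Mode A's outputs fed to mode B reproduce the same state."""
        tree = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.5))
        laws = build_loss_laws(tree, fluid)
        q = np.array([2e-6, 1e-6, 3e-6])
        a = solve_given_outlet_flows(tree, laws, 1.2e4, q)
        b = solve_given_outlet_pressures(tree, laws, a.inlet_flow, a.outlet_pressures)
        np.testing.assert_allclose(b.outlet_flows, a.outlet_flows, rtol=1e-8)
        assert b.inlet_pressure == pytest.approx(1.2e4, rel=1e-8)

    def test_newton_residuals_tiny(self, fluid):
        tree = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.3))
        laws = build_loss_laws(tree, fluid)
        p_out = np.array([1.15e4, 1.1e4, 1.19e4])
        st_ = solve_given_outlet_pressures(tree, laws, 6e-6, p_out)
        # every path equation satisfied to 1e-10 relative
        for i, o in enumerate(tree.outlets):
            drop = oracle_path_drop(tree, fluid, o, st_.outlet_flows)
            assert abs(st_.inlet_pressure - drop - p_out[i]) <= 1e-10 * 1.2e4
        assert abs(st_.outlet_flows.sum() - 6e-6) <= 1e-10 * 6e-6


class TestConservationProperty:
    @given(
        seed=st.integers(0, 2**16),
        depth=st.integers(2, 4),
        asym=st.floats(0, 0.8),
        sten=st.floats(0, 0.7),
    )
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_mass_balance_on_random_trees(self, seed, depth, asym, sten):
        tree = generate_tree(
            TreeGenSpec(depth=depth, asymmetry=asym, stenosis_prob=sten, seed=seed)
        )
        fluid = FluidProps()
        laws = build_loss_laws(tree, fluid)
        rng = np.random.default_rng(seed + 1)
        q = rng.uniform(0.5e-6, 4e-6, tree.n_outlets)
        a = solve_given_outlet_flows(tree, laws, 1.2e4, q)
        assert a.conservation_error(tree) <= 1e-10
        b = solve_given_outlet_pressures(tree, laws, a.inlet_flow, a.outlet_pressures)
        assert b.conservation_error(tree) <= 1e-10
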