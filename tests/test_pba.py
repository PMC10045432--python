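"""Alternating boundary-condition iteration: convergence, FFR, fixed point."""

import numpy as np
import pytest

from ffrtree import (
    MeasuredInlet,
    PBAConfig,
    StenosisSpec,
    compute_ffr,
    make_fixture,
    relative_error,
    run_steady,
)
from ffrtree.pba import BoundaryMode
from ffrtree.synthetic import TreeGenSpec, generate_tree

from conftest import three_outlet_tree


class TestComputeFFR:
    def test_minimum_over_outlets(self):
        ffr, outlet = compute_ffr([90.0, 80.0, 70.0], 100.0)
        assert ffr == pytest.approx(0.70)
        assert outlet == 3

    def test_no_drop_gives_unity(self):
        ffr, _ = compute_ffr([100.0, 100.0], 100.0)
        assert ffr == 1.0

    def test_unit_invariance(self):
        mm = compute_ffr([90.0, 80.0], 100.0)
        pa = compute_ffr([90.0 * 133.322, 80.0 * 133.322], 100.0 * 133.322)
        assert mm[0] == pytest.approx(pa[0], rel=1e-14)

    def test_uniform_rescale_invariance(self):
        p = np.array([1.1e4, 1.05e4, 1.15e4])
        f1, _ = compute_ffr(p, 1.2e4)
        f2, _ = compute_ffr(10 * p, 10 * 1.2e4)
        assert f1 == pytest.approx(f2, rel=1e-14)

    def test_tie_reports_lowest_index(self):
        _, outlet = compute_ffr([70.0, 70.0, 90.0], 100.0)
        assert outlet == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_ffr([], 100.0)


@pytest.mark.parametrize(
    "calc,invasive,expected",
    [(0.762, 0.76, 0.26), (0.683, 0.68, 0.44), (0.80, 0.76, 5.26), (0.5, 0.5, 0.0)],
)
def test_relative_error_clinical_pairs(calc, invasive, expected):
    assert relative_error(calc, invasive) == pytest.approx(expected, abs=5e-3)


class TestSteadyIteration:
    def test_linear_network_converges_at_round_two(self, fluid):
        """With S=0 the round-1 state is a fixed point: round 2 reproduces it."""
        tree = three_outlet_tree()
        measured = MeasuredInlet(pressure=1.2e4, flow=6e-6)
        res = run_steady(tree, fluid, measured)
        assert res.converged and not res.diverged
        assert res.n_rounds == 2
        r1, r2 = res.iterations[0][2], res.iterations[1][2]
        np.testing.assert_allclose(r2.outlet_flows, r1.outlet_flows, rtol=1e-8)
        np.testing.assert_allclose(r2.outlet_pressures, r1.outlet_pressures, rtol=1e-8)
        assert res.residuals[0].pressure_residual < 1e-6
        assert res.residuals[0].flow_residual < 1e-6

    def test_rounds_alternate_modes(self, fluid):
        tree = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.5))
        measured = MeasuredInlet(pressure=1.2e4, flow=6e-6)
        res = run_steady(
            tree, fluid, measured, PBAConfig(tolerance_pct=0.0, max_rounds=5)
        )
        modes = [b.mode for _, b, _ in res.iterations]
        for i, m in enumerate(modes, start=1):
            expect = (
                BoundaryMode.INLET_PRESSURE_OUTLET_FLOWS
                if i % 2 == 1
                else BoundaryMode.INLET_FLOW_OUTLET_PRESSURES
            )
            assert m is expect
        # odd rounds prescribe P_exp, even rounds Q_exp
        assert res.iterations[0][1].prescribed_inlet == 1.2e4
        assert res.iterations[1][1].prescribed_inlet == 6e-6

    def test_vanishing_losses_give_unit_ffr(self, fluid):
        tree = generate_tree(TreeGenSpec(depth=2, root_radius_cm=0.5, length_factor=0.01))
        measured = MeasuredInlet(pressure=1.2e4, flow=1e-7)
        res = run_steady(tree, fluid, measured)
        assert res.ffr == pytest.approx(1.0, abs=1e-6)

    def test_fixture_conserves_inlet_flow_every_round(self, fluid):
        tree, measured = make_fixture("CT209")
        res = run_steady(tree, fluid, measured)
        for _, _, state in res.iterations:
            assert state.outlet_flows.sum() == pytest.approx(
                measured.flow, rel=1e-8
            )

    def test_stenosis_lowers_ffr(self, fluid):
        measured = MeasuredInlet(pressure=1.2e4, flow=6e-6)
        healthy = three_outlet_tree()
        mild = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.6))
        tight = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.3))
        ffrs = [run_steady(t, fluid, measured).ffr for t in (healthy, mild, tight)]
        assert ffrs[0] > ffrs[1] > ffrs[2]

    def test_fixed_point_satisfies_both_inlet_measurements(self, fluid):
        """The converged state carries P_exp and Q_exp simultaneously."""
        tree = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.4))
        measured = MeasuredInlet(pressure=1.2e4, flow=6e-6)
        res = run_steady(tree, fluid, measured)
        assert res.converged
        # last flow-prescribing round recovered P_exp as a solved quantity
        flow_rounds = [
            s for _, b, s in res.iterations
            if b.mode is BoundaryMode.INLET_FLOW_OUTLET_PRESSURES
        ]
        assert flow_rounds[-1].inlet_pressure == pytest.approx(1.2e4, rel=1e-6)
        assert flow_rounds[-1].inlet_flow == pytest.approx(6e-6, rel=1e-10)

    def test_inconsistent_initial_flows_still_converge(self, fluid):
        """A non-Murray seed violating conservation is pulled to the fixed point."""
        tree = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.4))
        measured = MeasuredInlet(pressure=1.2e4, flow=6e-6)
        bad_seed = np.array([3e-6, 3e-6, 3e-6])  # sums to 1.5 × Q_exp
        res = run_steady(tree, fluid, measured, initial_flows=bad_seed)
        assert res.converged
        assert res.residuals[0].flow_residual > 0.1  # round 2 had to redistribute
        final = res.final_state
        assert final.outlet_flows.sum() == pytest.approx(6e-6, rel=1e-8)
        # convergence flag is exactly the threshold rule on the last record
        last = res.residuals[-1]
        assert last.pressure_residual < 0.1 and last.flow_residual < 0.1

    def test_deterministic_history(self, fluid):
        tree = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.5))
        measured = MeasuredInlet(pressure=1.2e4, flow=6e-6)
        r1 = run_steady(tree, fluid, measured)
        r2 = run_steady(tree, fluid, measured)
        assert r1.ffr == r2.ffr
        for (_, _, s1), (_, _, s2) in zip(r1.iterations, r2.iterations):
            assert np.array_equal(s1.outlet_pressures, s2.outlet_pressures)
            assert np.array_equal(s1.outlet_flows, s2.outlet_flows)

    def test_round_cap_respected(self, fluid):
        tree = three_outlet_tree(stenosis=StenosisSpec(area_ratio=0.5))
        measured = MeasuredInlet(pressure=1.2e4, flow=6e-6)
        res = run_steady(tree, fluid, measured, PBAConfig(tolerance_pct=0.0, max_rounds=7))
        assert res.n_rounds == 7
        assert not res.converged

    def test_states_conserve_mass(self, fluid):
        tree, measured = make_fixture("CHN13")
        res = run_steady(tree, fluid, measured)
        for _, _, state in res.iterations:
            assert state.conservation_error(tree) <= 1e-10
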