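"""Reduced-order steady flow solver for rigid vessel networks.

Each segment is a lumped element with pressure loss ΔP(Q) = R·Q + S·Q·|Q|:
R is the Hagen–Poiseuille viscous resistance 8μl/(πr⁴) and S an inertial
loss coefficient contributed by a stenosis (S = 0 on healthy segments).
ΔP is strictly increasing in Q, so both boundary-condition modes the
iterative algorithm alternates are well posed:

* mode A — inlet pressure plus per-outlet flows prescribed: a direct
  evaluation (flows by conservation, pressures by marching down);
* mode B — inlet flow plus per-outlet pressures prescribed: a damped
  Newton solve for the outlet flows and the inlet pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import MMHG_TO_PA, FluidProps, VesselTree

__all__ = [
    "SegmentLossLaw",
    "FlowState",
    "SolverError",
    "build_loss_laws",
    "solve_given_outlet_flows",
    "solve_given_outlet_pressures",
]


class SolverError(RuntimeError):
    """Newton iteration failed to converge; carries the last residual norm."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last scaled residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class SegmentLossLaw:
    """Pressure-loss law ΔP(Q) = R·Q + S·Q·|Q| of one segment.

    ``viscous_resistance`` R in Pa·s/m³, ``turbulent_coeff`` S in Pa·s²/m⁶.
    """

    viscous_resistance: float
    turbulent_coeff: float = 0.0

    def __post_init__(self) -> None:
        if not self.viscous_resistance > 0:
            raise ValueError("viscous_resistance must be > 0")
        if self.turbulent_coeff < 0:
            raise ValueError("turbulent_coeff must be >= 0")

    def dp(self, q: float) -> float:
        return self.viscous_resistance * q + self.turbulent_coeff * q * abs(q)

    def dp_dq(self, q: float) -> float:
        return self.viscous_resistance + 2.0 * self.turbulent_coeff * abs(q)


def build_loss_laws(tree: VesselTree, fluid: FluidProps) -> dict[str, SegmentLossLaw]:
    """Per-segment loss laws: Poiseuille R, plus a stenosis loss if present.

    A stenosed segment of reference area A₀ = πr² narrowed to A_s adds
    S = K_t · ρ/(2A₀²) · (A₀/A_s − 1)², the Borda–Carnot-type expansion
    loss; S → 0 continuously as A_s → A₀.
    """
    laws: dict[str, SegmentLossLaw] = {}
    for seg in tree.segments:
        r = 8.0 * fluid.viscosity * seg.length / (np.pi * seg.radius**4)
        s = 0.0
        if seg.stenosis is not None:
            a0 = np.pi * seg.radius**2
            s = (
                seg.stenosis.turbulent_coeff
                * fluid.density
                / (2.0 * a0**2)
                * (1.0 / seg.stenosis.area_ratio - 1.0) ** 2
            )
        laws[seg.id] = SegmentLossLaw(viscous_resistance=r, turbulent_coeff=s)
    return laws


@dataclass(frozen=True)
class FlowState:
    """Solved network state: nodal pressures and segment/boundary flows.

    ``nodal_pressures`` maps each segment id to the pressure at its distal
    end (Pa); ``segment_flows`` to its volumetric flow (m³/s).  Outlet
    arrays are ordered by outlet index.
    """

    inlet_pressure: float
    inlet_flow: float
    nodal_pressures: dict[str, float]
    segment_flows: dict[str, float]
    outlet_pressures: np.ndarray
    outlet_flows: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "outlet_pressures", np.asarray(self.outlet_pressures, float))
        object.__setattr__(self, "outlet_flows", np.asarray(self.outlet_flows, float))

    def conservation_error(self, tree: VesselTree) -> float:
        """Largest relative mass-balance violation over junctions + globally."""
        scale = max(abs(self.inlet_flow), 1e-300)
        worst = abs(self.inlet_flow - self.outlet_flows.sum()) / scale
        for seg in tree.segments:
            ch = tree.children(seg.id)
            if ch:
                resid = abs(self.segment_flows[seg.id] - sum(self.segment_flows[c] for c in ch))
                worst = max(worst, resid / scale)
        return worst

    def to_outlet_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pressure_Pa": self.outlet_pressures,
                "pressure_mmHg": self.outlet_pressures / MMHG_TO_PA,
                "flow_cm3_s": self.outlet_flows * 1e6,
            },
            index=pd.RangeIndex(1, self.outlet_pressures.size + 1, name="outlet"),
        )

    def to_segment_frame(self) -> pd.DataFrame:
        ids = sorted(self.segment_flows)
        return pd.DataFrame(
            {
                "flow_cm3_s": [self.segment_flows[i] * 1e6 for i in ids],
                "distal_pressure_Pa": [self.nodal_pressures[i] for i in ids],
            },
            index=pd.Index(ids, name="segment"),
        )


def _segment_flows_from_outlets(tree: VesselTree, q_out: np.ndarray) -> dict[str, float]:
    """Flows per segment: each carries the sum of its subtree's outlet flows."""
    by_leaf = {o.segment_id: q_out[i] for i, o in enumerate(tree.outlets)}
    flows: dict[str, float] = {}
    for sid in tree.postorder():
        ch = tree.children(sid)
        flows[sid] = by_leaf[sid] if not ch else sum(flows[c] for c in ch)
    return flows


def _march_pressures(
    tree: VesselTree, laws: dict[str, SegmentLossLaw], inlet_pressure: float, flows: dict[str, float]
) -> dict[str, float]:
    """Pressure at each segment's distal end, marching down from the inlet."""
    p: dict[str, float] = {}
    order = tree.postorder()[::-1]  # parents first
    for sid in order:
        seg = tree.segment(sid)
        upstream = inlet_pressure if seg.parent is None else p[seg.parent]
        p[sid] = upstream - laws[sid].dp(flows[sid])
    return p


def solve_given_outlet_flows(
    tree: VesselTree,
    laws: dict[str, SegmentLossLaw],
    inlet_pressure: float,
    outlet_flows,
) -> FlowState:
    """Mode A: prescribe inlet pressure and per-outlet flows (direct evaluation).

    Segment flows follow from conservation; the inlet flow equals the sum
    of the prescribed outlet flows by construction.
    """
    q_out = np.asarray(outlet_flows, dtype=float)
    if q_out.size != tree.n_outlets:
        raise ValueError(f"expected {tree.n_outlets} outlet flows, got {q_out.size}")
    flows = _segment_flows_from_outlets(tree, q_out)
    press = _march_pressures(tree, laws, inlet_pressure, flows)
    p_out = np.array([press[o.segment_id] for o in tree.outlets])
    return FlowState(
        inlet_pressure=inlet_pressure,
        inlet_flow=float(q_out.sum()),
        nodal_pressures=press,
        segment_flows=flows,
        outlet_pressures=p_out,
        outlet_flows=q_out,
    )


def _path_segments(tree: VesselTree) -> list[list[str]]:
    return [tree.path_from_root(o.segment_id) for o in tree.outlets]


def _linear_solve(
    tree: VesselTree,
    laws: dict[str, SegmentLossLaw],
    inlet_flow: float,
    p_out: np.ndarray,
) -> np.ndarray:
    """Outlet flows of the S=0 (purely resistive) network — Newton's seed.

    Unknowns x = (q₁..q_N, P_in); path equations P_in − Σ R q = p_out plus
    the global conservation row Σ q = Q_in.
    """
    n = tree.n_outlets
    paths = _path_segments(tree)
    below: dict[str, list[int]] = {}
    for i, path in enumerate(paths):
        for sid in path:
            below.setdefault(sid, []).append(i)
    a = np.zeros((n + 1, n + 1))
    b = np.zeros(n + 1)
    for sid, outs in below.items():
        r = laws[sid].viscous_resistance
        for i in outs:
            for j in outs:
                a[i, j] -= r
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    b[:n] = p_out
    b[n] = inlet_flow
    return np.linalg.solve(a, b)[:n]


def solve_given_outlet_pressures(
    tree: VesselTree,
    laws: dict[str, SegmentLossLaw],
    inlet_flow: float,
    outlet_pressures,
    initial_flows=None,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> FlowState:
    """Mode B: prescribe inlet flow and per-outlet pressures (Newton solve).

    Solves for the outlet flows qᵢ and the inlet pressure P_in such that
    every root→outlet path drop matches P_in − p_outᵢ and Σ qᵢ = Q_in.
    Damped Newton (step halving on residual increase) with analytic
    Jacobian, seeded from the linearised S=0 solve or ``initial_flows``.

    Raises
    ------
    SolverError
        If the scaled residual does not fall below ``tol`` within
        ``max_iter`` iterations.
    """
    if not inlet_flow > 0:
        raise ValueError("inlet_flow must be > 0")
    p_out = np.asarray(outlet_pressures, dtype=float)
    n = tree.n_outlets
    if p_out.size != n:
        raise ValueError(f"expected {n} outlet pressures, got {p_out.size}")

    paths = _path_segments(tree)
    below: dict[str, list[int]] = {}
    for i, path in enumerate(paths):
        for sid in path:
            below.setdefault(sid, []).append(i)

    p_scale = max(np.abs(p_out).max(), 1.0)
    q_scale = inlet_flow

    def residual(q: np.ndarray, p_in: float) -> tuple[np.ndarray, dict[str, float]]:
        flows = _segment_flows_from_outlets(tree, q)
        f = np.empty(n + 1)
        for i, path in enumerate(paths):
            drop = sum(laws[sid].dp(flows[sid]) for sid in path)
            f[i] = (p_in - drop - p_out[i]) / p_scale
        f[n] = (q.sum() - inlet_flow) / q_scale
        return f, flows

    if initial_flows is not None:
        q = np.asarray(initial_flows, dtype=float).copy()
        # keep the seed strictly feasible in scale
        if not np.all(np.isfinite(q)) or q.size != n:
            raise ValueError("initial_flows must be a finite vector of per-outlet flows")
    else:
        q = _linear_solve(tree, laws, inlet_flow, p_out)
    flows = _segment_flows_from_outlets(tree, q)
    p_in = p_out.max() + max(
        sum(laws[s].dp(flows[s]) for s in path) for path in paths
    )

    f, flows = residual(q, p_in)
    norm = np.abs(f).max()
    for _ in range(max_iter):
        if norm < tol:
            break
        jac = np.zeros((n + 1, n + 1))
        for sid, outs in below.items():
            dd = laws[sid].dp_dq(flows[sid]) / p_scale
            for i in outs:
                for j in outs:
                    jac[i, j] -= dd
        jac[:n, n] = 1.0 / p_scale
        jac[n, :n] = 1.0 / q_scale
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular Jacobian: {exc}", norm) from exc
        lam = 1.0
        for _half in range(40):
            q_new = q + lam * step[:n]
            p_new = p_in + lam * step[n]
            f_new, flows_new = residual(q_new, p_new)
            if np.abs(f_new).max() < norm or lam < 1e-12:
                break
            lam *= 0.5
        q, p_in, f, flows = q_new, p_new, f_new, flows_new
        norm = np.abs(f).max()
    if norm >= tol and norm > 1e-10:
        raise SolverError("Newton iteration did not converge", norm)

    press = _march_pressures(tree, laws, p_in, flows)
    return FlowState(
        inlet_pressure=float(p_in),
        inlet_flow=float(inlet_flow),
        nodal_pressures=press,
        segment_flows=flows,
        outlet_pressures=np.array([press[o.segment_id] for o in tree.outlets]),
        outlet_flows=q,
    )
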