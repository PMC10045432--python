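"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities from first principles
(nodal resistance-network assembly, per-path hand summation) rather than
calling the package's solver internals, so that solver tests compare two
independent routes.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from ffrtree import FluidProps, OutletFace, Segment, StenosisSpec, VesselTree


@pytest.fixture
def fluid() -> FluidProps:
    return FluidProps()


def make_y_tree(
    r_root=2e-3,
    r_left=1.6e-3,
    r_right=1.6e-3,
    length_factor=10.0,
    stenosis_left: StenosisSpec | None = None,
) -> VesselTree:
    """Root plus two leaf branches; symmetric unless radii/stenosis differ."""
    segs = (
        Segment("root", r_root, length_factor * r_root, None),
        Segment("a", r_left, length_factor * r_left, "root", stenosis=stenosis_left),
        Segment("b", r_right, length_factor * r_right, "root"),
    )
    outs = (
        OutletFace("a", np.pi * (r_left * 100) ** 2, 1),
        OutletFace("b", np.pi * (r_right * 100) ** 2, 2),
    )
    return VesselTree(segs, outs)


@pytest.fixture
def y_tree() -> VesselTree:
    return make_y_tree()


def three_outlet_tree(stenosis=None) -> VesselTree:
    """Asymmetric 3-outlet tree: root → (branch → 2 leaves, 1 leaf)."""
    segs = (
        Segment("root", 2.5e-3, 0.03, None),
        Segment("m", 2.0e-3, 0.02, "root", stenosis=stenosis),
        Segment("l1", 1.5e-3, 0.015, "m"),
        Segment("l2", 1.2e-3, 0.012, "m"),
        Segment("l3", 1.8e-3, 0.018, "root"),
    )
    outs = (
        OutletFace("l1", np.pi * 0.15**2, 1),
        OutletFace("l2", np.pi * 0.12**2, 2),
        OutletFace("l3", np.pi * 0.18**2, 3),
    )
    return VesselTree(segs, outs)


# -- independent oracles --------------------------------------------------


def oracle_resistance(seg: Segment, mu: float) -> float:
    return 8.0 * mu * seg.length / (np.pi * seg.radius**4)


def oracle_stenosis_coeff(seg: Segment, rho: float) -> float:
    if seg.stenosis is None:
        return 0.0
    a0 = np.pi * seg.radius**2
    return (
        seg.stenosis.turbulent_coeff
        * rho
        / (2.0 * a0**2)
        * (1.0 / seg.stenosis.area_ratio - 1.0) ** 2
    )


def oracle_path_drop(tree: VesselTree, fluid: FluidProps, outlet: OutletFace, q_out) -> float:
    """Hand summation of R·Q + S·Q|Q| drops along the root→outlet path."""
    q_out = np.asarray(q_out, float)
    leaf_flows = {o.segment_id: q_out[i] for i, o in enumerate(tree.outlets)}

    def subtree_flow(sid: str) -> float:
        ch = tree.children(sid)
        if not ch:
            return leaf_flows[sid]
        return sum(subtree_flow(c) for c in ch)

    drop = 0.0
    for sid in tree.path_from_root(outlet.segment_id):
        seg = tree.segment(sid)
        q = subtree_flow(sid)
        drop += oracle_resistance(seg, fluid.viscosity) * q
        drop += oracle_stenosis_coeff(seg, fluid.density) * q * abs(q)
    return drop


def oracle_linear_network(tree: VesselTree, fluid: FluidProps, inlet_flow, outlet_pressures):
    """Sparse nodal solve of the S=0 resistance network.

    Nodes are the inlet face plus each segment's distal end; conductance
    1/R per segment; Dirichlet pressures at outlet nodes; flow injection
    at the inlet node.  Returns (inlet_pressure, outlet_flows).
    """
    ids = [s.id for s in tree.segments]
    idx = {"inlet": 0, **{sid: i + 1 for i, sid in enumerate(ids)}}
    n = len(idx)
    g = sp.lil_matrix((n, n))
    for s in tree.segments:
        cond = 1.0 / oracle_resistance(s, fluid.viscosity)
        a = idx["inlet"] if s.parent is None else idx[s.parent]
        b = idx[s.id]
        g[a, a] += cond
        g[b, b] += cond
        g[a, b] -= cond
        g[b, a] -= cond
    rhs = np.zeros(n)
    rhs[0] = inlet_flow
    fixed = {idx[o.segment_id]: p for o, p in zip(tree.outlets, outlet_pressures)}
    a_mat = g.tocsc()
    dense = a_mat.toarray()
    for j, v in fixed.items():
        for i in range(n):
            if i != j:
                rhs[i] -= dense[i, j] * v
        dense[j, :] = 0.0
        dense[:, j] = 0.0
        dense[j, j] = 1.0
        rhs[j] = v
    p = spsolve(sp.csr_matrix(dense), rhs)
    flows = []
    for o in tree.outlets:
        seg = tree.segment(o.segment_id)
        cond = 1.0 / oracle_resistance(seg, fluid.viscosity)
        up = idx["inlet"] if seg.parent is None else idx[seg.parent]
        flows.append(cond * (p[up] - p[idx[o.segment_id]]))
    return float(p[0]), np.array(flows)


def ulp(printed: float) -> float:
    """Unit in the last printed decimal place of a table value."""
    s = repr(float(printed))
    if "." not in s:
        return 1.0
    return 10.0 ** -(len(s.split(".")[1]))
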