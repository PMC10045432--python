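"""Packaged clinical fixtures and randomized Murray-consistent tree generation.

The fixtures carry the published inlet measurements and outlet-area
tables of three patient coronary trees (CT209, CHN13, CHN03) and the
benchmark-nozzle inlet, verbatim.  The published data fix the outlet
areas and the inlet pair only; the internal branching topology and the
segment lengths are not published, so the fixture trees use an
illustrative two-level left/right grouping with lengths synthesized as
10× radius.  Quantitative pressure drops on these trees are therefore
illustrative; the Murray split and all conservation properties are
data-anchored.

``generate_tree`` builds random binary trees whose radii satisfy the cube
law r_parent³ = Σ r_daughter³ exactly at every bifurcation, optionally
with random stenoses — the test bed for solver and iteration properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import MeasuredInlet, OutletFace, Segment, StenosisSpec, VesselTree

__all__ = [
    "FIXTURE_NAMES",
    "TreeGenSpec",
    "fixture_outlet_table",
    "fixture_inlet",
    "make_fixture",
    "generate_tree",
]

CM = 1e-2

FIXTURE_NAMES = ("CT209", "CHN13", "CHN03", "FDA_INLET")

# Published outlet tables, verbatim: (A_i cm², d_i cm, d_i³ cm³, α_i, Q_i cm³/s).
_OUTLET_TABLES = {
    "CT209": [
        (1.674, 1.46, 3.111, 0.082, 0.769),
        (4.105, 2.286, 11.948, 0.314, 2.955),
        (1.802, 1.515, 3.475, 0.091, 0.859),
        (0.977, 1.116, 1.388, 0.037, 0.343),
        (1.398, 1.334, 2.374, 0.062, 0.587),
        (4.114, 2.289, 11.988, 0.315, 2.965),
        (0.925, 1.085, 1.279, 0.034, 0.316),
        (0.568, 0.851, 0.616, 0.016, 0.152),
        (1.173, 1.222, 1.824, 0.048, 0.451),
    ],
    "CHN13": [
        (2.712, 1.858, 6.418, 0.227, 1.630),
        (1.832, 1.527, 3.564, 0.126, 0.905),
        (1.005, 1.131, 1.447, 0.051, 0.368),
        (1.950, 1.576, 3.913, 0.139, 0.994),
        (1.969, 1.583, 3.970, 0.141, 1.009),
        (3.382, 2.075, 8.936, 0.316, 2.270),
    ],
    "CHN03": [
        (2.5675, 1.8081, 5.9106, 0.2240, 1.3847),
        (2.2262, 1.6836, 4.7721, 0.1808, 1.1179),
        (2.1930, 1.6710, 4.6658, 0.1768, 1.0930),
        (1.8206, 1.5225, 3.5293, 0.1338, 0.8268),
        (1.7784, 1.5048, 3.4074, 0.1291, 0.7982),
        (2.0126, 1.6008, 4.1021, 0.1555, 0.9610),
    ],
}

# Published inlet pairs: pressure as printed in both mmHg and Pa, flow in
# cm³/s (or velocity in m/s for the nozzle).  The CHN13 mmHg/Pa pair is
# internally inconsistent in the source (90.61 mmHg ≈ 12080 Pa ≠ 12870.12);
# both printed values are kept and the inconsistency is flagged, not fixed.
_INLETS = {
    "CT209": {"pressure_mmHg": 90.53, "pressure_Pa": 12070.12, "flow_cm3_s": 9.39944,
              "pressure_consistent": True},
    "CHN13": {"pressure_mmHg": 90.61, "pressure_Pa": 12870.12, "flow_cm3_s": 7.17551,
              "pressure_consistent": False},
    "CHN03": {"pressure_mmHg": 76.5, "pressure_Pa": 10201.9, "flow_cm3_s": 6.18,
              "pressure_consistent": True},
    "FDA_INLET": {"pressure_mmHg": 63.61, "pressure_Pa": 8480.0, "velocity_m_s": 0.184,
                  "pressure_consistent": True},
}

#: Scaled nozzle bore (3 mm) used to convert the inlet velocity to a flow.
_FDA_TUBE_DIAMETER_M = 3e-3


def fixture_outlet_table(name: str) -> pd.DataFrame:
    """The published outlet table, verbatim, as a DataFrame (1-based index)."""
    if name not in _OUTLET_TABLES:
        raise KeyError(f"no outlet table for fixture {name!r}")
    return pd.DataFrame(
        _OUTLET_TABLES[name],
        columns=["Ai (cm^2)", "di (cm)", "di3 (cm^3)", "alpha_i", "Qi (cm^3/s)"],
        index=pd.RangeIndex(1, len(_OUTLET_TABLES[name]) + 1, name="outlet"),
    )


def fixture_inlet(name: str) -> MeasuredInlet:
    """The published inlet measurement for a fixture (verbatim Pa values)."""
    if name not in _INLETS:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    raw = _INLETS[name]
    if name == "FDA_INLET":
        v = raw["velocity_m_s"]
        area = np.pi * (_FDA_TUBE_DIAMETER_M / 2.0) ** 2
        return MeasuredInlet(
            pressure=raw["pressure_Pa"],
            flow=v * area,
            pressure_mmHg=raw["pressure_mmHg"],
            velocity=v,
        )
    return MeasuredInlet(
        pressure=raw["pressure_Pa"],
        flow=raw["flow_cm3_s"] * 1e-6,
        pressure_mmHg=raw["pressure_mmHg"],
    )


def inlet_pressure_consistent(name: str) -> bool:
    """Whether the printed mmHg/Pa inlet pair is internally consistent."""
    return _INLETS[name]["pressure_consistent"]


def _fixture_tree(name: str, length_factor: float) -> VesselTree:
    """Two-level tree over the published outlet areas.

    Outlets split into a left and a right group (first/second half of the
    table order); intermediate and root radii follow the cube law over
    their descendants.  Topology and lengths are illustrative — only the
    outlet areas are data.
    """
    rows = _OUTLET_TABLES[name]
    n = len(rows)
    d_cm = [2.0 * np.sqrt(a / np.pi) for a, *_ in rows]
    r_m = [d / 2.0 * CM for d in d_cm]
    half = (n + 1) // 2
    groups = {"L": list(range(half)), "R": list(range(half, n))}

    segments: list[Segment] = []
    outlets: list[OutletFace] = []
    r_branch = {}
    for gname, idxs in groups.items():
        r_branch[gname] = float(np.cbrt(sum(r_m[i] ** 3 for i in idxs)))
    r_root = float(np.cbrt(sum(r**3 for r in r_branch.values())))
    segments.append(Segment("inlet", r_root, length_factor * r_root, None))
    for gname, idxs in groups.items():
        rb = r_branch[gname]
        segments.append(Segment(gname, rb, length_factor * rb, "inlet"))
        for i in idxs:
            sid = f"out{i + 1}"
            segments.append(Segment(sid, r_m[i], length_factor * r_m[i], gname))
            outlets.append(OutletFace(segment_id=sid, area_cm2=rows[i][0], index=i + 1))
    inlet_area = np.pi * r_root**2
    return VesselTree(tuple(segments), tuple(outlets), inlet_area)


def make_fixture(
    name: str, length_factor: float = 10.0
) -> tuple[VesselTree | None, MeasuredInlet]:
    """Return (tree, measured inlet) for a named fixture.

    CT209 has 9 outlets; CHN13 and CHN03 have 6.  FDA_INLET carries no
    tree (the nozzle is not a branching network): the tree slot is None.
    """
    inlet = fixture_inlet(name)
    if name == "FDA_INLET":
        return None, inlet
    return _fixture_tree(name, length_factor), inlet


@dataclass(frozen=True)
class TreeGenSpec:
    """Recipe for a random Murray-consistent binary tree.

    ``depth`` — number of bifurcation levels (depth 1 = single segment);
    ``root_radius_cm`` — inlet radius; ``asymmetry`` ∈ [0,1] — spread of
    the daughter cube-share around ½ (0 = perfectly symmetric);
    ``stenosis_prob`` — per-non-root-segment probability of a stenosis
    with area_ratio drawn from ``stenosis_severity_range``.  The Murray
    exponent is fixed at 3.
    """

    depth: int = 3
    root_radius_cm: float = 0.2
    asymmetry: float = 0.0
    stenosis_prob: float = 0.0
    stenosis_severity_range: tuple[float, float] = (0.3, 0.8)
    length_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        if not 0.0 <= self.stenosis_prob <= 1.0:
            raise ValueError("stenosis_prob must lie in [0, 1]")
        lo, hi = self.stenosis_severity_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("stenosis_severity_range must satisfy 0 < lo <= hi < 1")


def generate_tree(spec: TreeGenSpec) -> VesselTree:
    """Generate a random binary tree satisfying the cube law at every junction.

    Deterministic for a fixed seed.  Each bifurcation splits the parent's
    r³ into shares (f, 1−f) with f = ½ + asymmetry·(u − ½), u ~ U(0,1), so
    r_parent³ = Σ r_daughter³ holds exactly by construction.
    """
    rng = np.random.default_rng(spec.seed)
    segments: list[Segment] = []
    outlets: list[OutletFace] = []

    def maybe_stenosis() -> StenosisSpec | None:
        if spec.stenosis_prob > 0 and rng.random() < spec.stenosis_prob:
            lo, hi = spec.stenosis_severity_range
            return StenosisSpec(area_ratio=float(rng.uniform(lo, hi)))
        return None

    def build(sid: str, radius_m: float, parent: str | None, level: int) -> None:
        segments.append(
            Segment(
                id=sid,
                radius=radius_m,
                length=spec.length_factor * radius_m,
                parent=parent,
                stenosis=None if parent is None else maybe_stenosis(),
            )
        )
        if level == spec.depth:
            area_cm2 = np.pi * (radius_m / CM) ** 2
            outlets.append(
                OutletFace(segment_id=sid, area_cm2=float(area_cm2), index=len(outlets) + 1)
            )
            return
        f = 0.5 + spec.asymmetry * (rng.random() - 0.5)
        r3 = radius_m**3
        build(sid + "0", float((f * r3) ** (1.0 / 3.0)), sid, level + 1)
        build(sid + "1", float(((1.0 - f) * r3) ** (1.0 / 3.0)), sid, level + 1)

    root_r = spec.root_radius_cm * CM
    build("s", root_r, None, 1)
    return VesselTree(tuple(segments), tuple(outlets), np.pi * root_r**2)
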