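"""Vascular-tree domain types, unit conversion and file I/O.

A coronary artery tree is represented as a rooted, directed tree of
cylindrical segments.  The root segment carries the inlet face (aortic
side); every leaf segment carries exactly one outlet face.  Geometry is
held in SI units internally (metres, Pa, m³/s); the file formats and the
clinical tables speak cm², cm³/s and mmHg, so conversion happens at the
interface, never implicitly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

__all__ = [
    "MMHG_TO_PA",
    "TreeFormatError",
    "TreeTopologyError",
    "StenosisSpec",
    "Segment",
    "OutletFace",
    "MeasuredInlet",
    "FluidProps",
    "VesselTree",
    "diameter_from_area",
    "convert_pressure",
    "load_tree",
    "save_tree",
    "load_measured_inlet",
    "read_outlet_table",
]

#: mmHg → Pa conversion constant (standard gravity, 0 °C mercury density).
MMHG_TO_PA = 133.322

CM = 1e-2
CM2 = 1e-4
CM3 = 1e-6


class TreeFormatError(ValueError):
    """A tree-description file violates the schema (names the offending field)."""


class TreeTopologyError(ValueError):
    """Segment connectivity is not a rooted tree (cycle, multiple roots, ...)."""


def diameter_from_area(area: float) -> float:
    """Equivalent circular diameter d = 2·√(A/π).

    Units are preserved: cm² in → cm out (the convention of the outlet
    tables), m² in → m out.

    Raises
    ------
    ValueError
        If ``area`` is not strictly positive.
    """
    if not area > 0:
        raise ValueError(f"area must be positive, got {area}")
    return 2.0 * math.sqrt(area / math.pi)


def convert_pressure(value_mmHg: float) -> float:
    """Convert a pressure from mmHg to Pa (1 mmHg = 133.322 Pa)."""
    return value_mmHg * MMHG_TO_PA


@dataclass(frozen=True)
class StenosisSpec:
    """Focal narrowing of a segment, as an area ratio plus a loss coefficient.

    Parameters
    ----------
    area_ratio : float
        Stenotic over reference lumen area, A_s/A_0, in (0, 1).
    turbulent_coeff : float
        Dimensionless empirical coefficient K_t of the quadratic
        (inertial) pressure loss across the narrowing.  The default 1.52
        is the classical sudden-expansion value.
    """

    area_ratio: float
    turbulent_coeff: float = 1.52

    def __post_init__(self) -> None:
        if not 0.0 < self.area_ratio < 1.0:
            raise ValueError(f"area_ratio must lie in (0, 1), got {self.area_ratio}")
        if self.turbulent_coeff < 0:
            raise ValueError("turbulent_coeff must be >= 0")


@dataclass(frozen=True)
class Segment:
    """One cylindrical vessel segment.

    ``radius`` and ``length`` are in metres.  ``parent`` is the id of the
    upstream segment, or ``None`` for the root (inlet) segment.
    """

    id: str
    radius: float
    length: float
    parent: str | None = None
    stenosis: StenosisSpec | None = None

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"segment {self.id!r}: radius must be > 0")
        if not self.length > 0:
            raise ValueError(f"segment {self.id!r}: length must be > 0")


@dataclass(frozen=True)
class OutletFace:
    """A distal outflow face, with the lumen area of the clinical tables.

    ``area_cm2`` is the measured cross-section A_i in cm²; ``diameter_cm``
    the equivalent diameter d_i.  If a diameter is supplied (e.g. read
    verbatim from a table) it must agree with 2·√(A/π) to 0.5 %.
    """

    segment_id: str
    area_cm2: float
    index: int
    diameter_cm: float | None = None

    def __post_init__(self) -> None:
        if not self.area_cm2 > 0:
            raise ValueError(f"outlet {self.index}: area must be > 0")
        d = diameter_from_area(self.area_cm2)
        if self.diameter_cm is None:
            object.__setattr__(self, "diameter_cm", d)
        elif abs(self.diameter_cm - d) > 5e-3 * d:
            raise ValueError(
                f"outlet {self.index}: stored diameter {self.diameter_cm} cm "
                f"inconsistent with area {self.area_cm2} cm² (expected {d:.4f} cm)"
            )


@dataclass(frozen=True)
class MeasuredInlet:
    """Patient-specific inlet measurements: pressure P_exp and flow Q_exp.

    ``pressure`` is in Pa, ``flow`` in m³/s.  ``pressure_mmHg`` keeps the
    clinically reported value when one exists; it is informational and may
    disagree slightly with ``pressure`` when the source table itself is
    inconsistent.  ``velocity`` (m/s) is carried for inlets specified as a
    mean velocity rather than a volumetric flow.
    """

    pressure: float
    flow: float
    pressure_mmHg: float | None = None
    velocity: float | None = None

    def __post_init__(self) -> None:
        if not self.pressure > 0:
            raise ValueError("inlet pressure must be > 0")
        if not self.flow > 0:
            raise ValueError("inlet flow must be > 0")

    @classmethod
    def from_clinical(
        cls,
        flow_cm3_s: float,
        pressure_mmHg: float | None = None,
        pressure_Pa: float | None = None,
        velocity: float | None = None,
    ) -> "MeasuredInlet":
        """Build from clinical units (mmHg, cm³/s).

        A verbatim Pa value takes precedence over the mmHg conversion when
        both are given, so that table-reported pairs are preserved exactly.
        """
        if pressure_Pa is None:
            if pressure_mmHg is None:
                raise ValueError("one of pressure_mmHg or pressure_Pa is required")
            pressure_Pa = convert_pressure(pressure_mmHg)
        return cls(
            pressure=pressure_Pa,
            flow=flow_cm3_s * CM3,
            pressure_mmHg=pressure_mmHg,
            velocity=velocity,
        )

    @property
    def flow_cm3_s(self) -> float:
        return self.flow / CM3


@dataclass(frozen=True)
class FluidProps:
    """Newtonian blood properties: μ = 0.0035 Pa·s, ρ = 1056 kg/m³."""

    viscosity: float = 0.0035
    density: float = 1056.0

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError("viscosity must be > 0")
        if not self.density > 0:
            raise ValueError("density must be > 0")


@dataclass
class VesselTree:
    """A validated rooted tree of segments with one inlet and N ≥ 1 outlets."""

    segments: tuple[Segment, ...]
    outlets: tuple[OutletFace, ...]
    inlet_area: float | None = None  # m², optional descriptive
    _children: dict[str, list[str]] = field(init=False, repr=False, compare=False)
    _by_id: dict[str, Segment] = field(init=False, repr=False, compare=False)
    _root: str = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.segments = tuple(self.segments)
        self.outlets = tuple(sorted(self.outlets, key=lambda o: o.index))
        self._by_id = {s.id: s for s in self.segments}
        if len(self._by_id) != len(self.segments):
            raise TreeTopologyError("duplicate segment ids")
        self._validate_topology()
        self._validate_outlets()

    # -- topology ---------------------------------------------------------

    def _validate_topology(self) -> None:
        roots = [s.id for s in self.segments if s.parent is None]
        if len(roots) != 1:
            raise TreeTopologyError(f"expected exactly one root segment, found {roots}")
        self._root = roots[0]
        g = nx.DiGraph()
        g.add_nodes_from(self._by_id)
        for s in self.segments:
            if s.parent is not None:
                if s.parent not in self._by_id:
                    raise TreeTopologyError(
                        f"segment {s.id!r} references unknown parent {s.parent!r}"
                    )
                g.add_edge(s.parent, s.id)
        if not nx.is_arborescence(g):
            raise TreeTopologyError("segment connectivity is not a rooted tree")
        self._children = {n: sorted(g.successors(n)) for n in g.nodes}

    def _validate_outlets(self) -> None:
        if not self.outlets:
            raise TreeTopologyError("tree must have at least one outlet")
        leaves = {sid for sid, ch in self._children.items() if not ch}
        seen: set[str] = set()
        for o in self.outlets:
            if o.segment_id not in self._by_id:
                raise TreeFormatError(f"outlet {o.index} references unknown segment {o.segment_id!r}")
            if o.segment_id not in leaves:
                raise TreeTopologyError(f"outlet {o.index} attached to non-leaf segment {o.segment_id!r}")
            if o.segment_id in seen:
                raise TreeTopologyError(f"segment {o.segment_id!r} carries more than one outlet")
            seen.add(o.segment_id)
        missing = leaves - seen
        if missing:
            raise TreeTopologyError(f"leaf segments without an outlet face: {sorted(missing)}")

    # -- accessors --------------------------------------------------------

    @property
    def root(self) -> Segment:
        return self._by_id[self._root]

    @property
    def n_outlets(self) -> int:
        return len(self.outlets)

    def segment(self, seg_id: str) -> Segment:
        return self._by_id[seg_id]

    def children(self, seg_id: str) -> list[str]:
        return self._children[seg_id]

    def path_from_root(self, seg_id: str) -> list[str]:
        """Segment ids on the root→segment path, inclusive of both ends."""
        path = [seg_id]
        s = self._by_id[seg_id]
        while s.parent is not None:
            path.append(s.parent)
            s = self._by_id[s.parent]
        return path[::-1]

    def postorder(self) -> list[str]:
        """Children-before-parent ordering of segment ids."""
        order: list[str] = []

        def visit(sid: str) -> None:
            for c in self._children[sid]:
                visit(c)
            order.append(sid)

        visit(self._root)
        return order

    def with_stenosis(self, seg_id: str, stenosis: StenosisSpec | None) -> "VesselTree":
        """Copy of the tree with the given segment's stenosis replaced."""
        segs = tuple(
            replace(s, stenosis=stenosis) if s.id == seg_id else s for s in self.segments
        )
        return VesselTree(segs, self.outlets, self.inlet_area)


# -- file I/O -------------------------------------------------------------


def _require(obj: dict, key: str, ctx: str):
    if key not in obj:
        raise TreeFormatError(f"{ctx}: missing required field {key!r}")
    return obj[key]


def load_tree(path) -> VesselTree:
    """Read a tree-description JSON file.

    Schema: ``segments`` (id, parent, radius_cm, length_cm, optional
    stenosis {area_ratio, Kt}), ``outlets`` (segment, area_cm2), optional
    ``inlet`` (segment, area_cm2).  Radii and lengths are converted from
    cm to metres on load.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TreeFormatError(f"not valid JSON: {exc}") from exc
    segments = []
    for raw in _require(doc, "segments", "tree file"):
        ctx = f"segment {raw.get('id', '?')!r}"
        sten = None
        if raw.get("stenosis") is not None:
            sraw = raw["stenosis"]
            sten = StenosisSpec(
                area_ratio=_require(sraw, "area_ratio", ctx + " stenosis"),
                turbulent_coeff=sraw.get("Kt", 1.52),
            )
        try:
            segments.append(
                Segment(
                    id=str(_require(raw, "id", ctx)),
                    radius=float(_require(raw, "radius_cm", ctx)) * CM,
                    length=float(_require(raw, "length_cm", ctx)) * CM,
                    parent=(str(raw["parent"]) if raw.get("parent") is not None else None),
                    stenosis=sten,
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, (TreeFormatError, TreeTopologyError)):
                raise
            raise TreeFormatError(f"{ctx}: {exc}") from exc
    outlets = []
    for i, raw in enumerate(_require(doc, "outlets", "tree file"), start=1):
        ctx = f"outlet {i}"
        outlets.append(
            OutletFace(
                segment_id=str(_require(raw, "segment", ctx)),
                area_cm2=float(_require(raw, "area_cm2", ctx)),
                index=int(raw.get("index", i)),
                diameter_cm=raw.get("diameter_cm"),
            )
        )
    inlet_area = None
    if doc.get("inlet") is not None:
        inlet_area = float(_require(doc["inlet"], "area_cm2", "inlet")) * CM2
    return VesselTree(tuple(segments), tuple(outlets), inlet_area)


def save_tree(tree: VesselTree, path) -> None:
    """Write a tree to the JSON schema read by :func:`load_tree`."""
    doc = {
        "segments": [
            {
                "id": s.id,
                "parent": s.parent,
                "radius_cm": s.radius / CM,
                "length_cm": s.length / CM,
                "stenosis": (
                    {"area_ratio": s.stenosis.area_ratio, "Kt": s.stenosis.turbulent_coeff}
                    if s.stenosis
                    else None
                ),
            }
            for s in tree.segments
        ],
        "outlets": [
            {
                "segment": o.segment_id,
                "area_cm2": o.area_cm2,
                "diameter_cm": o.diameter_cm,
                "index": o.index,
            }
            for o in tree.outlets
        ],
    }
    if tree.inlet_area is not None:
        doc["inlet"] = {"segment": tree.root.id, "area_cm2": tree.inlet_area / CM2}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_measured_inlet(path) -> MeasuredInlet:
    """Read measured-inlet JSON: ``{pressure_mmHg | pressure_Pa, flow_cm3_s}``."""
    with open(path) as fh:
        doc = json.load(fh)
    if "flow_cm3_s" not in doc:
        raise TreeFormatError("inlet file: missing required field 'flow_cm3_s'")
    if "pressure_mmHg" not in doc and "pressure_Pa" not in doc:
        raise TreeFormatError("inlet file: need 'pressure_mmHg' or 'pressure_Pa'")
    return MeasuredInlet.from_clinical(
        flow_cm3_s=float(doc["flow_cm3_s"]),
        pressure_mmHg=doc.get("pressure_mmHg"),
        pressure_Pa=doc.get("pressure_Pa"),
    )


def read_outlet_table(path) -> list[OutletFace]:
    """Read a flat CSV outlet table with columns ``Ai`` (cm²), optional ``di``.

    Column headers may carry unit suffixes ("Ai (cm^2)"); matching is on
    the leading token.  Rows become 1-based outlet faces on synthetic leaf
    ids ``out1..outN``.
    """
    df = pd.read_csv(path)
    cols = {str(c).strip().split()[0].lower(): c for c in df.columns}
    if "ai" not in cols:
        raise TreeFormatError("outlet table: missing required column 'Ai'")
    out = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        out.append(
            OutletFace(
                segment_id=f"out{i}",
                area_cm2=float(row[cols["ai"]]),
                index=i,
                diameter_cm=(float(row[cols["di"]]) if "di" in cols else None),
            )
        )
    return out
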