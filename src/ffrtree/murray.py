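"""Murray's-law power analysis and the cube-law outlet flow split.

Murray's principle: a vessel's radius minimises the total power spent
driving blood (Hagen–Poiseuille pumping term, ∝ Q²/r⁴) plus maintaining
the blood volume (metabolic term, ∝ r²).  The optimum gives Q ∝ r³, so
outlet flows of a tree split in proportion to the cubes of the outlet
diameters.  That split seeds the iterative boundary-condition algorithm;
the metabolic rate λ cancels in the normalised split and is only needed
for the power analysis itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tree import OutletFace, diameter_from_area

__all__ = [
    "MurrayParams",
    "MurraySplit",
    "poiseuille_power",
    "maintenance_power",
    "total_power",
    "optimal_flow",
    "murray_split",
]


@dataclass(frozen=True)
class MurrayParams:
    """Parameters of the power balance: metabolic rate λ (W/m³) and μ (Pa·s).

    λ may be ``None``: it cancels in the normalised cube-law split and is
    only required by :func:`optimal_flow`.
    """

    metabolic_rate: float | None = None
    viscosity: float = 0.0035

    def __post_init__(self) -> None:
        if self.metabolic_rate is not None and not self.metabolic_rate > 0:
            raise ValueError("metabolic_rate must be > 0 when given")
        if not self.viscosity > 0:
            raise ValueError("viscosity must be > 0")


def poiseuille_power(flow: float, radius: float, length: float, viscosity: float) -> float:
    """Pumping power (8 μ l / (π r⁴)) Q² to drive laminar flow Q through a vessel.

    All SI: Q in m³/s, r and l in m, μ in Pa·s; returns W.
    """
    if not (radius > 0 and length > 0 and viscosity > 0):
        raise ValueError("radius, length and viscosity must all be > 0")
    return 8.0 * viscosity * length / (math.pi * radius**4) * flow**2


def maintenance_power(radius: float, length: float, metabolic_rate: float) -> float:
    """Metabolic power λ·π l r² to maintain the blood volume of a vessel."""
    if not (radius > 0 and length > 0 and metabolic_rate > 0):
        raise ValueError("radius, length and metabolic_rate must all be > 0")
    return metabolic_rate * math.pi * length * radius**2


def total_power(flow: float, radius: float, length: float, params: MurrayParams) -> float:
    """Pumping plus maintenance power for a vessel carrying flow Q."""
    if params.metabolic_rate is None:
        raise ValueError("MurrayParams.metabolic_rate is required for the power balance")
    return poiseuille_power(flow, radius, length, params.viscosity) + maintenance_power(
        radius, length, params.metabolic_rate
    )


def optimal_flow(radius: float, params: MurrayParams) -> float:
    """Minimum-power flow (π/4) r³ √(λ/μ) for a vessel of radius r.

    This is the stationarity condition of the total power with respect to
    radius at fixed flow; it implies the cube law Q ∝ r³.
    """
    if not radius > 0:
        raise ValueError("radius must be > 0")
    if params.metabolic_rate is None:
        raise ValueError("MurrayParams.metabolic_rate is required for optimal_flow")
    return math.pi / 4.0 * radius**3 * math.sqrt(params.metabolic_rate / params.viscosity)


@dataclass(frozen=True)
class MurraySplit:
    """Cube-law split of an inlet flow over N outlets.

    ``cube_diameters`` holds dᵢ³, ``fractions`` the normalised shares
    αᵢ = dᵢ³/Σdⱼ³, ``flows`` the resulting Qᵢ = αᵢ·Q_in.  Flow units follow
    whatever unit the inlet flow was given in.
    """

    cube_diameters: np.ndarray
    fractions: np.ndarray
    flows: np.ndarray

    def __post_init__(self) -> None:
        for name in ("cube_diameters", "fractions", "flows"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(self.fractions > 0) or not np.all(self.flows > 0):
            raise ValueError("split entries must all be positive")
        if abs(self.fractions.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")

    @property
    def n(self) -> int:
        return self.fractions.size

    def to_frame(self, areas_cm2: Sequence[float] | None = None) -> pd.DataFrame:
        """Tabulate the split with the column layout of the clinical tables."""
        df = pd.DataFrame(
            {
                "di3 (cm^3)": self.cube_diameters,
                "alpha_i": self.fractions,
                "Qi (cm^3/s)": self.flows,
            },
            index=pd.RangeIndex(1, self.n + 1, name="outlet"),
        )
        if areas_cm2 is not None:
            df.insert(0, "Ai (cm^2)", np.asarray(areas_cm2, dtype=float))
            df.insert(1, "di (cm)", 2.0 * np.sqrt(df["Ai (cm^2)"] / np.pi))
        return df


def murray_split(outlets: Sequence[OutletFace], inlet_flow: float) -> MurraySplit:
    """Split an inlet flow over outlets in proportion to dᵢ³.

    Diameters are recomputed from the stored areas (d = 2√(A/π)), the
    derivation the clinical tables follow; any stored diameters are for
    cross-validation only.  ``inlet_flow`` may be in cm³/s or m³/s — the
    returned flows share its unit.
    """
    if len(outlets) == 0:
        raise ValueError("at least one outlet is required")
    if not inlet_flow > 0:
        raise ValueError("inlet_flow must be > 0")
    ordered = sorted(outlets, key=lambda o: o.index)
    d = np.array([diameter_from_area(o.area_cm2) for o in ordered])
    d3 = d**3
    alpha = d3 / d3.sum()
    return MurraySplit(cube_diameters=d3, fractions=alpha, flows=alpha * inlet_flow)
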