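"""Alternating boundary-condition iteration and FFR evaluation.

The algorithm couples the measured inlet pair (P_exp, Q_exp) with
Murray's-law outlet conditions by alternating which inlet quantity is
prescribed:

* round 1 — inlet pressure P_exp with Murray-split outlet flows; record
  the solved outlet pressures;
* round 2 — inlet flow Q_exp with the recorded outlet pressures; record
  the solved outlet flows;
* round 3 — inlet pressure P_exp with the recorded outlet flows; and so
  on, until the mean relative change of outlet pressures and flows
  between consecutive rounds falls below tolerance (or the round cap or
  a divergence guard trips).

FFR is the minimum outlet pressure of the final state over P_exp.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .murray import murray_split
from .solver import (
    FlowState,
    build_loss_laws,
    solve_given_outlet_flows,
    solve_given_outlet_pressures,
)
from .tree import FluidProps, MeasuredInlet, VesselTree

__all__ = [
    "BoundaryMode",
    "BoundaryState",
    "ResidualRecord",
    "PBAConfig",
    "PBAResult",
    "compute_ffr",
    "relative_error",
    "run_steady",
]

logger = logging.getLogger(__name__)


class BoundaryMode(enum.Enum):
    INLET_PRESSURE_OUTLET_FLOWS = "inlet_pressure_outlet_flows"
    INLET_FLOW_OUTLET_PRESSURES = "inlet_flow_outlet_pressures"


@dataclass(frozen=True)
class BoundaryState:
    """What is prescribed where in one round.

    In pressure-inlet rounds ``prescribed_inlet`` is P_exp (Pa) and
    ``prescribed_outlets`` are flows (m³/s); in flow-inlet rounds it is
    Q_exp (m³/s) and the outlets carry pressures (Pa).
    """

    mode: BoundaryMode
    prescribed_inlet: float
    prescribed_outlets: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "prescribed_outlets", np.asarray(self.prescribed_outlets, float)
        )


@dataclass(frozen=True)
class ResidualRecord:
    """Mean percent change of outlet quantities between consecutive rounds."""

    round: int
    pressure_residual: float
    flow_residual: float

    def __post_init__(self) -> None:
        if self.round < 2:
            raise ValueError("residuals are defined from round 2 onward")
        if self.pressure_residual < 0 or self.flow_residual < 0:
            raise ValueError("residuals must be >= 0")


@dataclass(frozen=True)
class PBAConfig:
    """Tunables of the outer iteration.

    ``tolerance_pct`` — convergence threshold on both mean residuals, in
    percent (default 0.1 %, i.e. 10⁻³ relative).  ``max_rounds`` — round
    cap (default 10).  ``divergence_patience`` — consecutive rounds of
    jointly increasing residuals that trip the divergence flag.
    """

    tolerance_pct: float = 0.1
    max_rounds: int = 10
    divergence_patience: int = 3
    newton_tol: float = 1e-12
    newton_max_iter: int = 50


@dataclass
class PBAResult:
    """Full iteration history plus the FFR outcome."""

    iterations: list[tuple[int, BoundaryState, FlowState]]
    residuals: list[ResidualRecord]
    converged: bool
    diverged: bool
    ffr: float
    ffr_outlet: int
    p_exp: float

    def __post_init__(self) -> None:
        if self.converged and self.diverged:
            raise ValueError("converged and diverged are mutually exclusive")

    @property
    def final_state(self) -> FlowState:
        return self.iterations[-1][2]

    @property
    def n_rounds(self) -> int:
        return len(self.iterations)

    @property
    def per_outlet_ffr(self) -> np.ndarray:
        return self.final_state.outlet_pressures / self.p_exp


def compute_ffr(outlet_pressures, p_exp: float) -> tuple[float, int]:
    """FFR = min(P₁…P_n)/P_exp, with the 1-based index of the minimising outlet.

    Ties report the lowest index.  Unit-invariant as long as pressures and
    P_exp share a unit.
    """
    p = np.asarray(outlet_pressures, dtype=float)
    if p.size == 0:
        raise ValueError("at least one outlet pressure is required")
    if not p_exp > 0:
        raise ValueError("p_exp must be > 0")
    idx = int(np.argmin(p))
    return float(p[idx] / p_exp), idx + 1


def relative_error(ffr_calc: float, ffr_invasive: float) -> float:
    """Percent relative error |FFR_calc − FFR_inv| / FFR_inv × 100."""
    if not ffr_invasive > 0:
        raise ValueError("invasive FFR must be > 0")
    return abs(ffr_calc - ffr_invasive) / ffr_invasive * 100.0


def _mean_pct_change(new: np.ndarray, old: np.ndarray) -> float:
    return float(np.mean(np.abs(new - old) / np.abs(old)) * 100.0)


def run_steady(
    tree: VesselTree,
    fluid: FluidProps,
    measured: MeasuredInlet,
    config: PBAConfig | None = None,
    initial_flows=None,
    newton_seed=None,
) -> PBAResult:
    """Run the steady alternating-boundary iteration to convergence.

    ``initial_flows`` (m³/s per outlet) overrides the Murray-split round-1
    outlet prescription; the default is the Murray split of Q_exp.
    ``newton_seed`` warm-starts the first flow-inlet Newton solve (an
    initial guess only — it cannot change the converged solution).
    """
    config = config or PBAConfig()
    laws = build_loss_laws(tree, fluid)

    if initial_flows is None:
        split = murray_split(tree.outlets, measured.flow)
        q = split.flows.copy()
    else:
        q = np.asarray(initial_flows, dtype=float).copy()
        if q.size != tree.n_outlets:
            raise ValueError(f"expected {tree.n_outlets} initial flows")

    iterations: list[tuple[int, BoundaryState, FlowState]] = []
    residuals: list[ResidualRecord] = []
    converged = diverged = False
    rising = 0

    for rnd in range(1, config.max_rounds + 1):
        if rnd % 2 == 1:
            bstate = BoundaryState(
                BoundaryMode.INLET_PRESSURE_OUTLET_FLOWS, measured.pressure, q
            )
            state = solve_given_outlet_flows(tree, laws, measured.pressure, q)
        else:
            p_prev = iterations[-1][2].outlet_pressures
            bstate = BoundaryState(
                BoundaryMode.INLET_FLOW_OUTLET_PRESSURES, measured.flow, p_prev
            )
            seed = iterations[-1][2].outlet_flows
            if rnd == 2 and newton_seed is not None:
                seed = np.asarray(newton_seed, dtype=float)
            state = solve_given_outlet_pressures(
                tree,
                laws,
                measured.flow,
                p_prev,
                initial_flows=seed,
                tol=config.newton_tol,
                max_iter=config.newton_max_iter,
            )
            q = state.outlet_flows
        logger.info(
            "round %d: %s inlet=%.6g", rnd, bstate.mode.value, bstate.prescribed_inlet
        )
        iterations.append((rnd, bstate, state))

        if rnd >= 2:
            prev = iterations[-2][2]
            rec = ResidualRecord(
                round=rnd,
                pressure_residual=_mean_pct_change(
                    state.outlet_pressures, prev.outlet_pressures
                ),
                flow_residual=_mean_pct_change(state.outlet_flows, prev.outlet_flows),
            )
            residuals.append(rec)
            if (
                rec.pressure_residual < config.tolerance_pct
                and rec.flow_residual < config.tolerance_pct
            ):
                converged = True
                break
            if len(residuals) >= 2:
                last = residuals[-2]
                if (
                    rec.pressure_residual > last.pressure_residual
                    and rec.flow_residual > last.flow_residual
                ):
                    rising += 1
                else:
                    rising = 0
                if rising >= config.divergence_patience:
                    diverged = True
                    break

    final = iterations[-1][2]
    ffr, outlet = compute_ffr(final.outlet_pressures, measured.pressure)
    return PBAResult(
        iterations=iterations,
        residuals=residuals,
        converged=converged,
        diverged=diverged,
        ffr=ffr,
        ffr_outlet=outlet,
        p_exp=measured.pressure,
    )
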