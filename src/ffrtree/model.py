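"""Model/Results façade over the boundary-alternation pipeline.

``FFRModel`` binds a vessel tree, the measured inlet pair and the fluid
properties; ``fit()`` runs the steady alternating-boundary iteration and
returns an ``FFRResults`` carrying the FFR estimate, per-outlet state,
residual history and a text summary.  ``fit_transient()`` wraps the
quasi-steady pulsatile driver the same way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pba import PBAConfig, PBAResult, run_steady
from .pulsatile import TransientConfig, TransientResult, Waveform, run_transient
from .synthetic import make_fixture
from .tree import (
    MMHG_TO_PA,
    FluidProps,
    MeasuredInlet,
    VesselTree,
    load_measured_inlet,
    load_tree,
)

__all__ = ["FFRModel", "FFRResults", "TransientFFRResults"]


class FFRModel:
    """Fractional-flow-reserve model of a coronary tree under measured inlet data.

    Parameters
    ----------
    tree : VesselTree
        The vascular network (one inlet, N outlets).
    measured : MeasuredInlet
        Patient inlet pressure P_exp (Pa) and flow Q_exp (m³/s).
    fluid : FluidProps, optional
        Blood properties; defaults μ = 0.0035 Pa·s, ρ = 1056 kg/m³.
    config : PBAConfig, optional
        Outer-iteration tunables (tolerance 0.1 %, round cap 10).
    """

    def __init__(
        self,
        tree: VesselTree,
        measured: MeasuredInlet,
        fluid: FluidProps | None = None,
        config: PBAConfig | None = None,
    ):
        self.tree = tree
        self.measured = measured
        self.fluid = fluid or FluidProps()
        self.config = config or PBAConfig()

    @classmethod
    def from_files(cls, tree_path, inlet_path, **kwargs) -> "FFRModel":
        """Build from a tree-description JSON and a measured-inlet JSON."""
        return cls(load_tree(tree_path), load_measured_inlet(inlet_path), **kwargs)

    @classmethod
    def from_fixture(cls, name: str, **kwargs) -> "FFRModel":
        """Build from a packaged clinical fixture (CT209, CHN13, CHN03)."""
        tree, inlet = make_fixture(name)
        if tree is None:
            raise ValueError(f"fixture {name!r} carries no vessel tree")
        return cls(tree, inlet, **kwargs)

    def fit(self, initial_flows=None) -> "FFRResults":
        """Run the steady iteration; returns the fitted results."""
        res = run_steady(
            self.tree, self.fluid, self.measured, self.config, initial_flows=initial_flows
        )
        return FFRResults(self, res)

    def fit_transient(
        self,
        flow_wave: Waveform,
        pressure_wave: Waveform | None = None,
        cycles: int = 2,
        steps_per_cycle: int = 100,
    ) -> "TransientFFRResults":
        """Run the quasi-steady pulsatile driver; returns transient results."""
        res = run_transient(
            self.tree,
            self.fluid,
            self.measured,
            flow_wave,
            pressure_wave,
            self.config,
            TransientConfig(cycles=cycles, steps_per_cycle=steps_per_cycle),
        )
        return TransientFFRResults(self, res)


class FFRResults:
    """Results of a steady fit: FFR, convergence diagnostics, outlet state."""

    def __init__(self, model: FFRModel, result: PBAResult):
        self.model = model
        self._result = result

    # -- primary outcomes -------------------------------------------------

    @property
    def ffr(self) -> float:
        return self._result.ffr

    @property
    def ffr_outlet(self) -> int:
        return self._result.ffr_outlet

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def diverged(self) -> bool:
        return self._result.diverged

    @property
    def n_rounds(self) -> int:
        return self._result.n_rounds

    @property
    def result(self) -> PBAResult:
        """The full iteration history (rounds, boundary states, flow states)."""
        return self._result

    # -- tables -----------------------------------------------------------

    def outlet_table(self) -> pd.DataFrame:
        """Final-state per-outlet pressures, flows and per-outlet FFR."""
        df = self._result.final_state.to_outlet_frame()
        df["ffr_i"] = self._result.per_outlet_ffr
        return df

    def residual_table(self) -> pd.DataFrame:
        """Per-round mean percent residuals of outlet pressures and flows."""
        return pd.DataFrame(
            [
                {
                    "round": r.round,
                    "pressure_residual_pct": r.pressure_residual,
                    "flow_residual_pct": r.flow_residual,
                }
                for r in self._result.residuals
            ]
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        m = self.model.measured
        lines = [
            "Fractional Flow Reserve — alternating boundary-condition fit",
            "=" * 62,
            f"Outlets:                 {self.model.tree.n_outlets}",
            f"Inlet pressure P_exp:    {m.pressure:.2f} Pa"
            + (f" ({m.pressure / MMHG_TO_PA:.2f} mmHg)"),
            f"Inlet flow Q_exp:        {m.flow_cm3_s:.5f} cm3/s",
            f"Rounds run:              {self.n_rounds}",
            f"Converged:               {self.converged}"
            + ("  (diverged)" if self.diverged else ""),
            f"FFR:                     {self.ffr:.4f}  (outlet {self.ffr_outlet})",
            "-" * 62,
            self.outlet_table().to_string(float_format=lambda x: f"{x:.4f}"),
        ]
        if self._result.residuals:
            lines += ["-" * 62, self.residual_table().to_string(index=False,
                      float_format=lambda x: f"{x:.6f}")]
        return "\n".join(lines)

    def plot_residuals(self, ax=None):
        """Log-scale residual history (mean % change per round)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.residual_table()
        if not df.empty:
            ax.semilogy(df["round"], df["pressure_residual_pct"], "o-", label="pressure")
            ax.semilogy(df["round"], df["flow_residual_pct"], "s-", label="flow")
            ax.legend()
        ax.set_xlabel("round")
        ax.set_ylabel("mean residual (%)")
        return ax


class TransientFFRResults:
    """Results of a quasi-steady pulsatile fit: FFR(t) and its cycle mean."""

    def __init__(self, model: FFRModel, result: TransientResult):
        self.model = model
        self._result = result

    @property
    def mean_ffr(self) -> float:
        """Trapezoidal time-average of FFR over the final cycle (the outcome)."""
        return self._result.mean_ffr

    @property
    def ffr_series(self) -> np.ndarray:
        return self._result.ffr_series

    @property
    def times(self) -> np.ndarray:
        return self._result.times

    @property
    def diverged(self) -> bool:
        return self._result.diverged

    @property
    def result(self) -> TransientResult:
        return self._result

    def to_frame(self) -> pd.DataFrame:
        return self._result.to_frame()

    def summary(self) -> str:
        r = self._result
        return "\n".join(
            [
                "Fractional Flow Reserve — quasi-steady pulsatile fit",
                "=" * 62,
                f"Timesteps:               {r.times.size}",
                f"Flagged steps:           {r.flagged_steps}",
                f"Run diverged:            {r.diverged}",
                f"FFR range over cycles:   [{r.ffr_series.min():.4f}, {r.ffr_series.max():.4f}]",
                f"Mean FFR (final cycle):  {r.mean_ffr:.4f}",
            ]
        )

    def plot_ffr(self, ax=None):
        """FFR time series over the simulated cycles."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.ffr_series)
        ax.axhline(self.mean_ffr, ls="--", color="k", label=f"mean {self.mean_ffr:.3f}")
        ax.set_xlabel("t (s)")
        ax.set_ylabel("FFR")
        ax.legend()
        return ax
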