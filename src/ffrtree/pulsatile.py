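"""Quasi-steady pulsatile driver: periodic inlet waveforms and cycle-mean FFR.

The network is rigid (no compliance or inertance), so a pulsatile run is
a sequence of steady solves with the inlet prescriptions scaled by
periodic waveforms — valid whenever storage effects are negligible and
only time-averaged quantities are of interest.  Each timestep runs the
full alternating-boundary iteration at the instantaneous scaled inlet
pair, warm-starting the nonlinear solves from the previous step.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pba import PBAConfig, PBAResult, run_steady
from .tree import FluidProps, MeasuredInlet, VesselTree

__all__ = [
    "WaveKind",
    "WaveQuantity",
    "Waveform",
    "sinus_value",
    "time_average",
    "TransientConfig",
    "StepSummary",
    "TransientResult",
    "run_transient",
]


class WaveKind(enum.Enum):
    SINUS = "sinus"
    TABLE = "table"


class WaveQuantity(enum.Enum):
    FLOW_SCALE = "flow_scale"
    VELOCITY = "velocity"
    PRESSURE_SCALE = "pressure_scale"


def sinus_value(
    t: float, mean: float, cos_amp: float, sin_amp: float, period: float = 1.0
) -> float:
    """mean − cos_amp·cos(2πt/T) − sin_amp·sin(2πt/T)."""
    w = 2.0 * math.pi * t / period
    return mean - cos_amp * math.cos(w) - sin_amp * math.sin(w)


@dataclass(frozen=True)
class Waveform:
    """A periodic inlet waveform, analytic (sinus) or tabulated.

    SINUS uses ``coefficients`` = (mean, cos_amp, sin_amp); TABLE uses
    ``samples`` = (times, values) covering [0, period) monotonically and
    is interpolated periodically.  ``quantity`` says what the values mean:
    an absolute velocity, or a dimensionless scale factor on the steady
    flow or pressure prescription.
    """

    kind: WaveKind
    period: float = 1.0
    coefficients: tuple[float, float, float] | None = None
    samples: tuple[np.ndarray, np.ndarray] | None = None
    quantity: WaveQuantity = WaveQuantity.FLOW_SCALE

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ValueError("period must be > 0")
        if self.kind is WaveKind.SINUS:
            if self.coefficients is None:
                raise ValueError("SINUS waveform requires coefficients")
            if not self.coefficients[0] > 0:
                raise ValueError("SINUS mean must be > 0")
        else:
            if self.samples is None:
                raise ValueError("TABLE waveform requires samples")
            t = np.asarray(self.samples[0], float)
            v = np.asarray(self.samples[1], float)
            if t.size != v.size or t.size < 2:
                raise ValueError("TABLE waveform needs >= 2 (t, value) samples")
            if np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] >= self.period:
                raise ValueError("TABLE samples must cover [0, period) monotonically")
            object.__setattr__(self, "samples", (t, v))

    # -- constructors -----------------------------------------------------

    @classmethod
    def sinus(
        cls,
        mean: float,
        cos_amp: float,
        sin_amp: float,
        period: float = 1.0,
        quantity: WaveQuantity = WaveQuantity.VELOCITY,
    ) -> "Waveform":
        return cls(WaveKind.SINUS, period, (mean, cos_amp, sin_amp), None, quantity)

    @classmethod
    def coronary_sinus(cls) -> "Waveform":
        """The benchmark sinus inlet: 0.184 − 0.02432·cos(2πt) − 0.09822·sin(2πt) m/s."""
        return cls.sinus(0.184, 0.02432, 0.09822, period=1.0, quantity=WaveQuantity.VELOCITY)

    @classmethod
    def from_table(
        cls, times, values, period: float, quantity: WaveQuantity = WaveQuantity.FLOW_SCALE
    ) -> "Waveform":
        return cls(
            WaveKind.TABLE,
            period,
            None,
            (np.asarray(times, float), np.asarray(values, float)),
            quantity,
        )

    @classmethod
    def from_csv(
        cls, path, period: float | None = None, quantity: WaveQuantity = WaveQuantity.FLOW_SCALE
    ) -> "Waveform":
        """Read a two-column CSV ``t_s,value``; period defaults to the time span."""
        df = pd.read_csv(path)
        if "t_s" not in df.columns or "value" not in df.columns:
            raise ValueError("waveform CSV requires columns 't_s' and 'value'")
        t = df["t_s"].to_numpy(float)
        v = df["value"].to_numpy(float)
        if period is None:
            period = float(t[-1] + (t[-1] - t[0]) / max(t.size - 1, 1))
        return cls.from_table(t, v, period, quantity)

    @classmethod
    def constant(cls, value: float = 1.0, quantity: WaveQuantity = WaveQuantity.FLOW_SCALE):
        return cls.sinus(value, 0.0, 0.0, period=1.0, quantity=quantity)

    # -- evaluation -------------------------------------------------------

    def value(self, t):
        """Waveform value at time t (scalar or array), periodically extended."""
        t = np.asarray(t, dtype=float)
        tau = np.mod(t, self.period)
        if self.kind is WaveKind.SINUS:
            mean, ca, sa = self.coefficients
            w = 2.0 * np.pi * tau / self.period
            out = mean - ca * np.cos(w) - sa * np.sin(w)
        else:
            ts, vs = self.samples
            # wrap: append the first sample at t = period
            ts_w = np.concatenate([ts, [self.period + ts[0]]])
            vs_w = np.concatenate([vs, [vs[0]]])
            out = np.interp(tau, ts_w, vs_w)
        return out if out.ndim else float(out)

    def time_average(self) -> float:
        """Exact cycle mean: analytic for SINUS, trapezoidal for TABLE."""
        if self.kind is WaveKind.SINUS:
            return self.coefficients[0]  # harmonics integrate to zero
        ts, vs = self.samples
        ts_w = np.concatenate([ts, [self.period + ts[0]]])
        vs_w = np.concatenate([vs, [vs[0]]])
        return float(np.trapezoid(vs_w, ts_w) / self.period)

    def normalized(self, quantity: WaveQuantity = WaveQuantity.FLOW_SCALE) -> "Waveform":
        """Unit-mean scale-factor version of this waveform."""
        mean = self.time_average()
        if self.kind is WaveKind.SINUS:
            m, ca, sa = self.coefficients
            return Waveform(WaveKind.SINUS, self.period, (1.0, ca / mean, sa / mean), None, quantity)
        ts, vs = self.samples
        return Waveform(WaveKind.TABLE, self.period, None, (ts, vs / mean), quantity)


def time_average(w: Waveform) -> float:
    """Exact time-average of a waveform over one period."""
    if w.kind is WaveKind.TABLE and w.samples[0].size < 2:
        raise ValueError("TABLE waveform needs at least 2 samples")
    return w.time_average()


@dataclass(frozen=True)
class TransientConfig:
    """Time discretisation of the quasi-steady run: 2 cycles, 100 steps each."""

    cycles: int = 2
    steps_per_cycle: int = 100


@dataclass(frozen=True)
class StepSummary:
    time: float
    ffr: float
    converged: bool
    diverged: bool
    n_rounds: int
    min_outlet_pressure: float


@dataclass
class TransientResult:
    """FFR time series and its final-cycle mean (the outcome value)."""

    times: np.ndarray
    ffr_series: np.ndarray
    mean_ffr: float
    per_step: list[StepSummary]
    flagged_steps: int
    diverged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.times, "ffr": self.ffr_series})


def _scale_factor(wave: Waveform | None, t: float) -> float:
    if wave is None:
        return 1.0
    if wave.quantity is WaveQuantity.VELOCITY:
        return wave.value(t) / wave.time_average()
    return float(wave.value(t))


def run_transient(
    tree: VesselTree,
    fluid: FluidProps,
    measured: MeasuredInlet,
    flow_wave: Waveform,
    pressure_wave: Waveform | None = None,
    config: PBAConfig | None = None,
    transient: TransientConfig | None = None,
) -> TransientResult:
    """Quasi-steady pulsatile run: per-timestep alternating-boundary solves.

    The inlet flow prescription is Q_exp scaled by ``flow_wave`` and the
    inlet pressure P_exp scaled by ``pressure_wave`` (default: constant 1).
    A preliminary steady run warm-starts the first step; each subsequent
    step warm-starts from its predecessor.  FFR(t) is evaluated against
    the instantaneous scaled inlet pressure; ``mean_ffr`` is the
    trapezoidal average over the final cycle.

    A step whose inner iteration diverges is flagged; if more than 10 % of
    steps are flagged the whole run is marked diverged.
    """
    config = config or PBAConfig()
    transient = transient or TransientConfig()
    if flow_wave.quantity is WaveQuantity.FLOW_SCALE:
        if abs(flow_wave.time_average() - 1.0) > 1e-6:
            raise ValueError(
                "FLOW_SCALE waveform must have unit time-average "
                f"(got {flow_wave.time_average():.8f}); use .normalized()"
            )
    if pressure_wave is not None and pressure_wave.quantity is WaveQuantity.PRESSURE_SCALE:
        if abs(pressure_wave.time_average() - 1.0) > 1e-6:
            raise ValueError("PRESSURE_SCALE waveform must have unit time-average")

    # preliminary steady run provides the warm start for step 0
    warm = run_steady(tree, fluid, measured, config).final_state.outlet_flows

    n = transient.cycles * transient.steps_per_cycle
    dt = flow_wave.period / transient.steps_per_cycle
    times = np.arange(n) * dt
    ffr = np.empty(n)
    per_step: list[StepSummary] = []
    flagged = 0
    for k, t in enumerate(times):
        sf = _scale_factor(flow_wave, t)
        sp = _scale_factor(pressure_wave, t)
        scaled = replace(
            measured,
            pressure=measured.pressure * sp,
            flow=measured.flow * sf,
            pressure_mmHg=None,
        )
        res: PBAResult = run_steady(tree, fluid, scaled, config, newton_seed=warm)
        warm = res.final_state.outlet_flows
        ffr[k] = res.ffr
        if res.diverged:
            flagged += 1
        per_step.append(
            StepSummary(
                time=float(t),
                ffr=res.ffr,
                converged=res.converged,
                diverged=res.diverged,
                n_rounds=res.n_rounds,
                min_outlet_pressure=float(res.final_state.outlet_pressures.min()),
            )
        )

    # final-cycle trapezoidal mean, closed periodically
    spc = transient.steps_per_cycle
    last = ffr[-spc:]
    t_last = times[-spc:]
    t_closed = np.concatenate([t_last, [t_last[0] + flow_wave.period]])
    f_closed = np.concatenate([last, [last[0]]])
    mean_ffr = float(np.trapezoid(f_closed, t_closed) / flow_wave.period)

    return TransientResult(
        times=times,
        ffr_series=ffr,
        mean_ffr=mean_ffr,
        per_step=per_step,
        flagged_steps=flagged,
        diverged=flagged > 0.1 * n,
    )
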