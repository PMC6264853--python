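"""Compliance dynamics of the renal pelvis.

The renal pelvis is a compliant reservoir with linear constitutive relation
ΔP = K ΔV.  Mass conservation plus Poiseuille's law for the inflow and outflow
conduits gives a first-order linear ODE for the gauge pressure P(t):

* scope inserted (irrigation on)::

      dP/dt + (K/Rin)(1 + Rin/Rout) P = (K/Rin) P_irr

  whose solution rises exponentially from P₀ to the plateau
  P_max = P_irr (1 + Rin/Rout)⁻¹ with time constant
  τ_in = (Rin/K)(1 + Rin/Rout)⁻¹;

* scope withdrawn (irrigation off)::

      dP/dt + (K/Rw) P = 0

  a pure exponential decay to zero gauge with τ_out = Rw/K.

The closed forms are implemented directly; :func:`integrate_ode` provides an
independent numerical oracle for them.  Pressures are gauge relative to the
bladder/atmospheric baseline and are nonnegative for nonnegative P₀.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .hydraulics import ResistanceSet
from .units import Pa_to_cmH2O

__all__ = [
    "CircuitParameters",
    "TimeConstants",
    "PhaseSegment",
    "PressureTrace",
    "steady_state_pressure",
    "rise_time",
    "decay_time",
    "time_constants",
    "insertion_pressure",
    "withdrawal_pressure",
    "running_mean_pressure",
    "integrate_ode",
    "nondimensionalize",
]

PhaseKind = Literal["inserted", "withdrawn"]


@dataclass(frozen=True)
class CircuitParameters:
    """Everything the pressure ODE needs for one configuration."""

    resistances: ResistanceSet
    stiffness: float  # K [Pa/m³]
    irrigation_pressure: float  # P_irr [Pa], gauge
    initial_pressure: float = 0.0  # P₀ [Pa], gauge

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError(f"stiffness must be positive, got {self.stiffness}")
        if self.irrigation_pressure <= 0:
            raise ValueError(
                f"irrigation pressure must be positive, got {self.irrigation_pressure}"
            )
        if self.initial_pressure < 0:
            raise ValueError(
                f"initial pressure must be nonnegative, got {self.initial_pressure}"
            )


@dataclass(frozen=True)
class TimeConstants:
    """Characteristic rise and decay times of the circuit [s]."""

    rise: float  # τ_in
    decay: float  # τ_out

    def __post_init__(self) -> None:
        if self.rise <= 0 or self.decay <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class PhaseSegment:
    """One analytic phase of a simulated procedure.

    Carries enough to reconstruct the exact solution (and its exact time
    integral) on the segment without resampling.
    """

    kind: PhaseKind
    t_start: float
    t_end: float
    p_start: float  # gauge pressure at t_start [Pa]
    tau: float  # τ_in or τ_out of this phase [s]
    p_plateau: float  # asymptote: P_max while inserted, 0 while withdrawn

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def pressure(self, t: np.ndarray | float) -> np.ndarray | float:
        """Exact pressure at absolute time(s) ``t`` within the segment."""
        decay = np.exp(-(np.asarray(t, dtype=float) - self.t_start) / self.tau)
        return self.p_plateau + (self.p_start - self.p_plateau) * decay

    @property
    def p_end(self) -> float:
        return float(self.pressure(self.t_end))

    def integral(self) -> float:
        """Exact ∫ P dt over the segment [Pa·s]."""
        T = self.duration
        return self.p_plateau * T + self.tau * (self.p_start - self.p_plateau) * (
            1.0 - float(np.exp(-T / self.tau))
        )

    def time_above(self, threshold: float) -> float:
        """Exact time spent above ``threshold`` within the segment [s]."""
        p0, p1 = self.p_start, self.p_end
        if p0 <= threshold and p1 <= threshold:
            return 0.0
        if p0 > threshold and p1 > threshold:
            return self.duration
        # monotone exponential: single crossing
        t_cross = self.tau * float(
            np.log((self.p_start - self.p_plateau) / (threshold - self.p_plateau))
        )
        t_cross = min(max(t_cross, 0.0), self.duration)
        return self.duration - t_cross if p0 <= threshold else t_cross


@dataclass(frozen=True)
class PressureTrace:
    """A sampled pressure-vs-time curve with phase labels.

    ``segments``, when present, carry the exact analytic phases the trace was
    sampled from; averaging and threshold metrics then use exact integrals
    rather than grid quadrature.
    """

    times: np.ndarray  # strictly increasing [s]
    pressures: np.ndarray  # gauge [Pa]
    phase_labels: np.ndarray  # "inserted" | "withdrawn" per sample
    segments: Optional[tuple[PhaseSegment, ...]] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pressures = np.asarray(self.pressures, dtype=float)
        labels = np.asarray(self.phase_labels)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pressures", pressures)
        object.__setattr__(self, "phase_labels", labels)
        if not (len(times) == len(pressures) == len(labels)):
            raise ValueError("times, pressures and phase_labels must align")
        if len(times) == 0:
            raise ValueError("trace must be nonempty")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(pressures < 0):
            raise ValueError("gauge pressures must be nonnegative")

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        """Trace as a DataFrame with clinical units in the column names."""
        return pd.DataFrame(
            {
                "time_s": self.times,
                "pressure_cmH2O": Pa_to_cmH2O(self.pressures),
                "phase": self.phase_labels,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# --- closed-form solutions ---------------------------------------------------


def steady_state_pressure(params: CircuitParameters) -> float:
    """Plateau pressure P_max = P_irr (1 + Rin/Rout)⁻¹ [Pa]; always < P_irr."""
    r = params.resistances
    return params.irrigation_pressure / (1.0 + r.inflow / r.outflow)


def rise_time(params: CircuitParameters) -> float:
    """Characteristic rise time τ_in = (Rin/K)(1 + Rin/Rout)⁻¹ [s]."""
    r = params.resistances
    return (r.inflow / params.stiffness) / (1.0 + r.inflow / r.outflow)


def decay_time(withdrawal_resistance: float, stiffness: float) -> float:
    """Characteristic decay time τ_out = Rw/K after scope removal [s]."""
    if withdrawal_resistance <= 0 or stiffness <= 0:
        raise ValueError("Rw and K must be positive")
    return withdrawal_resistance / stiffness


def time_constants(params: CircuitParameters) -> TimeConstants:
    return TimeConstants(
        rise=rise_time(params),
        decay=decay_time(params.resistances.withdrawal, params.stiffness),
    )


def insertion_pressure(t, params: CircuitParameters):
    """Pressure during irrigation, P_max(1 − e^(−t/τ)) + P₀ e^(−t/τ) [Pa].

    Accepts scalar or array ``t`` (seconds from the start of the phase).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    p_max = steady_state_pressure(params)
    tau = rise_time(params)
    decay = np.exp(-t / tau)
    out = p_max * (1.0 - decay) + params.initial_pressure * decay
    return out if out.ndim else float(out)


def withdrawal_pressure(t, t_r: float, p_r: float, tau_out: float):
    """Pressure after scope removal at ``t_r``: P_r e^(−(t−t_r)/τ_out) [Pa]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < t_r):
        raise ValueError("time must not precede the removal time")
    if p_r < 0:
        raise ValueError("removal pressure must be nonnegative")
    out = p_r * np.exp(-(t - t_r) / tau_out)
    return out if out.ndim else float(out)


def running_mean_pressure(t, params: CircuitParameters):
    """Running time average (1/t)∫₀ᵗ P dt of the insertion solution [Pa].

    Exact integral: P_max − (τ_in/t)(P_max − P₀)(1 − e^(−t/τ_in)).  The
    transient term is subtracted so that the t → 0 limit is P₀ and the
    t → ∞ limit is P_max.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be positive")
    p_max = steady_state_pressure(params)
    tau = rise_time(params)
    out = p_max - (tau / t) * (p_max - params.initial_pressure) * (
        1.0 - np.exp(-t / tau)
    )
    return out if out.ndim else float(out)


# --- numerical oracle --------------------------------------------------------


def integrate_ode(
    params: CircuitParameters,
    phase: PhaseKind,
    t_span: Sequence[float],
    initial_pressure: Optional[float] = None,
    rtol: float = 1e-9,
    atol: float = 1e-6,
) -> PressureTrace:
    """Numerically integrate the phase ODE; the oracle for the closed forms.

    Parameters
    ----------
    params
        Circuit parameters; ``initial_pressure`` overrides ``params.initial_pressure``.
    phase
        ``"inserted"`` (irrigation source on, resistances Rin/Rout) or
        ``"withdrawn"`` (no source, resistance Rw).
    t_span
        Nondecreasing sample times [s]; the solution is evaluated at each.
    rtol, atol
        Step control for ``scipy.integrate.solve_ivp`` (LSODA); defaults far
        below any model-relevant pressure scale.
    """
    t = np.asarray(t_span, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) < 0):
        raise ValueError("t_span must be a nondecreasing 1-D grid of length >= 2")
    p0 = params.initial_pressure if initial_pressure is None else float(initial_pressure)
    K = params.stiffness
    r = params.resistances

    if phase == "inserted":
        def rhs(_t, p):
            q_in = (params.irrigation_pressure - p) / r.inflow
            q_out = p / r.outflow
            return K * (q_in - q_out)
    elif phase == "withdrawn":
        def rhs(_t, p):
            return -K * p / r.withdrawal
    else:
        raise ValueError(f"unknown phase {phase!r}")

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [p0],
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    pressures = np.clip(sol.y[0], 0.0, None)  # clip solver noise at zero gauge
    labels = np.full(len(t), phase)
    return PressureTrace(times=t, pressures=pressures, phase_labels=labels)


def nondimensionalize(
    trace: PressureTrace, scale_pressure: float, scale_time: float
) -> PressureTrace:
    """Rescale a trace pointwise by (pressure scale, time scale).

    Dividing by (P_irr, τ_in) — or (P_max, τ_in) — collapses curves that share
    a geometry but differ in irrigation pressure onto a single shape.
    """
    if scale_pressure <= 0 or scale_time <= 0:
        raise ValueError("scales must be positive")
    return PressureTrace(
        times=trace.times / scale_time,
        pressures=trace.pressures / scale_pressure,
        phase_labels=trace.phase_labels,
        segments=None,
    )
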