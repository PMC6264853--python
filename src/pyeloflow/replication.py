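"""Pre-built scenario sets replicating published irrigation conditions.

Two scenario families are shipped:

* the representative-device family — one flexible scope, irrigation at 150 or
  200 cm H₂O, and four drainage options (no sheath, 10/12, 12/14, 14/16 Fr
  sheaths), giving eight pressure curves that collapse onto four shapes when
  normalized by irrigation pressure and rise time;

* a 13-curve validation family mirroring two earlier clinical studies: four
  sheath conditions with a flexible scope at 200 cm H₂O (an ex-vivo porcine
  protocol), plus nine semirigid-scope cases crossing three ureteral stone
  locations with three irrigation pressures and a nonzero baseline pressure
  (an in-vivo human protocol).  Device and protocol details the sources do not
  state are shipped as clearly documented synthetic placeholder defaults; the
  curve structure and collapse behaviour do not depend on their exact values.

A stone lodged in the ureter truncates the annular outflow path: the scope is
advanced only as far as the stone, so the ureter segment length equals the
stone's distance from the ureteral orifice (bladder end, increasing
proximally toward the kidney).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dynamics import (
    CircuitParameters,
    insertion_pressure,
    rise_time,
    running_mean_pressure,
    steady_state_pressure,
)
from .hydraulics import (
    AccessSheath,
    Anatomy,
    FluidProperties,
    ResistanceSet,
    Ureteroscope,
    annular_resistance,
    inflow_resistance,
    circular_resistance,
    sheath_from_label,
    stretched_diameter,
    table1_anatomy,
    table1_scope,
    withdrawal_resistance,
    outflow_resistance,
)
from .units import cmH2O_to_Pa, french_to_meters

__all__ = [
    "ScenarioConfig",
    "CollapseReport",
    "fig2_scenarios",
    "rehman_shao_scenarios",
    "stone_path_resistance",
    "collapse_check",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One irrigation scenario: a device set plus operating conditions."""

    label: str
    scope: Ureteroscope
    anatomy: Anatomy
    fluid: FluidProperties
    irrigation_pressure: float  # [Pa]
    initial_pressure: float = 0.0  # [Pa]
    sheath: Optional[AccessSheath] = None
    stone_location: Optional[float] = None  # distance from ureteral orifice [m]

    def __post_init__(self) -> None:
        if self.stone_location is not None:
            if not 0 < self.stone_location <= self.anatomy.ureter_length:
                raise ValueError(
                    "stone location must lie within the ureter "
                    f"(0, {self.anatomy.ureter_length}], got {self.stone_location}"
                )
            if self.sheath is not None:
                raise ValueError("ureteral-stone scenarios do not use a sheath")

    def resistances(self) -> ResistanceSet:
        mu = self.fluid.viscosity
        r_in = inflow_resistance(self.scope, mu)
        if self.stone_location is None:
            r_out = outflow_resistance(self.scope, self.anatomy, self.sheath, mu)
            r_w = withdrawal_resistance(self.anatomy, self.sheath, mu)
        else:
            # stone in the ureter: annular UPJ plus the truncated ureter path
            d_sc = self.scope.shaft_diameter
            d_upj = stretched_diameter(d_sc, self.anatomy.upj_stretch)
            r_out = annular_resistance(
                self.anatomy.upj_length, d_upj, d_sc, mu
            ) + stone_path_resistance(self.stone_location, self.scope, self.anatomy, mu)
            r_w = circular_resistance(
                self.anatomy.upj_length, self.anatomy.upj_diameter, mu
            ) + circular_resistance(
                self.stone_location, self.anatomy.ureter_diameter, mu
            )
        return ResistanceSet(inflow=r_in, outflow=r_out, withdrawal=r_w)

    def circuit_parameters(self) -> CircuitParameters:
        return CircuitParameters(
            resistances=self.resistances(),
            stiffness=self.anatomy.stiffness,
            irrigation_pressure=self.irrigation_pressure,
            initial_pressure=self.initial_pressure,
        )


def fig2_scenarios() -> list[ScenarioConfig]:
    """Eight representative-device scenarios: {no sheath, 10/12, 12/14,
    14/16 Fr} × {150, 200 cm H₂O}, zero initial pressure."""
    scope = table1_scope()
    anatomy = table1_anatomy()
    fluid = FluidProperties()
    scenarios = []
    for sheath_label in (None, "10/12", "12/14", "14/16"):
        sheath = None if sheath_label is None else sheath_from_label(sheath_label)
        for p_irr_cm in (150.0, 200.0):
            name = "no-sheath" if sheath_label is None else sheath_label.replace("/", "-")
            scenarios.append(
                ScenarioConfig(
                    label=f"{name}_{p_irr_cm:.0f}cmH2O",
                    scope=scope,
                    anatomy=anatomy,
                    fluid=fluid,
                    irrigation_pressure=cmH2O_to_Pa(p_irr_cm),
                    sheath=sheath,
                )
            )
    return scenarios


# Placeholder defaults for the semirigid-scope (in-vivo) cases.  The source
# study reports the scope model (an 8/9.8 Fr semirigid) and that three stone
# locations and three irrigation pressures were crossed, but not the exact
# values; these synthetic stand-ins preserve the 3 × 3 structure.
SEMIRIGID_SCOPE = Ureteroscope(
    shaft_diameter=french_to_meters(8.0),
    channel_diameter=french_to_meters(5.0),
    working_length=0.315,
)
SHAO_IRRIGATION_PRESSURES_CMH2O = (200.0, 150.0, 100.0)
SHAO_STONE_LOCATIONS_M = (0.05, 0.125, 0.20)  # distal, mid, proximal
SHAO_BASELINE_PRESSURE_CMH2O = 10.0
REHMAN_SHEATHS = (None, "10/12", "12/14", "14/16")


def rehman_shao_scenarios() -> list[ScenarioConfig]:
    """The 13-curve validation set: 4 flexible-scope sheath conditions at
    200 cm H₂O plus 3 stone locations × 3 pressures for a semirigid scope
    with nonzero baseline pressure."""
    fluid = FluidProperties()
    anatomy = table1_anatomy()
    scenarios = []
    scope = table1_scope()
    for sheath_label in REHMAN_SHEATHS:
        sheath = None if sheath_label is None else sheath_from_label(sheath_label)
        name = "no-sheath" if sheath_label is None else sheath_label.replace("/", "-")
        scenarios.append(
            ScenarioConfig(
                label=f"rehman_{name}",
                scope=scope,
                anatomy=anatomy,
                fluid=fluid,
                irrigation_pressure=cmH2O_to_Pa(200.0),
                sheath=sheath,
            )
        )
    stone_names = ("distal", "mid", "proximal")
    for stone_name, location in zip(stone_names, SHAO_STONE_LOCATIONS_M):
        for p_irr_cm in SHAO_IRRIGATION_PRESSURES_CMH2O:
            scenarios.append(
                ScenarioConfig(
                    label=f"shao_{stone_name}_{p_irr_cm:.0f}cmH2O",
                    scope=SEMIRIGID_SCOPE,
                    anatomy=anatomy,
                    fluid=fluid,
                    irrigation_pressure=cmH2O_to_Pa(p_irr_cm),
                    initial_pressure=cmH2O_to_Pa(SHAO_BASELINE_PRESSURE_CMH2O),
                    stone_location=location,
                )
            )
    return scenarios


def stone_path_resistance(
    stone_location: float,
    scope: Ureteroscope,
    anatomy: Anatomy,
    viscosity: float,
) -> float:
    """Annular resistance of the ureter over the scope's inserted length.

    ``stone_location`` is measured from the ureteral orifice increasing
    proximally; the scope is advanced to the stone, so the annular (stretched
    ureter around scope) segment has exactly that length.  Linear in the
    location; at the full ureter length it equals the no-sheath ureter
    segment of the standard outflow path.
    """
    if not 0 < stone_location <= anatomy.ureter_length:
        raise ValueError(
            f"stone location must be in (0, {anatomy.ureter_length}], "
            f"got {stone_location}"
        )
    d_ur = stretched_diameter(scope.shaft_diameter, anatomy.ureter_stretch)
    return annular_resistance(stone_location, d_ur, scope.shaft_diameter, viscosity)


@dataclass(frozen=True)
class CollapseReport:
    """Normalized curves on a shared normalized-time grid plus a dispersion
    statistic (max pointwise spread across curves)."""

    normalized_times: np.ndarray  # t/τ_in grid
    curves: dict[str, np.ndarray]  # label -> P/P_max on the grid
    dispersion: float

    def distinct_groups(self, tol: float = 1e-12) -> int:
        """Number of equivalence classes of curves at max-pointwise tolerance."""
        reps: list[np.ndarray] = []
        for curve in self.curves.values():
            if not any(np.max(np.abs(curve - r)) <= tol for r in reps):
                reps.append(curve)
        return len(reps)


def collapse_check(
    scenarios: Sequence[ScenarioConfig],
    t_hat_max: float = 6.0,
    n_points: int = 201,
    running_mean: bool = False,
    normalization: str = "max",
) -> CollapseReport:
    """Normalize each scenario's insertion curve onto a shared t̂ = t/τ_in grid.

    With ``normalization="max"`` pressures are divided by the per-curve
    plateau P_max: every zero-baseline scenario then follows 1 − e^(−t̂)
    exactly and collapses to machine precision, while a nonzero initial
    pressure leaves a residual (P₀/P_max) e^(−t̂) and only a near-collapse.
    With ``normalization="irrigation"`` pressures are divided by P_irr
    instead, so curves group by drainage geometry: each sheath option keeps
    its own plateau fraction and the groups stay distinct.  With
    ``running_mean=True`` the running time-averaged curves are normalized
    instead (the grid then starts just above zero).
    """
    if len(scenarios) < 2:
        raise ValueError("collapse check needs at least two scenarios")
    if normalization not in ("max", "irrigation"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if running_mean:
        t_hat = np.linspace(t_hat_max / n_points, t_hat_max, n_points)
    else:
        t_hat = np.linspace(0.0, t_hat_max, n_points)
    curves: dict[str, np.ndarray] = {}
    for sc in scenarios:
        params = sc.circuit_parameters()
        tau = rise_time(params)
        scale = (
            steady_state_pressure(params)
            if normalization == "max"
            else params.irrigation_pressure
        )
        t = t_hat * tau
        p = running_mean_pressure(t, params) if running_mean else insertion_pressure(t, params)
        curves[sc.label] = np.asarray(p, dtype=float) / scale
    stacked = np.vstack(list(curves.values()))
    dispersion = float(np.max(stacked.max(axis=0) - stacked.min(axis=0)))
    return CollapseReport(normalized_times=t_hat, curves=curves, dispersion=dispersion)
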