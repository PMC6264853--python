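"""Hydraulic resistances of the ureteroscopy pipe network.

The irrigation circuit is modelled as a set of conduits in series carrying
quasi-static, laminar, Newtonian (Poiseuille) flow:

* inflow — the scope's circular working channel, ``Rin = 128 μ ℓ_sc / (π d_irr⁴)``;
* outflow — annular gaps around the inserted scope, in series: the short
  ureteropelvic-junction (UPJ) segment plus either the access-sheath lumen or,
  without a sheath, the ureter itself.  An annulus with outer/inner diameters
  (d_o, d_i) behaves like a circular pipe with effective fourth-power diameter
  ``d̃⁴ = d_o⁴ − d_i⁴ − (d_o² − d_i²)² / ln(d_o/d_i)``;
* withdrawal — the same UPJ/sheath (or ureter) path with the scope removed,
  so the conduits revert to circular cross-sections at their nominal diameters.

While the scope is inserted, the soft UPJ and ureter are distended by it; their
effective outer diameters are taken as fixed multiples of the scope diameter
(defaults 1.11 and 1.14).  The nominal relaxed UPJ diameter is backed out of a
Whitaker-test operating point via :func:`whitaker_upj_diameter`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .units import cP_to_PaS, cmH2O_per_ml_to_Pa_per_m3, french_to_meters

__all__ = [
    "FluidProperties",
    "Ureteroscope",
    "AccessSheath",
    "Anatomy",
    "WhitakerMeasurement",
    "ResistanceSet",
    "circular_resistance",
    "annular_effective_d4",
    "annular_resistance",
    "stretched_diameter",
    "inflow_resistance",
    "outflow_resistance",
    "withdrawal_resistance",
    "whitaker_upj_diameter",
    "resistance_set",
    "sheath_from_label",
    "SHEATH_LENGTH_DEFAULT",
]

# Representative access-sheath working length [m]
SHEATH_LENGTH_DEFAULT = 0.35


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class FluidProperties:
    """Irrigant/urine fluid properties.  Saline is ≈ 1 cP."""

    viscosity: float = cP_to_PaS(1.0)  # dynamic viscosity [Pa·s]

    def __post_init__(self) -> None:
        _require_positive(viscosity=self.viscosity)


@dataclass(frozen=True)
class Ureteroscope:
    """Flexible or semirigid ureteroscope, idealized as a uniform cylinder.

    The shaft is treated at its tip diameter, a reasonable approximation for
    the whole shaft of common flexible scopes.
    """

    shaft_diameter: float  # d_sc [m]
    channel_diameter: float  # d_irr, irrigation working channel [m]
    working_length: float  # ℓ_sc [m]

    def __post_init__(self) -> None:
        _require_positive(
            shaft_diameter=self.shaft_diameter,
            channel_diameter=self.channel_diameter,
            working_length=self.working_length,
        )
        if self.channel_diameter >= self.shaft_diameter:
            raise ValueError(
                "working channel diameter must be smaller than the shaft "
                f"diameter ({self.channel_diameter} >= {self.shaft_diameter})"
            )


@dataclass(frozen=True)
class AccessSheath:
    """Ureteral access sheath; ``inner_diameter`` is the lumen the scope and
    the draining irrigant share (a "10/12 Fr" sheath has a 10 Fr lumen)."""

    inner_diameter: float  # d_sh [m]
    length: float = SHEATH_LENGTH_DEFAULT  # ℓ_sh [m]

    def __post_init__(self) -> None:
        _require_positive(inner_diameter=self.inner_diameter, length=self.length)


@dataclass(frozen=True)
class Anatomy:
    """Upper-urinary-tract geometry and renal pelvis stiffness.

    ``upj_diameter`` and ``ureter_diameter`` are the relaxed (nominal) sizes;
    while the scope is inserted their effective outer diameters are
    ``stretch × scope diameter`` (the scope distends the soft tissue).
    """

    upj_diameter: float  # d_upj, relaxed [m]
    upj_length: float  # ℓ_upj [m]
    ureter_diameter: float  # d_ur, relaxed [m]
    ureter_length: float  # ℓ_ur [m]
    stiffness: float  # K, renal pelvis ΔP = K ΔV [Pa/m³]
    upj_stretch: float = 1.11  # distended UPJ diameter / scope diameter
    ureter_stretch: float = 1.14  # distended ureter diameter / scope diameter

    def __post_init__(self) -> None:
        _require_positive(
            upj_diameter=self.upj_diameter,
            upj_length=self.upj_length,
            ureter_diameter=self.ureter_diameter,
            ureter_length=self.ureter_length,
            stiffness=self.stiffness,
        )
        if self.upj_stretch < 1 or self.ureter_stretch < 1:
            raise ValueError("stretch factors must be >= 1")


@dataclass(frozen=True)
class WhitakerMeasurement:
    """A Whitaker-test operating point: pressure drop across the upper tract
    at a known perfusion flow rate."""

    pressure_drop: float  # ΔP [Pa]
    flow_rate: float  # Q [m³/s]

    def __post_init__(self) -> None:
        _require_positive(pressure_drop=self.pressure_drop, flow_rate=self.flow_rate)


@dataclass(frozen=True)
class ResistanceSet:
    """The three hydraulic resistances of the circuit [Pa·s/m³]."""

    inflow: float  # Rin, scope channel
    outflow: float  # Rout, annular path around the inserted scope
    withdrawal: float  # Rw, circular path with the scope removed

    def __post_init__(self) -> None:
        _require_positive(
            inflow=self.inflow, outflow=self.outflow, withdrawal=self.withdrawal
        )


# --- elementary resistances --------------------------------------------------


def circular_resistance(length: float, diameter: float, viscosity: float) -> float:
    """Poiseuille resistance of a circular tube, ``128 μ ℓ / (π d⁴)`` [Pa·s/m³]."""
    _require_positive(length=length, diameter=diameter, viscosity=viscosity)
    return 128.0 * viscosity * length / (math.pi * diameter**4)


def annular_effective_d4(d_outer: float, d_inner: float) -> float:
    """Effective fourth-power diameter of an annular gap [m⁴].

    ``d̃⁴ = d_o⁴ − d_i⁴ − (d_o² − d_i²)² / ln(d_o/d_i)``.  Positive and
    strictly increasing in ``d_outer`` for any ``d_outer > d_inner > 0``; the
    circular limit ``d_o⁴`` is recovered as ``d_inner → 0``.
    """
    if d_inner < 0 or d_outer <= d_inner:
        raise ValueError(
            f"need d_outer > d_inner >= 0, got d_outer={d_outer}, d_inner={d_inner}"
        )
    if d_inner == 0.0:
        return d_outer**4
    return (
        d_outer**4
        - d_inner**4
        - (d_outer**2 - d_inner**2) ** 2 / math.log(d_outer / d_inner)
    )


def annular_resistance(
    length: float, d_outer: float, d_inner: float, viscosity: float
) -> float:
    """Poiseuille resistance of an annular conduit [Pa·s/m³]."""
    _require_positive(length=length, viscosity=viscosity)
    return 128.0 * viscosity * length / (math.pi * annular_effective_d4(d_outer, d_inner))


def stretched_diameter(scope_diameter: float, stretch: float) -> float:
    """Distended outer diameter of a soft conduit around the inserted scope."""
    _require_positive(scope_diameter=scope_diameter)
    if stretch < 1:
        raise ValueError(f"stretch factor must be >= 1, got {stretch}")
    return scope_diameter * stretch


# --- circuit resistances -----------------------------------------------------


def inflow_resistance(scope: Ureteroscope, viscosity: float) -> float:
    """Rin: the scope's irrigation channel."""
    return circular_resistance(scope.working_length, scope.channel_diameter, viscosity)


def outflow_resistance(
    scope: Ureteroscope,
    anatomy: Anatomy,
    sheath: Optional[AccessSheath],
    viscosity: float,
) -> float:
    """Rout: annular UPJ segment plus the annular sheath (or ureter) segment.

    With the scope inserted, the UPJ and ureter outer walls sit at their
    stretched diameters; the sheath lumen is rigid.  Raises ``ValueError`` if
    any outer diameter does not clear the scope shaft.
    """
    d_sc = scope.shaft_diameter
    d_upj = stretched_diameter(d_sc, anatomy.upj_stretch)
    if d_upj <= d_sc:
        raise ValueError("stretched UPJ diameter does not clear the scope shaft")
    r_upj = annular_resistance(anatomy.upj_length, d_upj, d_sc, viscosity)
    if sheath is not None:
        if sheath.inner_diameter <= d_sc:
            raise ValueError(
                "sheath lumen must be wider than the scope shaft "
                f"({sheath.inner_diameter} <= {d_sc})"
            )
        r_distal = annular_resistance(sheath.length, sheath.inner_diameter, d_sc, viscosity)
    else:
        d_ur = stretched_diameter(d_sc, anatomy.ureter_stretch)
        r_distal = annular_resistance(anatomy.ureter_length, d_ur, d_sc, viscosity)
    return r_upj + r_distal


def withdrawal_resistance(
    anatomy: Anatomy, sheath: Optional[AccessSheath], viscosity: float
) -> float:
    """Rw: the outflow path with the scope removed — circular conduits in
    series at nominal (non-distended) diameters."""
    r_upj = circular_resistance(anatomy.upj_length, anatomy.upj_diameter, viscosity)
    if sheath is not None:
        r_distal = circular_resistance(sheath.length, sheath.inner_diameter, viscosity)
    else:
        r_distal = circular_resistance(
            anatomy.ureter_length, anatomy.ureter_diameter, viscosity
        )
    return r_upj + r_distal


def whitaker_upj_diameter(
    measurement: WhitakerMeasurement, upj_length: float, viscosity: float
) -> float:
    """Nominal UPJ diameter from a Whitaker-test operating point [m].

    Inverts Poiseuille's law ``ΔP = R Q`` with ``R = 128 μ ℓ / (π d⁴)``:
    ``d = (128 μ ℓ Q / (π ΔP))^(1/4)``.  Exact inverse of
    :func:`circular_resistance` composed with ``ΔP = R Q``.
    """
    _require_positive(upj_length=upj_length, viscosity=viscosity)
    return (
        128.0
        * viscosity
        * upj_length
        * measurement.flow_rate
        / (math.pi * measurement.pressure_drop)
    ) ** 0.25


def resistance_set(
    scope: Ureteroscope,
    anatomy: Anatomy,
    sheath: Optional[AccessSheath],
    fluid: FluidProperties,
) -> ResistanceSet:
    """All three circuit resistances for one device/anatomy configuration."""
    mu = fluid.viscosity
    return ResistanceSet(
        inflow=inflow_resistance(scope, mu),
        outflow=outflow_resistance(scope, anatomy, sheath, mu),
        withdrawal=withdrawal_resistance(anatomy, sheath, mu),
    )


def sheath_from_label(label: str, length: float = SHEATH_LENGTH_DEFAULT) -> AccessSheath:
    """Build an :class:`AccessSheath` from a clinical size label.

    ``"10/12"`` (or ``"10/12 Fr"``) means a 10 Fr inner lumen and 12 Fr outer
    diameter; the lumen governs the flow.  A bare ``"10"`` is taken as the
    lumen size.
    """
    text = label.strip().lower().removesuffix("fr").strip()
    inner = text.split("/")[0]
    try:
        inner_fr = float(inner)
    except ValueError as exc:
        raise ValueError(f"cannot parse sheath label {label!r}") from exc
    return AccessSheath(inner_diameter=french_to_meters(inner_fr), length=length)


def table1_scope() -> Ureteroscope:
    """The representative flexible scope (Karl Storz Flex-X2 dimensions)."""
    return Ureteroscope(
        shaft_diameter=french_to_meters(7.5),
        channel_diameter=french_to_meters(3.6),
        working_length=0.67,
    )


def table1_anatomy(stiffness_cmH2O_per_ml: float = 0.4) -> Anatomy:
    """Representative upper-tract anatomy and renal pelvis stiffness."""
    return Anatomy(
        upj_diameter=french_to_meters(1.3),
        upj_length=0.005,
        ureter_diameter=french_to_meters(8.5),
        ureter_length=0.25,
        stiffness=cmH2O_per_ml_to_Pa_per_m3(stiffness_cmH2O_per_ml),
    )
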