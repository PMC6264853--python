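"""Boundary unit conversions.

All internal computation in this package is SI (m, Pa, Pa·s, m³/s, Pa/m³, s).
Clinical units — French gauge, cm H₂O, centipoise, mL/min — are accepted and
emitted only at the boundaries (configs, CLI flags, CSV exports, summaries).

Conventions used throughout urology:

* French gauge: 3 Fr = 1 mm of diameter.
* 1 cm H₂O = 98.1 Pa.
* 1 cP = 10⁻³ Pa·s (saline is ≈ 1 cP).
* Renal pelvis stiffness is quoted in cm H₂O/mL; 1 cm H₂O/mL = 9.81×10⁷ Pa/m³.
"""

from __future__ import annotations

import re

PA_PER_CMH2O = 98.1
M_PER_FR = 1.0e-3 / 3.0  # 3 Fr = 1 mm
PAS_PER_CP = 1.0e-3
M3_PER_ML = 1.0e-6
PA_PER_M3_PER_CMH2O_PER_ML = PA_PER_CMH2O / M3_PER_ML  # 9.81e7


def french_to_meters(size: float) -> float:
    """Convert a French-gauge diameter to meters (3 Fr = 1 mm)."""
    if size < 0:
        raise ValueError(f"French size must be nonnegative, got {size}")
    return size * M_PER_FR


def meters_to_french(d: float) -> float:
    """Exact inverse of :func:`french_to_meters`."""
    if d < 0:
        raise ValueError(f"diameter must be nonnegative, got {d}")
    return d / M_PER_FR


def cmH2O_to_Pa(p: float) -> float:
    """Convert a pressure in cm H₂O to Pa (1 cm H₂O = 98.1 Pa)."""
    return p * PA_PER_CMH2O


def Pa_to_cmH2O(p: float) -> float:
    return p / PA_PER_CMH2O


def cP_to_PaS(mu: float) -> float:
    """Convert dynamic viscosity in centipoise to Pa·s."""
    return mu * PAS_PER_CP


def ml_per_min_to_m3_per_s(q: float) -> float:
    return q * M3_PER_ML / 60.0


def ml_per_s_to_m3_per_s(q: float) -> float:
    return q * M3_PER_ML


def cmH2O_per_ml_to_Pa_per_m3(k: float) -> float:
    """Convert a compliance stiffness in cm H₂O/mL to Pa/m³ (factor 9.81×10⁷)."""
    return k * PA_PER_M3_PER_CMH2O_PER_ML


# --- quantity-string parsing for configs and CLI flags -----------------------

# unit token -> (dimension, factor to SI)
_UNIT_TABLE: dict[str, tuple[str, float]] = {
    "m": ("length", 1.0),
    "cm": ("length", 1.0e-2),
    "mm": ("length", 1.0e-3),
    "fr": ("length", M_PER_FR),
    "f": ("length", M_PER_FR),
    "pa": ("pressure", 1.0),
    "kpa": ("pressure", 1.0e3),
    "cmh2o": ("pressure", PA_PER_CMH2O),
    "pa.s": ("viscosity", 1.0),
    "pa*s": ("viscosity", 1.0),
    "cp": ("viscosity", PAS_PER_CP),
    "m3/s": ("flow", 1.0),
    "ml/s": ("flow", M3_PER_ML),
    "ml/min": ("flow", M3_PER_ML / 60.0),
    "l/min": ("flow", 1.0e-3 / 60.0),
    "s": ("time", 1.0),
    "sec": ("time", 1.0),
    "min": ("time", 60.0),
    "h": ("time", 3600.0),
    "pa/m3": ("stiffness", 1.0),
    "cmh2o/ml": ("stiffness", PA_PER_M3_PER_CMH2O_PER_ML),
    "": ("dimensionless", 1.0),
}

_QUANTITY_RE = re.compile(r"^\s*([-+]?[\d._]+(?:[eE][-+]?\d+)?)\s*([^\s]*)\s*$")


def parse_quantity(text: str | float | int, expect: str | None = None) -> float:
    """Parse a quantity string like ``"7.5 Fr"`` or ``"150 cmH2O"`` into SI.

    Bare numbers are accepted only when ``expect`` is ``None`` or
    ``"dimensionless"``; quantities with a dimension must state their unit so
    that configs never rely on implicit units.

    Parameters
    ----------
    text
        The quantity string (or a bare number for dimensionless values).
    expect
        Optional dimension name (``"length"``, ``"pressure"``, ``"viscosity"``,
        ``"flow"``, ``"time"``, ``"stiffness"``, ``"dimensionless"``); a
        mismatch raises ``ValueError``.
    """
    if isinstance(text, (int, float)):
        if expect not in (None, "dimensionless"):
            raise ValueError(
                f"bare number {text!r} given where a quantity with units "
                f"({expect}) is required"
            )
        return float(text)
    m = _QUANTITY_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse quantity {text!r}")
    value = float(m.group(1))
    unit = m.group(2).lower().replace("·", ".").replace("h_2o", "h2o")
    if unit not in _UNIT_TABLE:
        raise ValueError(f"unknown unit {m.group(2)!r} in {text!r}")
    dim, factor = _UNIT_TABLE[unit]
    if expect is not None and dim != expect:
        raise ValueError(f"expected a {expect} quantity, got {text!r} ({dim})")
    return value * factor
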