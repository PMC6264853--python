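"""Config loading, fixture generation and run orchestration.

Configs are YAML with nested sections mirroring the parameter groups
(irrigation, ureteroscope, sheath, physiology, fluid, protocol, simulation).
Every dimensional field is a quantity *string* with an explicit unit
(``"7.5 Fr"``, ``"150 cmH2O"``, ``"0.4 cmH2O/mL"``); bare numbers are only
accepted for dimensionless fields.  Unknown keys are rejected so typos never
silently fall back to defaults.  All quantities are converted to SI on load.

Example::

    label: demo
    irrigation: {pressure: "150 cmH2O", initial_pressure: "0 cmH2O"}
    ureteroscope:
      shaft_diameter: "7.5 Fr"
      channel_diameter: "3.6 Fr"
      working_length: "67 cm"
    sheath: {inner_diameter: "10 Fr", length: "35 cm"}   # omit for no sheath
    physiology:
      upj_diameter: "1.3 Fr"
      upj_length: "0.5 cm"
      ureter_diameter: "8.5 Fr"
      ureter_length: "25 cm"
      stiffness: "0.4 cmH2O/mL"
      upj_stretch: 1.11
      ureter_stretch: 1.14
    protocol: {name: option4}      # or phases: [[inserted, "2 min"], ...]
    simulation: {sampling_interval: "1 s", threshold: "40 cmH2O"}
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .dynamics import CircuitParameters, PressureTrace, time_constants
from .hydraulics import (
    AccessSheath,
    Anatomy,
    FluidProperties,
    Ureteroscope,
)
from .protocol import (
    Phase,
    Protocol,
    peak_pressure,
    simulate_protocol,
    table2_protocols,
    time_above_threshold,
    time_averaged_pressure,
)
from .replication import ScenarioConfig, fig2_scenarios, rehman_shao_scenarios
from .units import Pa_to_cmH2O, cmH2O_to_Pa, parse_quantity

__all__ = ["RunConfig", "ConfigError", "load_config", "emit_config", "run", "generate_fixtures"]

logger = logging.getLogger("pyeloflow")


class ConfigError(ValueError):
    """A configuration problem, with the offending field in the message."""


@dataclass(frozen=True)
class RunConfig:
    """A fully validated, SI-converted simulation run."""

    label: str
    scope: Ureteroscope
    anatomy: Anatomy
    fluid: FluidProperties
    irrigation_pressure: float  # [Pa]
    initial_pressure: float  # [Pa]
    protocol: Protocol
    sheath: Optional[AccessSheath] = None
    stone_location: Optional[float] = None  # [m]
    sampling_interval: float = 1.0  # [s]
    threshold: float = cmH2O_to_Pa(40.0)  # reporting threshold [Pa]
    plot: bool = False
    seed: Optional[int] = None  # reserved; the model is deterministic

    def scenario(self) -> ScenarioConfig:
        return ScenarioConfig(
            label=self.label,
            scope=self.scope,
            anatomy=self.anatomy,
            fluid=self.fluid,
            irrigation_pressure=self.irrigation_pressure,
            initial_pressure=self.initial_pressure,
            sheath=self.sheath,
            stone_location=self.stone_location,
        )

    def circuit_parameters(self) -> CircuitParameters:
        return self.scenario().circuit_parameters()


def _section(raw: Mapping[str, Any], name: str, allowed: set[str], required: bool = True) -> dict:
    sec = raw.get(name)
    if sec is None:
        if required:
            raise ConfigError(f"missing config section {name!r}")
        return {}
    if not isinstance(sec, Mapping):
        raise ConfigError(f"config section {name!r} must be a mapping")
    unknown = set(sec) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    return dict(sec)


def _quantity(sec: Mapping[str, Any], section: str, key: str, dim: str, default=None) -> float:
    if key not in sec:
        if default is not None:
            return default
        raise ConfigError(f"missing field {section}.{key}")
    try:
        return parse_quantity(sec[key], expect=dim)
    except ValueError as exc:
        raise ConfigError(f"field {section}.{key}: {exc}") from exc


def _parse_protocol(raw: Mapping[str, Any]) -> Protocol:
    sec = _section(raw, "protocol", {"name", "phases"})
    if ("name" in sec) == ("phases" in sec):
        raise ConfigError("protocol: give exactly one of 'name' or 'phases'")
    if "name" in sec:
        named = {p.name: p for p in table2_protocols()}
        name = str(sec["name"])
        if name not in named:
            raise ConfigError(
                f"protocol.name: unknown protocol {name!r}; options are {sorted(named)}"
            )
        return named[name]
    phases = []
    for i, item in enumerate(sec["phases"]):
        try:
            kind, duration = item
            phases.append(Phase(str(kind), parse_quantity(duration, expect="time")))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"protocol.phases[{i}]: {exc}") from exc
    try:
        return Protocol(tuple(phases), name=str(raw.get("label", "custom")))
    except ValueError as exc:
        raise ConfigError(f"protocol.phases: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, converting everything to SI."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config {path} is not a mapping")
    top_allowed = {
        "label", "irrigation", "ureteroscope", "sheath", "physiology",
        "fluid", "stone_location", "protocol", "simulation",
    }
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    irr = _section(raw, "irrigation", {"pressure", "initial_pressure"})
    sc = _section(raw, "ureteroscope", {"shaft_diameter", "channel_diameter", "working_length"})
    phys = _section(
        raw,
        "physiology",
        {"upj_diameter", "upj_length", "ureter_diameter", "ureter_length",
         "stiffness", "upj_stretch", "ureter_stretch"},
    )
    fl = _section(raw, "fluid", {"viscosity"}, required=False)
    sh = _section(raw, "sheath", {"inner_diameter", "length"}, required=False)
    sim = _section(
        raw, "simulation",
        {"sampling_interval", "threshold", "plot", "seed"},
        required=False,
    )

    try:
        scope = Ureteroscope(
            shaft_diameter=_quantity(sc, "ureteroscope", "shaft_diameter", "length"),
            channel_diameter=_quantity(sc, "ureteroscope", "channel_diameter", "length"),
            working_length=_quantity(sc, "ureteroscope", "working_length", "length"),
        )
        anatomy = Anatomy(
            upj_diameter=_quantity(phys, "physiology", "upj_diameter", "length"),
            upj_length=_quantity(phys, "physiology", "upj_length", "length"),
            ureter_diameter=_quantity(phys, "physiology", "ureter_diameter", "length"),
            ureter_length=_quantity(phys, "physiology", "ureter_length", "length"),
            stiffness=_quantity(phys, "physiology", "stiffness", "stiffness"),
            upj_stretch=float(phys.get("upj_stretch", 1.11)),
            ureter_stretch=float(phys.get("ureter_stretch", 1.14)),
        )
        fluid = FluidProperties(
            viscosity=_quantity(fl, "fluid", "viscosity", "viscosity", default=1e-3)
        )
        sheath = None
        if sh:
            sheath = AccessSheath(
                inner_diameter=_quantity(sh, "sheath", "inner_diameter", "length"),
                length=_quantity(sh, "sheath", "length", "length"),
            )
            if sheath.inner_diameter <= scope.shaft_diameter:
                raise ConfigError(
                    "sheath.inner_diameter must exceed ureteroscope.shaft_diameter"
                )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    stone_location = None
    if raw.get("stone_location") is not None:
        stone_location = parse_quantity(raw["stone_location"], expect="length")

    config = RunConfig(
        label=str(raw.get("label", path.stem)),
        scope=scope,
        anatomy=anatomy,
        fluid=fluid,
        irrigation_pressure=_quantity(irr, "irrigation", "pressure", "pressure"),
        initial_pressure=_quantity(irr, "irrigation", "initial_pressure", "pressure", default=0.0),
        protocol=_parse_protocol(raw),
        sheath=sheath,
        stone_location=stone_location,
        sampling_interval=_quantity(sim, "simulation", "sampling_interval", "time", default=1.0),
        threshold=_quantity(sim, "simulation", "threshold", "pressure", default=cmH2O_to_Pa(40.0)),
        plot=bool(sim.get("plot", False)),
        seed=None if sim.get("seed") is None else int(sim["seed"]),
    )
    # surface invalid device/anatomy combinations (e.g. stone outside ureter,
    # stretched diameter not clearing the scope) at load time
    try:
        config.circuit_parameters()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return config


def _si(value: float, unit: str) -> str:
    return f"{value!r} {unit}"


def emit_config(config: RunConfig) -> dict:
    """RunConfig → config mapping (SI quantity strings; exact round-trip)."""
    doc: dict[str, Any] = {
        "label": config.label,
        "irrigation": {
            "pressure": _si(config.irrigation_pressure, "Pa"),
            "initial_pressure": _si(config.initial_pressure, "Pa"),
        },
        "ureteroscope": {
            "shaft_diameter": _si(config.scope.shaft_diameter, "m"),
            "channel_diameter": _si(config.scope.channel_diameter, "m"),
            "working_length": _si(config.scope.working_length, "m"),
        },
        "physiology": {
            "upj_diameter": _si(config.anatomy.upj_diameter, "m"),
            "upj_length": _si(config.anatomy.upj_length, "m"),
            "ureter_diameter": _si(config.anatomy.ureter_diameter, "m"),
            "ureter_length": _si(config.anatomy.ureter_length, "m"),
            "stiffness": _si(config.anatomy.stiffness, "Pa/m3"),
            "upj_stretch": config.anatomy.upj_stretch,
            "ureter_stretch": config.anatomy.ureter_stretch,
        },
        "fluid": {"viscosity": _si(config.fluid.viscosity, "Pa.s")},
        "protocol": (
            {"name": config.protocol.name}
            if config.protocol.name in {p.name for p in table2_protocols()}
            else {"phases": [[p.kind, _si(p.duration, "s")] for p in config.protocol.phases]}
        ),
        "simulation": {
            "sampling_interval": _si(config.sampling_interval, "s"),
            "threshold": _si(config.threshold, "Pa"),
            "plot": config.plot,
        },
    }
    if config.sheath is not None:
        doc["sheath"] = {
            "inner_diameter": _si(config.sheath.inner_diameter, "m"),
            "length": _si(config.sheath.length, "m"),
        }
    if config.stone_location is not None:
        doc["stone_location"] = _si(config.stone_location, "m")
    if config.seed is not None:
        doc["simulation"]["seed"] = config.seed
    return doc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(emit_config(config), sort_keys=False))


def _log_parameters(config: RunConfig, params: CircuitParameters) -> None:
    r = params.resistances
    logger.info("run %s: effective parameters (SI / clinical)", config.label)
    logger.info(
        "  P_irr = %.6g Pa (%.4g cmH2O); P_0 = %.6g Pa (%.4g cmH2O)",
        params.irrigation_pressure, Pa_to_cmH2O(params.irrigation_pressure),
        params.initial_pressure, Pa_to_cmH2O(params.initial_pressure),
    )
    logger.info(
        "  Rin = %.6g, Rout = %.6g, Rw = %.6g Pa.s/m3; K = %.6g Pa/m3 (%.4g cmH2O/mL)",
        r.inflow, r.outflow, r.withdrawal,
        params.stiffness, params.stiffness * 1e-6 / 98.1,
    )


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute a run: simulate, export CSV + summary JSON, optional plot.

    Returns the summary dict.  Identical configs produce byte-identical CSVs
    (the model is deterministic).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.circuit_parameters()
    _log_parameters(config, params)

    trace = simulate_protocol(config.protocol, params, config.sampling_interval)
    taus = time_constants(params)
    p_max = params.irrigation_pressure / (
        1.0 + params.resistances.inflow / params.resistances.outflow
    )
    summary = {
        "label": config.label,
        "protocol": config.protocol.name,
        "peak_pressure_cmH2O": Pa_to_cmH2O(peak_pressure(trace)),
        "plateau_pressure_cmH2O": Pa_to_cmH2O(p_max),
        "tau_in_s": taus.rise,
        "tau_out_s": taus.decay,
        "mean_pressure_cmH2O": Pa_to_cmH2O(time_averaged_pressure(trace, "full")),
        "threshold_cmH2O": Pa_to_cmH2O(config.threshold),
        "time_above_threshold_s": time_above_threshold(trace, config.threshold),
        "total_time_s": config.protocol.total_time,
        "cumulative_insertion_time_s": config.protocol.insertion_time,
    }
    trace_path = outdir / f"{config.label}_trace.csv"
    trace.to_csv(trace_path)
    (outdir / f"{config.label}_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    if config.plot:
        _plot_trace(trace, config, outdir / f"{config.label}.png")
    logger.info(
        "  wrote %s (peak %.4g cmH2O, mean %.4g cmH2O)",
        trace_path, summary["peak_pressure_cmH2O"], summary["mean_pressure_cmH2O"],
    )
    return summary


def _plot_trace(trace: PressureTrace, config: RunConfig, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trace.times / 60.0, Pa_to_cmH2O(trace.pressures), lw=1.5)
    ax.axhline(Pa_to_cmH2O(config.threshold), ls="--", c="crimson", lw=1,
               label=f"threshold {Pa_to_cmH2O(config.threshold):.0f} cmH2O")
    ax.set_xlabel("time [min]")
    ax.set_ylabel("renal pelvis pressure [cm H$_2$O]")
    ax.set_title(config.label)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _scenario_run_config(scenario: ScenarioConfig, protocol: Protocol) -> RunConfig:
    return RunConfig(
        label=scenario.label,
        scope=scenario.scope,
        anatomy=scenario.anatomy,
        fluid=scenario.fluid,
        irrigation_pressure=scenario.irrigation_pressure,
        initial_pressure=scenario.initial_pressure,
        protocol=protocol,
        sheath=scenario.sheath,
        stone_location=scenario.stone_location,
    )


def generate_fixtures(target_dir: str | Path) -> list[Path]:
    """Emit ready-to-run configs for every shipped scenario.

    Writes the eight sheath × irrigation-pressure scenarios, the 13-curve
    validation set, and the four reference withdrawal schedules (with a 10/12
    Fr sheath at 150 cm H₂O), each as a YAML config that passes
    :func:`load_config`.
    """
    target = Path(target_dir)
    written: list[Path] = []
    single = table2_protocols()[0]  # one 20-min insertion

    for sub, scenarios in (
        ("fig2", fig2_scenarios()),
        ("fig3", rehman_shao_scenarios()),
    ):
        d = target / sub
        d.mkdir(parents=True, exist_ok=True)
        for sc in scenarios:
            path = d / f"{sc.label}.yaml"
            save_config(_scenario_run_config(sc, single), path)
            written.append(path)

    d = target / "protocols"
    d.mkdir(parents=True, exist_ok=True)
    base = [s for s in fig2_scenarios() if s.label == "10-12_150cmH2O"][0]
    for protocol in table2_protocols():
        cfg = dataclasses.replace(
            _scenario_run_config(base, protocol), label=f"sweep_{protocol.name}"
        )
        path = d / f"{protocol.name}.yaml"
        save_config(cfg, path)
        written.append(path)
    return written
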