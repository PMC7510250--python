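"""Run configuration: schema, validation, canonical fixtures, result writers.

Configurations are YAML with explicit unit suffixes on every physical field
(``*_cm``, ``*_mmhg``, ``*_s`` ...), validated by pydantic. Validation is not
fail-fast: :func:`validate_config` reports the complete list of violations.

A bundled generator emits the five canonical scenario configurations with
all the circuit constants (130 cm arms, 0.04/0.08/0.5 cm diameters, blood
rho/eta, the 100 +- 20 mmHg / 1 s inlet, the 30 cm pumped trunk between 10
and 40 cm, 0.52 cm balls, 0.016/0.2 cm gaps, the dual 1e-2 / 2e-4 s time
steps) plus the calibrated defaults, which are flagged as such in comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _pkg_version
from .circuit import (GRAVITY_M_S2, Circuit, FluidProperties, InletLaw,
                      PorousInterface, VesselSegment, canonical_circuit,
                      canonical_probes)
from .errors import ConfigurationError
from .forcing import CANONICAL_DISPLACEMENT_CM, ForcingSchedule, WallMotionLaw
from .scenarios import SCENARIOS, ScenarioResult, compare_scenarios
from .solver import SolverConfig
from .valves import (SEAT_LEAK_RESISTANCE_REF_MMHG_S_ML, BallValveSpec,
                     configure_incompetence)


class FluidSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    density_kg_m3: float = Field(1060.0, gt=0)
    viscosity_pa_s: float = Field(0.0035, gt=0)


class SegmentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    length_cm: float = Field(gt=0)
    diameter_cm: float = Field(gt=0)
    elevation_drop_cm: float = 0.0
    wall: Literal["rigid", "prescribed-motion"] = "rigid"
    role: Literal["aorta", "artery", "vein", "calf"] = "vein"
    resistance_mmhg_s_ml: Optional[float] = Field(None, ge=0)


class PorousSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    resistance_mmhg_s_ml: float = Field(gt=0)


class InletSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean_mmhg: float = 100.0
    amplitude_mmhg: float = Field(20.0, ge=0)
    period_s: float = Field(1.0, gt=0)


class WallMotionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    displacement_amplitude_cm: float = Field(CANONICAL_DISPLACEMENT_CM, ge=0)
    z0_cm: float = 10.0
    length_cm: float = Field(30.0, gt=0)
    period_s: float = Field(1.0, gt=0)


class ValveSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ball_diameter_cm: float = Field(0.52, gt=0)
    seat_diameter_cm: float = Field(0.50, gt=0)
    travel_max_cm: float = Field(0.5, gt=0)
    min_gap_cm: float = Field(0.016, gt=0)
    residual_area_fraction: Optional[float] = Field(None, gt=0, le=1)
    relaxation_time_s: float = Field(5e-3, gt=0)
    dynamics: Literal["relaxation", "inertial"] = "relaxation"
    seat_leak_resistance_ref_mmhg_s_ml: float = Field(
        SEAT_LEAK_RESISTANCE_REF_MMHG_S_ML, gt=0)


class ValvesSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    distal: ValveSection = ValveSection()
    proximal: ValveSection = ValveSection()


class SolverSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dt_slow_s: float = Field(1e-2, gt=0)
    dt_fast_s: float = Field(2e-4, gt=0)
    total_cycles: int = Field(10, ge=2)
    dx_cm: float = Field(1.0, gt=0)
    scheme: Literal["semi-implicit", "explicit"] = "semi-implicit"
    seed: int = 0
    cadence_s: Optional[float] = Field(None, gt=0)


class OutputSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    directory: Optional[str] = None


class RunConfig(BaseModel):
    """Complete, validated description of one simulation run."""

    model_config = ConfigDict(extra="forbid")

    scenario: Literal["clinostatism", "orthostatism", "walking_healthy",
                      "walking_severe", "walking_partial"]
    gravity_m_s2: float = Field(GRAVITY_M_S2, ge=0)
    outlet_pressure_mmhg: float = 0.0
    fluid: FluidSection = FluidSection()
    segments: list[SegmentSection]
    porous_interface: PorousSection
    inlet: InletSection = InletSection()
    wall_motion: WallMotionSection = WallMotionSection()
    valves: ValvesSection = ValvesSection()
    solver: SolverSection = SolverSection()
    output: OutputSection = OutputSection()

    def cross_field_violations(self) -> list[str]:
        """Consistency checks beyond per-field bounds (complete list)."""
        v: list[str] = []
        if self.inlet.mean_mmhg - self.inlet.amplitude_mmhg < 0:
            v.append("inlet: mean_mmhg - amplitude_mmhg must be >= 0")
        if self.solver.dt_fast_s > self.solver.dt_slow_s:
            v.append("solver: dt_fast_s must be <= dt_slow_s (solver contract)")
        if self.wall_motion.enabled and \
                abs(self.wall_motion.period_s - self.inlet.period_s) > 1e-12:
            v.append("wall_motion: period_s must equal the reporting cycle length")
        for s in self.segments:
            if abs(s.elevation_drop_cm) > s.length_cm * (1 + 1e-12):
                v.append(f"segments[{s.name}]: |elevation_drop_cm| exceeds length_cm")
        for side in ("distal", "proximal"):
            vs: ValveSection = getattr(self.valves, side)
            if vs.ball_diameter_cm <= vs.seat_diameter_cm:
                v.append(f"valves.{side}: ball_diameter_cm must exceed seat_diameter_cm")
            if not (0 < vs.min_gap_cm < vs.travel_max_cm):
                v.append(f"valves.{side}: need 0 < min_gap_cm < travel_max_cm")
        scen = SCENARIOS[self.scenario]
        if scen.wall_motion_on != self.wall_motion.enabled:
            v.append(f"scenario {self.scenario}: wall_motion.enabled must be "
                     f"{scen.wall_motion_on}")
        if scen.gravity_on != (self.gravity_m_s2 > 0):
            v.append(f"scenario {self.scenario}: gravity must be "
                     f"{'on' if scen.gravity_on else 'off'}")
        return v


# -- build runtime objects from a config ----------------------------------


def build_circuit(cfg: RunConfig) -> Circuit:
    segs = tuple(
        VesselSegment(s.name, s.length_cm, s.diameter_cm, s.elevation_drop_cm,
                      s.wall, s.role, s.resistance_mmhg_s_ml)
        for s in cfg.segments)
    porous_after = max(i for i, s in enumerate(segs) if s.role in ("aorta", "artery"))
    return Circuit(
        fluid=FluidProperties(cfg.fluid.density_kg_m3, cfg.fluid.viscosity_pa_s),
        segments=segs,
        porous_interface=PorousInterface(cfg.porous_interface.resistance_mmhg_s_ml),
        porous_after=porous_after,
        inlet=InletLaw(cfg.inlet.mean_mmhg, cfg.inlet.amplitude_mmhg, cfg.inlet.period_s),
        outlet_pressure_mmhg=cfg.outlet_pressure_mmhg,
        gravity_m_s2=cfg.gravity_m_s2,
        probes=canonical_probes(),
    )


def build_forcing(cfg: RunConfig, circuit: Circuit) -> ForcingSchedule:
    wall = None
    if cfg.wall_motion.enabled:
        wall = WallMotionLaw(cfg.wall_motion.displacement_amplitude_cm,
                             cfg.wall_motion.z0_cm, cfg.wall_motion.length_cm,
                             cfg.wall_motion.period_s)
    return ForcingSchedule(inlet=circuit.inlet, wall_motion=wall)


def build_valves(cfg: RunConfig) -> tuple[BallValveSpec, BallValveSpec]:
    out = []
    for side in ("distal", "proximal"):
        s: ValveSection = getattr(cfg.valves, side)
        out.append(BallValveSpec(
            ball_diameter_cm=s.ball_diameter_cm, seat_diameter_cm=s.seat_diameter_cm,
            travel_max_cm=s.travel_max_cm, min_gap_cm=s.min_gap_cm,
            residual_area_fraction=s.residual_area_fraction,
            relaxation_time_s=s.relaxation_time_s, dynamics=s.dynamics,
            seat_leak_resistance_ref_mmhg_s_ml=s.seat_leak_resistance_ref_mmhg_s_ml))
    return (out[0], out[1])


def build_solver_config(cfg: RunConfig) -> SolverConfig:
    return SolverConfig(dt_slow_s=cfg.solver.dt_slow_s, dt_fast_s=cfg.solver.dt_fast_s,
                        total_cycles=cfg.solver.total_cycles, dx_cm=cfg.solver.dx_cm,
                        scheme=cfg.solver.scheme, cadence_s=cfg.solver.cadence_s,
                        seed=cfg.solver.seed)


def run_config_for_scenario(name: str) -> RunConfig:
    """Canonical configuration of one scenario, with calibrated defaults."""
    scen = SCENARIOS[name]
    circuit = canonical_circuit(gravity_on=scen.gravity_on)
    distal, proximal = configure_incompetence(
        (BallValveSpec(), BallValveSpec()), scen.valve_grade)
    return RunConfig(
        scenario=name,
        gravity_m_s2=circuit.gravity_m_s2,
        segments=[SegmentSection(
            name=s.name, length_cm=s.length_cm, diameter_cm=s.diameter_cm,
            elevation_drop_cm=s.elevation_drop_cm, wall=s.wall, role=s.role,
            resistance_mmhg_s_ml=s.resistance_mmhg_s_ml) for s in circuit.segments],
        porous_interface=PorousSection(
            resistance_mmhg_s_ml=circuit.porous_interface.resistance_mmhg_s_ml),
        wall_motion=WallMotionSection(enabled=scen.wall_motion_on),
        valves=ValvesSection(
            distal=ValveSection(min_gap_cm=distal.min_gap_cm),
            proximal=ValveSection(min_gap_cm=proximal.min_gap_cm)),
    )


# -- file I/O --------------------------------------------------------------


def to_yaml(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(to_yaml(cfg).encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration.

    Raises :class:`ConfigurationError` carrying the *complete* violation
    list; parse failures carry the YAML position.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}",
                                 violations=[str(exc)]) from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping",
                                 violations=["top level must be a mapping"])
    try:
        cfg = RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        violations = [
            f"{'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}"
            for err in exc.errors()]
        raise ConfigurationError(f"{path}: {len(violations)} violation(s)",
                                 violations=violations) from exc
    violations = cfg.cross_field_violations()
    if violations:
        raise ConfigurationError(f"{path}: {len(violations)} violation(s)",
                                 violations=violations)
    return cfg


def generate_canonical_configs(output_dir: str | Path) -> list[Path]:
    """Write the five canonical scenario configurations to ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    header = ("# Canonical scenario configuration.\n"
              "# Segment resistances, the porous resistance, the wall-motion\n"
              "# displacement amplitude and the valve seat-leak reference\n"
              "# resistance are calibrated values (see docs/methods.md).\n")
    for name in SCENARIOS:
        cfg = run_config_for_scenario(name)
        p = out / f"{name}.yaml"
        p.write_text(header + to_yaml(cfg))
        paths.append(p)
    return paths


def run_from_config(cfg: RunConfig) -> ScenarioResult:
    """Execute a validated configuration."""
    from .scenarios import run_scenario  # local import to keep layering clear

    circuit = build_circuit(cfg)
    wall = None
    if cfg.wall_motion.enabled:
        wall = WallMotionLaw(cfg.wall_motion.displacement_amplitude_cm,
                             cfg.wall_motion.z0_cm, cfg.wall_motion.length_cm,
                             cfg.wall_motion.period_s)
    return run_scenario(SCENARIOS[cfg.scenario],
                        solver_config=build_solver_config(cfg),
                        valve_pair=build_valves(cfg),
                        circuit=circuit,
                        wall_motion=wall)


def _metrics_dict(res: ScenarioResult) -> dict:
    out = {"scenario": res.scenario.name,
           "discarded_cycles": res.discarded_cycles,
           "converged": res.converged}
    for probe in ("ankle", "knee"):
        m = getattr(res, probe)
        out[probe] = {
            "net_volume_ml": m.net_volume_ml,
            "antegrade_volume_ml": m.antegrade_volume_ml,
            "retrograde_volume_ml": m.retrograde_volume_ml,
            "ejection_fraction_pct": m.ejection_fraction_pct,
            "cycles_averaged": m.cycles_averaged,
        }
    return out


def write_results(res: ScenarioResult, out_dir: str | Path,
                  cfg: RunConfig | None = None) -> list[Path]:
    """Write probe CSV, metrics JSON and run-metadata JSON for one run.

    Numeric CSV formatting keeps 9+ significant digits; the metrics JSON is
    byte-deterministic for identical configuration and seed.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigurationError(f"cannot create output directory {out}: {exc}") from exc
    files = []

    series_path = out / f"{res.scenario.name}_series.csv"
    res.run.data.to_csv(series_path, index=False, float_format="%.10g")
    files.append(series_path)

    metrics_path = out / f"{res.scenario.name}_metrics.json"
    metrics_path.write_text(json.dumps(_metrics_dict(res), indent=2, sort_keys=True))
    files.append(metrics_path)

    meta_path = out / f"{res.scenario.name}_meta.json"
    meta = {
        "scenario": res.scenario.name,
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "software_version": _pkg_version,
        "seed": res.run.config.seed,
        "scheme": res.run.config.scheme,
        "dt_s": res.run.dt_s,
        "dx_cm": res.run.discretization.dx_cm,
        "n_edges": res.run.discretization.n_edges,
        "discarded_cycles": res.discarded_cycles,
    }
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    files.append(meta_path)
    return files


def write_comparison(results: dict[str, ScenarioResult], out_dir: str | Path) -> list[Path]:
    """Write the multi-scenario comparison report (Markdown + CSV + JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = compare_scenarios({k: v.knee for k, v in results.items()})
    files = []
    md = out / "comparison.md"
    md.write_text(report.to_markdown() + "\n")
    files.append(md)
    rows = []
    for name, res in results.items():
        rows.append({"scenario": name,
                     "net_ml": res.knee.net_volume_ml,
                     "antegrade_ml": res.knee.antegrade_volume_ml,
                     "retrograde_ml": res.knee.retrograde_volume_ml,
                     "ef_pct": res.knee.ejection_fraction_pct,
                     "reduction_vs_healthy_pct": report.reduction_pct.get(name)})
    csv = out / "comparison.csv"
    pd.DataFrame(rows).to_csv(csv, index=False, float_format="%.10g")
    files.append(csv)
    js = out / "comparison.json"
    js.write_text(json.dumps({
        "pump_gain": report.pump_gain,
        "reduction_pct": report.reduction_pct,
        "reflux_augmentation_ml": report.reflux_augmentation_ml,
        "net_volumes_ml": report.net_volumes_ml,
    }, indent=2, sort_keys=True))
    files.append(js)
    return files
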