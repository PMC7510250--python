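"""Canonical scenarios and per-cycle flow-volume metrics.

Five canonical simulations probe the calf pump:

1. clinostatism — supine rest: gravity off, muscle pump off;
2. orthostatism — standing rest: gravity on, muscle pump off; venous return
   is driven by the arterial pulsation alone;
3. walking, healthy — gravity on, muscle pump on, both valves competent;
4. walking, severe dysfunction — both valves' ball travel restricted to a
   ~2 mm residual gap;
5. walking, partial dysfunction — distal valve restricted, proximal
   competent.

The scientific outputs are per-cycle integrated flow volumes at the ankle
and knee cross-sections (net / antegrade / retrograde, heart-ward positive),
the calf ejection fraction EF = net / (pi R^2 h), and the healthy-vs-
dysfunction comparison (pump gain over orthostatism, percent reduction of
venous return, reflux augmentation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .circuit import CALF_LENGTH_CM, CALF_RADIUS_CM, canonical_circuit
from .errors import ComparisonError, InsufficientDataError, InvalidParameterError
from .forcing import ForcingSchedule, WallMotionLaw
from .solver import RunResult, SolverConfig, run
from .valves import BallValveSpec, configure_incompetence


@dataclass(frozen=True)
class Scenario:
    """Switch set of one canonical simulation."""

    name: str
    gravity_on: bool
    wall_motion_on: bool
    valve_grade: str  # "healthy" | "severe" | "partial"

    def __post_init__(self) -> None:
        if self.name.startswith("walking") and not self.wall_motion_on:
            raise InvalidParameterError("walking scenarios need wall motion")
        if self.name in ("clinostatism",) and (self.gravity_on or self.wall_motion_on):
            raise InvalidParameterError("clinostatism: gravity and wall motion are off")
        if self.name == "orthostatism" and (not self.gravity_on or self.wall_motion_on):
            raise InvalidParameterError("orthostatism: gravity on, wall motion off")


SCENARIOS: dict[str, Scenario] = {
    "clinostatism": Scenario("clinostatism", False, False, "healthy"),
    "orthostatism": Scenario("orthostatism", True, False, "healthy"),
    "walking_healthy": Scenario("walking_healthy", True, True, "healthy"),
    "walking_severe": Scenario("walking_severe", True, True, "severe"),
    "walking_partial": Scenario("walking_partial", True, True, "partial"),
}

#: resting calf trunk volume pi R^2 h (mL)
CALF_VOLUME_ML = math.pi * CALF_RADIUS_CM**2 * CALF_LENGTH_CM


@dataclass(frozen=True)
class CycleMetrics:
    """Per-cycle flow volumes at one probe, averaged over post-transient cycles."""

    net_volume_ml: float
    antegrade_volume_ml: float
    retrograde_volume_ml: float  # <= 0
    ejection_fraction_pct: float
    probe: str  # "ankle" | "knee"
    cycles_averaged: int


def ejection_fraction(net_volume_ml: float, calf_radius_cm: float = CALF_RADIUS_CM,
                      calf_length_cm: float = CALF_LENGTH_CM) -> float:
    """EF (%) = ejected volume over the resting trunk volume pi R^2 h."""
    if calf_radius_cm <= 0 or calf_length_cm <= 0:
        raise InvalidParameterError("calf dimensions must be > 0")
    return 100.0 * net_volume_ml / (math.pi * calf_radius_cm**2 * calf_length_cm)


def per_cycle_volumes(time_s: np.ndarray, flow_ml_s: np.ndarray,
                      period_s: float) -> pd.DataFrame:
    """Trapezoidal net/antegrade/retrograde volume for every complete cycle."""
    t = np.asarray(time_s, dtype=float)
    q = np.asarray(flow_ml_s, dtype=float)
    if t.size < 2 or t[-1] - t[0] < period_s * (1 - 1e-9):
        raise InsufficientDataError("series shorter than one full period")
    t0 = t[0]
    n_cycles = int(math.floor((t[-1] - t0) / period_s + 1e-9))
    rows = []
    for k in range(n_cycles):
        lo, hi = t0 + k * period_s, t0 + (k + 1) * period_s
        sel = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        tt, qq = t[sel], q[sel]
        rows.append({
            "cycle": k,
            "t_start_s": lo,
            "net_ml": float(np.trapezoid(qq, tt)),
            "antegrade_ml": float(np.trapezoid(np.maximum(qq, 0.0), tt)),
            "retrograde_ml": float(np.trapezoid(np.minimum(qq, 0.0), tt)),
        })
    return pd.DataFrame(rows)


def discard_transient(cycles: pd.DataFrame, rel_tol: float = 0.01,
                      min_discard: int = 2) -> tuple[pd.DataFrame, int, bool]:
    """Drop initial cycles until the per-cycle net volume settles.

    Discards at least ``min_discard`` cycles, then keeps everything from the
    first cycle whose net volume changed by less than ``rel_tol`` relative to
    its predecessor. Returns (kept cycles, number discarded, converged flag).
    """
    net = cycles["net_ml"].to_numpy()
    n = len(net)
    for k in range(max(1, min_discard), n):
        denom = max(abs(net[k - 1]), 1e-30)
        if abs(net[k] - net[k - 1]) / denom < rel_tol:
            return cycles.iloc[k:], k, True
    k = min(max(1, min_discard), n - 1)
    return cycles.iloc[k:], k, False


def cycle_volumes(flow_series: pd.Series, period_s: float,
                  probe: str = "knee", rel_tol: float = 0.01,
                  min_discard: int = 2) -> CycleMetrics:
    """Post-transient per-cycle flow volumes at a probe.

    ``flow_series`` is a flow (mL/s) indexed by time (s) covering at least
    one full period past the transient; heart-ward flow is positive.
    """
    cycles = per_cycle_volumes(flow_series.index.to_numpy(),
                               flow_series.to_numpy(), period_s)
    if len(cycles) > max(1, min_discard):
        kept, _, _ = discard_transient(cycles, rel_tol, min_discard)
    else:
        kept = cycles
    net = float(kept["net_ml"].mean())
    return CycleMetrics(
        net_volume_ml=net,
        antegrade_volume_ml=float(kept["antegrade_ml"].mean()),
        retrograde_volume_ml=float(kept["retrograde_ml"].mean()),
        ejection_fraction_pct=ejection_fraction(net),
        probe=probe,
        cycles_averaged=len(kept),
    )


@dataclass
class ScenarioResult:
    """Everything one scenario run produced."""

    scenario: Scenario
    run: RunResult
    ankle: CycleMetrics
    knee: CycleMetrics
    cycles_knee: pd.DataFrame
    discarded_cycles: int
    converged: bool


def default_cycles(scenario: Scenario) -> int:
    # resting scenarios settle slowly in wall-clock terms but cost nothing
    # at the slow step; pump scenarios settle within a few cycles
    return 10 if scenario.wall_motion_on else 15


def run_scenario(name: str | Scenario,
                 solver_config: SolverConfig | None = None,
                 displacement_amplitude_cm: float | None = None,
                 valve_pair: tuple[BallValveSpec, BallValveSpec] | None = None,
                 circuit=None,
                 wall_motion: WallMotionLaw | None = None) -> ScenarioResult:
    """Run one canonical scenario and compute its cycle metrics.

    The canonical circuit, forcing and valve pair are built from the
    scenario's switches; any of them can be overridden for sensitivity
    studies (e.g. a custom valve pair for gap sweeps).
    """
    scenario = SCENARIOS[name] if isinstance(name, str) else name
    if circuit is None:
        circuit = canonical_circuit(gravity_on=scenario.gravity_on)
    wall = None
    if scenario.wall_motion_on:
        if wall_motion is not None:
            wall = wall_motion
        elif displacement_amplitude_cm is not None:
            wall = WallMotionLaw(displacement_amplitude_cm=displacement_amplitude_cm)
        else:
            wall = WallMotionLaw()
    forcing = ForcingSchedule(inlet=circuit.inlet, wall_motion=wall)
    if valve_pair is None:
        valve_pair = configure_incompetence((BallValveSpec(), BallValveSpec()),
                                            scenario.valve_grade)
    cfg = solver_config or SolverConfig(total_cycles=default_cycles(scenario))

    result = run(circuit, forcing, valve_pair, cfg)
    period = result.cycle_period_s
    t = result.data["time_s"].to_numpy()

    metrics = {}
    for probe, col in (("ankle", "Q_ankle_ml_s"), ("knee", "Q_knee_ml_s")):
        cycles = per_cycle_volumes(t, result.data[col].to_numpy(), period)
        kept, discarded, converged = discard_transient(
            cycles, cfg.transient_rel_tol, cfg.min_discard_cycles)
        net = float(kept["net_ml"].mean())
        metrics[probe] = CycleMetrics(
            net_volume_ml=net,
            antegrade_volume_ml=float(kept["antegrade_ml"].mean()),
            retrograde_volume_ml=float(kept["retrograde_ml"].mean()),
            ejection_fraction_pct=ejection_fraction(net),
            probe=probe,
            cycles_averaged=len(kept),
        )
        if probe == "knee":
            cycles_knee, knee_discarded, knee_converged = cycles, discarded, converged

    return ScenarioResult(scenario=scenario, run=result,
                          ankle=metrics["ankle"], knee=metrics["knee"],
                          cycles_knee=cycles_knee,
                          discarded_cycles=knee_discarded, converged=knee_converged)


@dataclass
class ComparisonReport:
    """Healthy vs dysfunction comparison of per-cycle knee metrics."""

    pump_gain: float | None
    reduction_pct: dict[str, float]
    reflux_augmentation_ml: dict[str, float]
    net_volumes_ml: dict[str, float]

    def to_markdown(self) -> str:
        lines = ["| scenario | net volume (mL/cycle) | reduction vs healthy | extra reflux (mL) |",
                 "|---|---|---|---|"]
        for name, net in self.net_volumes_ml.items():
            red = self.reduction_pct.get(name)
            reflux = self.reflux_augmentation_ml.get(name)
            lines.append("| {} | {:.3f} | {} | {} |".format(
                name, net,
                f"{round(red):d}%" if red is not None else "-",
                f"{reflux:.3f}" if reflux is not None else "-"))
        if self.pump_gain is not None:
            lines.append(f"\nPump gain (walking / orthostatism net volume): "
                         f"{self.pump_gain:.2f}")
        return "\n".join(lines)


def compare_scenarios(metrics: dict[str, CycleMetrics]) -> ComparisonReport:
    """Pump gain and dysfunction-induced reduction of venous return.

    Requires at least the healthy walking baseline; orthostatism (for the
    pump gain) and any dysfunction grades are included when present.
    """
    if "walking_healthy" not in metrics:
        raise ComparisonError("comparison requires the walking_healthy baseline")
    healthy = metrics["walking_healthy"]
    gain = None
    if "orthostatism" in metrics and metrics["orthostatism"].net_volume_ml != 0:
        gain = healthy.net_volume_ml / metrics["orthostatism"].net_volume_ml
    reductions: dict[str, float] = {}
    reflux: dict[str, float] = {}
    for name, m in metrics.items():
        if name.startswith("walking") and name != "walking_healthy":
            reductions[name] = 100.0 * (healthy.net_volume_ml - m.net_volume_ml) \
                / healthy.net_volume_ml
            reflux[name] = abs(m.retrograde_volume_ml) - abs(healthy.retrograde_volume_ml)
    return ComparisonReport(
        pump_gain=gain,
        reduction_pct=reductions,
        reflux_augmentation_ml=reflux,
        net_volumes_ml={k: m.net_volume_ml for k, m in metrics.items()},
    )
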