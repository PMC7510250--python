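"""Optional plotting of probe time series (requires matplotlib)."""

from __future__ import annotations

from .scenarios import ScenarioResult


def plot_flow_cycles(result: ScenarioResult, last_cycles: int = 2, ax=None):
    """Flow rate at the ankle and knee cross-sections over the last cycles.

    Systole (first half of each cycle) is shaded. Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    d = result.run.data
    period = result.run.cycle_period_s
    t_max = d["time_s"].iloc[-1]
    sel = d["time_s"] >= t_max - last_cycles * period
    dd = d[sel]
    ax.plot(dd["time_s"], dd["Q_ankle_ml_s"], label="ankle (upstream)")
    ax.plot(dd["time_s"], dd["Q_knee_ml_s"], label="knee (downstream)")
    t0 = t_max - last_cycles * period
    for k in range(last_cycles):
        ax.axvspan(t0 + k * period, t0 + (k + 0.5) * period, alpha=0.1, color="gray")
    ax.axhline(0.0, lw=0.5, color="k")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("flow (mL/s)")
    ax.set_title(f"{result.scenario.name}: net {result.knee.net_volume_ml:.3f} mL/cycle")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_valve_positions(result: ScenarioResult, last_cycles: int = 2, ax=None):
    """Ball positions of the distal and proximal valves over the last cycles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.5))
    d = result.run.data
    period = result.run.cycle_period_s
    t_max = d["time_s"].iloc[-1]
    dd = d[d["time_s"] >= t_max - last_cycles * period]
    ax.plot(dd["time_s"], dd["x_distal_cm"], label="distal")
    ax.plot(dd["time_s"], dd["x_proximal_cm"], label="proximal")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ball lift (cm)")
    ax.legend(loc="best", fontsize=8)
    return ax
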