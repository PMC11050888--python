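"""Comparative figures: pulp traces vs. the damage threshold, and bar
charts of peak pulp temperature, composite volume and safe-time limits."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — headless use
import matplotlib.pyplot as plt

from .analysis import ComparativeSummary, CRITICAL_TEMPERATURE_C, DesignResult

__all__ = ["plot_pulp_traces", "plot_summary_bars"]

_PRETTY = {
    "direct_access": "direct access",
    "occlusal_distal": "occlusal-distal",
    "vertical_slot": "vertical slot",
    "horizontal_slot": "horizontal slot",
}


def plot_pulp_traces(results: dict[str, DesignResult], path,
                     T_crit: float = CRITICAL_TEMPERATURE_C) -> None:
    """Pulp temperature evolution for each design against the 42.5 C line."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for kind, res in results.items():
        s = res.pulp_series
        ax.plot(s.times, s.temperatures, label=_PRETTY.get(kind, kind))
    ax.axhline(T_crit, color="k", ls="--", lw=1,
               label=f"irreversible damage ({T_crit} °C)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pulp temperature (°C)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_summary_bars(summary: ComparativeSummary, prefix) -> list[str]:
    """Bar charts of peak pulp temperature, composite volume and the time
    limit to reach the damage threshold.  Returns the files written."""
    table = summary.table
    names = [_PRETTY.get(k, k) for k in table.index]
    written = []
    panels = [
        ("T_max_pulp_C", "peak pulp temperature (°C)", "max_pulp_temperature"),
        ("composite_volume_mm3", "composite volume (mm³)", "composite_volume"),
        ("t_cross_s", f"time to {summary.T_crit} °C (s)", "time_limit"),
    ]
    for col, ylabel, stem in panels:
        fig, ax = plt.subplots(figsize=(5.5, 4))
        ax.bar(names, table[col], color="#5b8db8")
        ax.set_ylabel(ylabel)
        ax.tick_params(axis="x", rotation=20)
        fig.tight_layout()
        out = f"{prefix}_{stem}.png"
        fig.savefig(out, dpi=150)
        plt.close(fig)
        written.append(out)
    return written
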