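"""Chart rendering: one stacked panel per strand, rate + credible band + signals."""

from __future__ import annotations

import numpy as np

from .chart import ChartResult

__all__ = ["plot_chart"]


def plot_chart(
    result: ChartResult,
    targets=None,
    pilot_cutoff: float | None = None,
    path=None,
    figsize=None,
):
    """Render a ChartResult as N stacked panels (earliest gate at the bottom).

    Each panel shows the strand's rate estimate m_i, the credible band, the
    target line, up/down signal markers, and (dashed) the pilot cut-off.
    Returns the matplotlib Figure; saves to ``path`` when given.
    """
    import matplotlib.pyplot as plt

    n = result.n_strands
    figsize = figsize or (10, 1.8 * n + 1)
    fig, axes = plt.subplots(n, 1, sharex=True, figsize=figsize, squeeze=False)
    axes = axes[:, 0]

    for panel, strand in enumerate(reversed(range(n))):  # last gate on top
        ax = axes[panel]
        sub = result.strand(strand)
        gate = result.gates.gates[strand]
        if len(sub):
            t = sub["calendar_time"].to_numpy()
            ax.fill_between(
                t, sub["ci_lo"], sub["ci_hi"], color="0.85", label="credible band"
            )
            ax.plot(t, sub["m"], lw=1.0, color="C0", label="rate")
            for direction, color in (("up", "red"), ("down", "green")):
                mask = (sub["signal"] == direction).to_numpy()
                if mask.any():
                    ax.plot(
                        t[mask],
                        sub["m"].to_numpy()[mask],
                        ".",
                        ms=3,
                        color=color,
                        label=f"{direction} signal",
                    )
        if targets is not None:
            ax.axhline(targets[strand], color="0.4", lw=0.8, ls=":")
        if pilot_cutoff is not None:
            ax.axvline(pilot_cutoff, color="k", lw=0.8, ls="--")
        ax.set_ylabel(f"{gate:g} d")
    axes[-1].set_xlabel("calendar time (days)")
    fig.suptitle("STRAND chart: risk-adjusted failure-rate estimates by gate")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
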