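"""Figure helpers: violin summaries and peak-aligned trace plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kinetics import AveragedTrace

__all__ = ["violin_plot", "plot_averaged_trace"]


def violin_plot(groups: dict[str, np.ndarray], ylabel: str, path) -> None:
    """Violin plot of per-object distributions, medians as dashed lines."""
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 3.2))
    data = [np.asarray(v, dtype=float) for v in groups.values()]
    parts = ax.violinplot(data, showextrema=False)
    for body in parts["bodies"]:
        body.set_alpha(0.6)
    for i, vals in enumerate(data, start=1):
        med = float(np.median(vals))
        ax.hlines(med, i - 0.25, i + 0.25, linestyles="dashed", color="k")
    ax.set_xticks(range(1, len(groups) + 1), list(groups))
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_averaged_trace(avg: AveragedTrace, path) -> None:
    """Mean normalized traces with shaded 95% CI, aligned at the reference peak."""
    fig, ax = plt.subplots(figsize=(4.2, 3.0))
    for ch, name in enumerate(avg.channel_names or [f"ch{i}" for i in range(avg.mean.shape[0])]):
        ax.plot(avg.times, avg.mean[ch], label=name)
        ax.fill_between(avg.times, avg.ci_low[ch], avg.ci_high[ch], alpha=0.25)
    ax.axvline(0.0, linestyle="dashed", color="k", linewidth=0.8)
    ax.set_xlabel("time relative to reference peak (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
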