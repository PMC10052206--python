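"""Trend plots: complexity with MBP/HR overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .trend import EventAnnotation, TrendPoint, trend_arrays


def plot_trend(trend: list[TrendPoint], data, times, variable_names,
               events: list[EventAnnotation] | None = None, path=None):
    """Three stacked panels — MBP, HR, complexity — on a shared time axis.

    Event annotations are drawn as vertical dashed lines.  Returns the
    figure; saves to ``path`` when given.
    """
    names = list(variable_names)
    cols = trend_arrays(trend)
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(10, 7))
    for ax, var, label, color in ((axes[0], "mbp", "MBP (mmHg)", "tab:red"),
                                  (axes[1], "hr", "HR (bpm)", "tab:green")):
        if var in names:
            ax.plot(times, np.asarray(data)[:, names.index(var)],
                    lw=0.6, color=color)
        ax.set_ylabel(label)
    axes[2].plot(cols["time"], cols["C"], lw=1.0, color="tab:blue", label="C")
    axes[2].fill_between(cols["time"], cols["C_min"], cols["C_critical"],
                         alpha=0.15, color="tab:blue",
                         label="[C_min, C_critical]")
    axes[2].set_ylabel("complexity (bits)")
    axes[2].set_xlabel("time (s)")
    axes[2].legend(loc="upper left", fontsize=8)
    for ev in events or []:
        for ax in axes:
            ax.axvline(ev.time, ls="--", lw=0.8, color="gray")
        axes[0].annotate(ev.kind, (ev.time, axes[0].get_ylim()[1]),
                         fontsize=7, rotation=90, va="top")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
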