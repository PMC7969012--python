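"""Publication-style panels for correlation curves.

One panel per condition: auto-correlations of both channels (top),
the cross-correlation with sem error bars (middle) and the per-lag
significance on a base-10 log scale (bottom).  Plotting is cosmetic;
the numeric record is the TSV output.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_condition_panel", "plot_curve"]

_P_FLOOR = 1e-300  # keep log10 finite for astronomically small p


def plot_curve(curve, ax, color="tab:red", label=None):
    """Curve with sem error bars on an existing axes."""
    ax.errorbar(
        curve.lags_px, curve.values, yerr=curve.sem,
        fmt="o-", ms=3, lw=1, capsize=2, color=color, label=label,
    )
    ax.axhline(0.0, color="0.6", lw=0.8, zorder=0)
    ax.set_xlabel("axial distance x (px)")


def plot_condition_panel(curves: dict, path, condition: str = ""):
    """Three-row panel: autos, cross, log10 p of the cross curve."""
    fig, axes = plt.subplots(3, 1, figsize=(4.2, 7.5), sharex=True)
    auto_names = [k for k in curves if k.startswith("auto_")]
    colors = ["tab:blue", "tab:green", "tab:orange"]
    for name, color in zip(auto_names, colors):
        plot_curve(curves[name], axes[0], color=color, label=name.removeprefix("auto_"))
    axes[0].set_ylabel("auto-correlation c(x)")
    axes[0].legend(frameon=False, fontsize=8)

    cross = curves["cross"]
    plot_curve(cross, axes[1], color="tab:red")
    axes[1].set_ylabel("cross-correlation g(x)")

    logp = np.log10(np.maximum(cross.p_values, _P_FLOOR))
    axes[2].plot(cross.lags_px, logp, "s-", ms=3, lw=1, color="0.2")
    axes[2].axhline(np.log10(0.05), color="tab:red", lw=0.8, ls="--")
    axes[2].set_ylabel("log10 p")
    axes[2].set_xlabel("axial distance x (px)")
    if condition:
        axes[0].set_title(condition)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
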