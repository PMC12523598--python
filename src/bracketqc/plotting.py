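"""Plot helpers: power-function panels and the run-size nomogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_power_curves", "plot_nomogram"]


def plot_power_curves(curves, path=None, *, thresholds=(0.9, 0.05)):
    """Ped vs shift for one or more rules (power-function panel).

    Horizontal guides mark the Ped and Pfr criteria.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(curve.shift_grid, curve.ped, label=curve.rule.name)
    ped_t, pfr_t = thresholds
    ax.axhline(ped_t, color="grey", ls="--", lw=0.8, label=f"Ped = {ped_t}")
    ax.axhline(pfr_t, color="grey", ls=":", lw=0.8, label=f"Pfr = {pfr_t}")
    ax.set_xlabel("systematic shift (SD units)")
    ax.set_ylabel("probability of rejection")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_nomogram(nomogram, path=None, *, workload_line=None):
    """Maximum allowed run size vs sigma, one curve per rule."""
    fig, ax = plt.subplots(figsize=(6, 4))
    df = nomogram.table
    for rule_name, grp in df.groupby("rule"):
        grp = grp.sort_values("sigma")
        ax.plot(grp["sigma"], np.maximum(grp["max_run_size"], 0.5), label=rule_name)
    if workload_line is not None:
        ax.axhline(workload_line, color="grey", ls="--", lw=0.8, label=f"n = {workload_line}")
    ax.set_yscale("log")
    ax.set_xlabel("sigma metric")
    ax.set_ylabel(f"max run size at Max E(Nuf) <= {nomogram.criterion}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
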