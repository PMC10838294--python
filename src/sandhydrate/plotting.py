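"""Presentation-only figure rendering for runs and sweeps.

Renders the standard panels: depth profiles of hydrate saturation and
dissolved pools at the snapshot times, the summary time series, per-node
generation-rate profiles, and sweep constraint-region maps. Nothing in
the numerical results depends on this module.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .simulator import RunResult, generation_rate_profiles  # noqa: E402
from .sweep import SweepResult, constraint_region  # noqa: E402


def plot_profiles(result: RunResult, path) -> None:
    """Depth-profile panels (S, DOC, CH4) at the stored snapshot times."""
    col = result.column
    z = col.node_depths
    snaps = result.snapshots or [result.final_state]
    fig, axes = plt.subplots(1, 3, figsize=(10, 6), sharey=True)
    cmap = plt.get_cmap("viridis")
    for k, s in enumerate(snaps):
        c = cmap(k / max(1, len(snaps) - 1))
        lbl = f"{s.t / 1e3:g} kyr"
        axes[0].plot(s.S, z, color=c, label=lbl)
        axes[1].plot(s.H + s.L, z, color=c)
        axes[2].plot(s.M, z, color=c)
    for ax, xl in zip(axes, ("hydrate saturation S", "DOC (H+L), mM",
                             "dissolved CH4, mM")):
        ax.set_xlabel(xl)
    sand = np.flatnonzero(col.is_sand)
    if sand.size:
        for ax in axes:
            ax.axhspan(z[sand[0]], z[sand[-1]], color="0.85", zorder=0)
    axes[0].set_ylabel("depth in interval, m")
    axes[0].invert_yaxis()
    axes[0].legend(fontsize=7, loc="lower right")
    fig.suptitle(f"{result.scenario.name}: snapshot profiles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_series(result: RunResult, path) -> None:
    """Summary time series: DOC maxima, hydrate maxima, HFZ thickness."""
    se = result.series
    t = se["t_yr"] / 1e3
    fig, axes = plt.subplots(3, 1, figsize=(7, 8), sharex=True)
    axes[0].plot(t, se["max_doc"], label="max DOC")
    axes[0].plot(t, se["max_doc_mud"], "--", label="mud")
    axes[0].plot(t, se["max_doc_sand"], ":", label="sand")
    axes[0].set_ylabel("DOC, mM")
    axes[0].legend(fontsize=8)
    axes[1].plot(t, se["max_S_sand"], label="sand")
    axes[1].plot(t, se["max_S_mud"], "--", label="mud")
    axes[1].set_ylabel("max S")
    axes[1].legend(fontsize=8)
    axes[2].plot(t, se["hfz_above_m"], label="above")
    axes[2].plot(t, se["hfz_below_m"], "--", label="below")
    axes[2].set_ylabel("HFZ, m")
    axes[2].set_xlabel("time, kyr")
    axes[2].legend(fontsize=8)
    fig.suptitle(f"{result.scenario.name}: time series")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_generation(result: RunResult, path) -> None:
    """Per-node DOC and methane generation-rate profiles (final state)."""
    col = result.column
    z = col.node_depths
    from .model_core import burial_depth
    d = burial_depth(result.scenario.burial, result.final_state.t)
    doc_rate, ch4_rate = generation_rate_profiles(
        result.final_state, col, result.scenario.rates, d)
    fig, axes = plt.subplots(1, 2, figsize=(7, 6), sharey=True)
    axes[0].plot(doc_rate, z)
    axes[0].set_xlabel("DOC generation, mM/kyr")
    axes[1].plot(ch4_rate, z)
    axes[1].set_xlabel("CH4 generation, mM/kyr")
    sand = np.flatnonzero(col.is_sand)
    if sand.size:
        for ax in axes:
            ax.axhspan(z[sand[0]], z[sand[-1]], color="0.85", zorder=0)
    axes[0].set_ylabel("depth in interval, m")
    axes[0].invert_yaxis()
    fig.suptitle(f"{result.scenario.name}: generation rates (final)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(result: SweepResult, path, metric: str = "max_doc") -> None:
    """Sweep map of one metric with the constraint-region boundary."""
    keh_ax, kfm_ax = result.spec.axes()
    grid = result.metric_grid(metric)
    fig, ax = plt.subplots(figsize=(7, 5.5))
    pm = ax.pcolormesh(kfm_ax, keh_ax, grid, shading="nearest")
    fig.colorbar(pm, ax=ax, label=metric)
    _, info = constraint_region(result)
    if info["boundary"]:
        b = np.array(info["boundary"])
        ax.plot(b[:, 1], b[:, 0], "r.", ms=8,
                label="constraint-region boundary")
    if result.spec.star is not None:
        ax.plot(result.spec.star[1], result.spec.star[0], "w*", ms=16,
                mec="k", label="star point")
    ax.set_xlabel("log10 K_fm")
    ax.set_ylabel("log10 K_eh")
    ax.legend(fontsize=8, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
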