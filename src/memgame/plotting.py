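"""Heat maps of the T-S plane and subgroup-colored lattice snapshots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .lattice import LatticeState
from .memory import MemoryConfig
from .observables import Subgroup, subgroup_of

__all__ = ["plot_heatmap", "render_snapshot", "plot_ledger"]

# C_C dark blue, C_D light blue, D_D dark red, D_C light red
SUBGROUP_COLORS = ("#00407a", "#7fbfff", "#8b0000", "#ff9999")
_SUBGROUP_CMAP = ListedColormap(SUBGROUP_COLORS)


def plot_heatmap(sweep_result, param, ax=None):
    """Stationary cooperator fraction over the (T, S) grid for one parameter."""
    cells = sweep_result.cell_means()
    cells = cells[cells["param"] == param]
    T_vals = np.sort(cells["T"].unique())
    S_vals = np.sort(cells["S"].unique())
    grid = np.full((S_vals.size, T_vals.size), np.nan)
    for _, row in cells.iterrows():
        grid[np.searchsorted(S_vals, row["S"]), np.searchsorted(T_vals, row["T"])] = row["rho_mean"]
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        grid,
        origin="lower",
        extent=(T_vals.min(), T_vals.max(), S_vals.min(), S_vals.max()),
        aspect="auto",
        vmin=0.0,
        vmax=1.0,
        cmap="viridis",
    )
    ax.set_xlabel("T")
    ax.set_ylabel("S")
    ax.figure.colorbar(im, ax=ax, label=r"$\rho_C$")
    return ax


def subgroup_grid(state: LatticeState, mem: MemoryConfig) -> np.ndarray:
    """Integer subgroup codes (0..3) for every site, vectorized."""
    current = state.strategies
    if mem.reference_lag == 0 or not state.strat_records:
        reference = current
    else:
        reference = state.reference_strategies()
    codes = np.empty_like(current)
    for cur in (0, 1):
        for ref in (0, 1):
            codes[(current == cur) & (reference == ref)] = int(subgroup_of(cur, ref))
    return codes


def render_snapshot(state: LatticeState, mem: MemoryConfig | None = None, ax=None):
    """Lattice snapshot with weak/strong coloring.

    Strong (weak) cooperators are dark (light) blue; strong (weak)
    defectors dark (light) red.
    """
    mem = mem or MemoryConfig()
    codes = subgroup_grid(state, mem)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(codes, cmap=_SUBGROUP_CMAP, vmin=0, vmax=3, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_ledger(ledger_frame, channels=None, ax=None, smooth: int = 1):
    """Invasion-rate curves over time for selected directed channels."""
    if ax is None:
        _, ax = plt.subplots()
    if channels is None:
        channels = [c for c in ledger_frame.columns if "<-" in c]
    mcs = ledger_frame["mcs"].to_numpy()
    for name in channels:
        y = ledger_frame[name].to_numpy(dtype=float)
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            y = np.convolve(y, kernel, mode="same")
        ax.plot(mcs, y, label=name)
    ax.set_xlabel("MCS")
    ax.set_ylabel("events per MCS")
    ax.legend(fontsize=8)
    return ax
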