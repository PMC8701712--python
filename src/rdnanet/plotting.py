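"""Optional matplotlib rendering of tracks, correlation heatmaps and logos.

These helpers exist for quick inspection; publication-grade styling is out
of scope.  Matplotlib's non-interactive Agg backend is assumed when saving.
"""

from __future__ import annotations

import numpy as np

from .differential import CALL_DOWN, CALL_UP, DifferentialTrack
from .occupancy import OccupancyProfile
from .reproducibility import CorrelationMatrix
from .seqcontext import ALPHABET, DiffLogoResult

__all__ = ["plot_track", "plot_correlation_heatmap", "plot_difference_logo"]

_SYMBOL_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def plot_track(
    profile: OccupancyProfile,
    ax=None,
    differential: DifferentialTrack | None = None,
    region: tuple[int, int] | None = None,
):
    """Occupancy versus position; optional significance underlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    pos = np.arange(1, len(profile) + 1)
    v = profile.values
    if region is not None:
        sel = (pos >= region[0]) & (pos <= region[1])
        pos, v = pos[sel], v[sel]
    ax.fill_between(pos, v, step="mid", linewidth=0, alpha=0.8)
    ax.set_xlabel("position (nt)")
    ax.set_ylabel("occupancy")
    ax.set_title(profile.label)
    if differential is not None:
        floor = -0.05 * (v.max() or 1.0)
        for call, color in ((CALL_UP, "green"), (CALL_DOWN, "black")):
            at = differential.positions_called(call)
            if region is not None:
                at = at[(at >= region[0]) & (at <= region[1])]
            ax.plot(at, np.full(at.size, floor), "|", color=color, markersize=4)
    return ax


def plot_correlation_heatmap(matrix: CorrelationMatrix, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(matrix.rho, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.labels)), matrix.labels)
    for i in range(len(matrix.labels)):
        for j in range(len(matrix.labels)):
            ax.text(j, i, f"{matrix.rho[i, j]:.2f}", ha="center", va="center",
                    fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="Spearman rho")
    return ax


def plot_difference_logo(result: DiffLogoResult, ax=None, alpha: float | None = None):
    """Stacked signed symbol contributions per offset; asterisks mark
    offsets that stay significant after Holm correction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    pos_base = np.zeros(result.offsets.size)
    neg_base = np.zeros(result.offsets.size)
    for i, sym in enumerate(ALPHABET):
        contrib = result.contributions[i]
        up = np.clip(contrib, 0, None)
        down = np.clip(contrib, None, 0)
        ax.bar(result.offsets, up, bottom=pos_base, color=_SYMBOL_COLORS[sym],
               label=sym, width=0.8)
        ax.bar(result.offsets, down, bottom=neg_base, color=_SYMBOL_COLORS[sym],
               width=0.8)
        pos_base += up
        neg_base += down
    for off in result.significant_offsets(alpha):
        idx = int(np.flatnonzero(result.offsets == off)[0])
        ax.annotate("*", (off, pos_base[idx]), ha="center", fontsize=12)
    ax.axhline(0, color="black", linewidth=0.8)
    ax.axvline(0, color="grey", linestyle=":", linewidth=0.8)
    ax.set_xlabel("offset from LNT (nt)")
    ax.set_ylabel("signed JS contribution (bits)")
    ax.legend(ncols=4, fontsize=8)
    return ax
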