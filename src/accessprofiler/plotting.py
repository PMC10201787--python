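"""Rendering of profile and heatmap artifacts (matplotlib, Agg backend)."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_profiles(profiles: Mapping[int, "object"], path, window: tuple[int, int] = (151, 300)) -> None:
    """Fold-accessibility dots plus LOESS curve per quantile group.

    ``profiles`` maps quantile index -> AggregateProfile with ``fold`` and
    ``smoothed`` filled; the shaded band marks the per-gene accessibility
    window upstream of the TSS.
    """
    fig, ax = plt.subplots(figsize=(7, 5))
    cmap = plt.get_cmap("viridis")
    for q in sorted(profiles):
        prof = profiles[q]
        color = cmap(q / 10)
        ax.plot(prof.offsets, prof.fold, ".", ms=1.5, alpha=0.25, color=color)
        if prof.smoothed is not None:
            ax.plot(prof.offsets, prof.smoothed, "-", lw=1.5, color=color, label=f"q{q}")
    ax.axvspan(window[0], window[1], color="grey", alpha=0.2)
    ax.invert_xaxis()  # read toward the TSS, left to right
    ax.set_xlabel("bp upstream of TSS")
    ax.set_ylabel("fold accessibility over background")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """log10(count+1) accessibility heatmap, highest expression on top."""
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", interpolation="nearest", cmap="magma")
    ax.set_xlabel("window (5' flank | body | 3' flank)")
    ax.set_ylabel("genes by descending expression")
    fig.colorbar(im, ax=ax, label="log10(insertions + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
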