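"""Figures: decay curves, LD-map tracks, phase tracks, triangular heatmap.

Plots are side artifacts for visual inspection; every number they show is
also written to TSV by the CLI, and the TSVs are the canonical outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .decay import DecayCurve
from .genotype_io import HaplotypePanel
from .ld_core import LDPairTable, _corr_matrix, _require_complete
from .local_ld import LDMapTrack
from .phase import LocalPhaseTrack, PhaseCurve


def plot_decay(curves: Iterable[DecayCurve], path: str | Path) -> Path:
    """Mean r² vs bin midpoint, one line per population."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in curves:
        t = c.table.dropna(subset=["mean_r2"])
        ax.plot(t["mid"], t["mean_r2"], marker=".", ms=3, lw=1,
                label=c.population_label or "population")
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel("mean $r^2$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_ld_map(
    tracks: Iterable[LDMapTrack], path: str | Path, value: str = "expected_r2"
) -> Path:
    """α̂ or expected r² at d_fixed vs middle-marker position, per chromosome."""
    tracks = list(tracks)
    chroms = sorted({c for t in tracks for c in t.table["chrom"].unique()})
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 2.6 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        for t in tracks:
            sub = t.table[t.table["chrom"] == chrom]
            label = t.population_label or f"N={t.window_size}"
            ax.plot(sub["mid_pos"] / 1e6, sub[value], lw=0.8,
                    label=f"{label} (N={t.window_size})")
        ax.set_title(f"chromosome {chrom}")
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel(r"$\hat\alpha$" if value == "alpha_hat" else "expected $r^2$")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_ld_map_multi_n(
    tracks: Sequence[LDMapTrack], chrom_mean_alpha: float | None, path: str | Path
) -> Path:
    """α̂ tracks for several window sizes with the chromosome-mean reference line."""
    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    for t in tracks:
        sub = t.table
        axes[0].plot(sub["mid_pos"] / 1e6, sub["alpha_hat"], lw=0.8,
                     label=f"N={t.window_size}")
        axes[1].plot(sub["mid_pos"] / 1e6, sub["expected_r2"], lw=0.8,
                     label=f"N={t.window_size}")
    if chrom_mean_alpha is not None:
        axes[0].axhline(chrom_mean_alpha, color="grey", lw=1,
                        label="chromosome mean")
    axes[0].set_ylabel(r"$\hat\alpha$")
    axes[1].set_ylabel("expected $r^2$")
    axes[1].set_xlabel("position (Mb)")
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_chromosome_alpha(table: pd.DataFrame, path: str | Path) -> Path:
    """mean(α̂) per chromosome (with sd error bars)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(table))
    ax.errorbar(x, table["mean_alpha"], yerr=table["sd_alpha"], fmt="o-", ms=4)
    ax.set_xticks(x, table["chrom"])
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"mean($\hat\alpha$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_phase_curves(curves: Iterable[PhaseCurve], path: str | Path) -> Path:
    """Persistence of phase vs distance, one line per population pair."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in curves:
        t = c.table.dropna(subset=["cor_r"])
        ax.plot(t["mid"], t["cor_r"], marker=".", ms=3, lw=1,
                label=f"{c.population_pair[0]}-{c.population_pair[1]} ({c.scenario})")
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel(r"cor($r_A$, $r_B$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_local_phase(tracks: Iterable[LocalPhaseTrack], path: str | Path) -> Path:
    """Sliding-window phase correlation vs position, per chromosome."""
    tracks = list(tracks)
    chroms = sorted({c for t in tracks for c in t.table["chrom"].unique()})
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 2.6 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        for t in tracks:
            sub = t.table[t.table["chrom"] == chrom]
            ax.plot(sub["mid_pos"] / 1e6, sub["cor_r"], lw=0.8,
                    label=f"{t.population_pair[0]}-{t.population_pair[1]} ({t.scenario})")
        ax.set_title(f"chromosome {chrom}")
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel(r"cor($r_A$, $r_B$)")
        ax.set_ylim(-1.05, 1.05)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_triangular_heatmap(
    panel: HaplotypePanel,
    chrom: str,
    path: str | Path,
    start_bp: int | None = None,
    end_bp: int | None = None,
    track: LDMapTrack | None = None,
) -> Path:
    """Rotated upper-triangle pairwise-r² heatmap for a chromosomal region.

    Darker blocks mean higher LD.  When an LD-map ``track`` is given, its
    expected-r² profile is drawn above the triangle so peaks can be
    compared with the high-LD blocks they summarize.
    """
    idx = [
        i for i, m in enumerate(panel.markers)
        if m.chrom == chrom
        and (start_bp is None or m.pos >= start_bp)
        and (end_bp is None or m.pos <= end_bp)
    ]
    if len(idx) < 2:
        raise ValueError(f"region {chrom}:{start_bp}-{end_bp} has <2 markers")
    sub = panel.subset_markers(np.asarray(idx))
    R2 = _corr_matrix(_require_complete(sub)) ** 2
    m = len(idx)
    # rotate the marker grid 45°: cell (i, j) centres at ((i+j)/2, (j−i)/2)
    corners = np.arange(m + 1) - 0.5
    I, J = np.meshgrid(corners, corners, indexing="ij")
    X, Y = (I + J) / 2.0, (J - I) / 2.0
    C = np.ma.masked_where(np.tril(np.ones((m, m), bool)), R2)

    nrows = 2 if track is not None else 1
    fig, axes = plt.subplots(
        nrows, 1, figsize=(8, 4 + 2 * (nrows - 1)), squeeze=False,
        gridspec_kw={"height_ratios": [1, 2] if track is not None else [1]},
    )
    if track is not None:
        t = track.table[track.table["chrom"] == chrom]
        axes[0, 0].plot(t["mid_pos"] / 1e6, t["expected_r2"], lw=0.9, color="black")
        axes[0, 0].set_ylabel("expected $r^2$")
        axes[0, 0].set_xlabel("position (Mb)")
    ax = axes[-1, 0]
    pcm = ax.pcolormesh(X, Y, C, cmap="Greys", vmin=0, vmax=1)
    ax.set_ylim(0, m / 2 + 1)
    ax.set_yticks([])
    ax.set_xlabel("marker index")
    fig.colorbar(pcm, ax=ax, label="$r^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
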