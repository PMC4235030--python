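"""Genome-wide LD decay summaries.

Marker pairs are pooled across autosomes and grouped into even physical-
distance bins (100 kb wide, 0–10 Mb by default); the mean r² per bin is the
decay curve.  Bins are half-open [lo, hi): a pair at exactly 100 kb falls
in the second bin, and pairs at exactly the distance cap are excluded.
Binning is done on integer base-pair distances so that pairs on exact bin
boundaries are never misassigned by floating-point division.

Also here: adjacent-pair summaries (mean/median spacing, mean r², the
proportion of pairs with r² above 0.3 and 0.2), per-chromosome mean r² at
target distances, and a Welch t-test comparing adjacent-pair r² between two
populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ld_core import LDPairTable


@dataclass
class DecayCurve:
    """Mean r² per distance bin.

    ``table`` columns: bin_lo, bin_hi, mid (Mb), mean_r2 (NaN when the bin
    is empty), n_pairs.
    """

    table: pd.DataFrame
    population_label: str = ""
    bin_width: float = 0.1
    max_distance: float = 10.0


@dataclass
class AdjacentSummary:
    median_spacing_kb: float
    mean_spacing_kb: float
    mean_r2: float
    sd_r2: float
    prop_r2_gt_03: float
    prop_r2_gt_02: float
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _pooled(pairs: LDPairTable | Iterable[LDPairTable]) -> tuple[pd.DataFrame, str]:
    if isinstance(pairs, LDPairTable):
        return pairs.pairs, pairs.population_label
    tables = list(pairs)
    label = tables[0].population_label if tables else ""
    df = pd.concat([t.pairs for t in tables], ignore_index=True)
    return df, label


def _bin_index(df: pd.DataFrame, bin_width: float) -> np.ndarray:
    """Half-open distance-bin index from integer bp distances."""
    d_bp = np.abs(df["pos_j"].to_numpy() - df["pos_i"].to_numpy()).astype(np.int64)
    return d_bp // int(round(bin_width * 1e6))


def binned_decay(
    pairs: LDPairTable | Iterable[LDPairTable],
    bin_width: float = 0.1,
    max_distance: float = 10.0,
) -> DecayCurve:
    """Mean r² in half-open distance bins of ``bin_width`` Mb up to ``max_distance``."""
    df, label = _pooled(pairs)
    n_bins = int(round(max_distance / bin_width))
    if len(df):
        idx = _bin_index(df, bin_width)
        keep = idx < n_bins
        idx = idx[keep]
        r2 = df["r2"].to_numpy()[keep]
        n = np.bincount(idx, minlength=n_bins)
        s = np.bincount(idx, weights=r2, minlength=n_bins)
    else:
        n = np.zeros(n_bins, dtype=int)
        s = np.zeros(n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    lo = np.arange(n_bins) * bin_width
    table = pd.DataFrame(
        {
            "bin_lo": lo,
            "bin_hi": lo + bin_width,
            "mid": lo + bin_width / 2,
            "mean_r2": mean,
            "n_pairs": n,
        }
    )
    return DecayCurve(
        table=table, population_label=label, bin_width=bin_width, max_distance=max_distance
    )


def adjacent_summary(pairs: LDPairTable) -> AdjacentSummary:
    """Spacing and r² summary over adjacent marker pairs."""
    df = pairs.pairs
    if df.empty:
        raise ValueError("no adjacent pairs to summarize")
    spacing_kb = df["d"].to_numpy() * 1e3
    r2 = df["r2"].to_numpy()
    return AdjacentSummary(
        median_spacing_kb=float(np.median(spacing_kb)),
        mean_spacing_kb=float(spacing_kb.mean()),
        mean_r2=float(r2.mean()),
        sd_r2=float(r2.std(ddof=1)) if len(r2) > 1 else 0.0,
        prop_r2_gt_03=float((r2 > 0.3).mean()),
        prop_r2_gt_02=float((r2 > 0.2).mean()),
        n_pairs=len(df),
    )


def ld_at_distances(
    pairs: LDPairTable,
    targets: Sequence[float] = (0.5, 1.0, 5.0),
    tolerance: float = 0.1,
    cumulative: bool = False,
) -> pd.DataFrame:
    """Per-chromosome mean r² for pairs near each target distance (Mb).

    For target D the window is the half-open interval [D − tolerance, D)
    (bin-local, matching the decay-curve convention); with
    ``cumulative=True`` it is all pairs with d < D instead.  Empty cells
    are NaN.  An "All" row pools every chromosome.
    """
    df = pairs.pairs
    d_bp = np.abs(df["pos_j"].to_numpy() - df["pos_i"].to_numpy()).astype(np.int64)
    r2 = df["r2"].to_numpy()
    chroms = df["chrom"].to_numpy()
    chrom_levels = list(dict.fromkeys(chroms)) + ["All"]
    out: dict[str, list] = {"chrom": chrom_levels}
    for D in targets:
        hi = int(round(D * 1e6))
        lo = 0 if cumulative else int(round((D - tolerance) * 1e6))
        sel = (d_bp >= lo) & (d_bp < hi)
        col = []
        for c in chrom_levels:
            mask = sel if c == "All" else sel & (chroms == c)
            col.append(float(r2[mask].mean()) if mask.any() else np.nan)
        out[f"{D}Mb"] = col
    return pd.DataFrame(out)


def compare_adjacent_ld(
    r2_a: Sequence[float], r2_b: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t-test on adjacent-pair r² values of two populations.

    Returns (t statistic, two-sided p-value).  When both samples have zero
    variance the test degenerates: equal means give (0, 1), unequal means
    (±inf, 0).
    """
    a = np.asarray(r2_a, dtype=float)
    b = np.asarray(r2_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
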