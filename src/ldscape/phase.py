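"""Persistence of LD phase between populations.

For a set of markers shared by populations A and B, the signed LD
correlations r_ij are computed in each population over the same marker
pairs, and the persistence of phase is their Pearson correlation

    cor(r_A, r_B) = Σ (r_ij(A) − r̄_A)(r_ij(B) − r̄_B) / (S_A S_B).

High values mean marker–marker phase relationships are shared — the
quantity that determines whether marker effects transfer between
populations in across-population genomic prediction.

Two common-marker scenarios are supported: Scenario I uses the markers
shared by *all* populations under study; Scenario II uses the markers
shared by one specific pair.  Markers are matched on (chromosome,
position) with allele-set verification: a marker whose REF/ALT labels are
swapped between panels is kept with a sign-flip flag (applied by
relabeling its alleles, which restores a common sign convention for r);
markers whose allele sets differ are dropped.

Outputs mirror the within-population decay module: distance-binned phase
curves and sliding-window local phase tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import HaplotypePanel
from .ld_core import _corr_matrix, _require_complete

logger = logging.getLogger(__name__)


@dataclass
class CommonMarkerSet:
    """Markers matched across panels on (chrom, pos) with allele checks.

    ``table`` columns: chrom, pos, then idx_<label> (row index in that
    panel) and flip_<label> (True when that panel's REF/ALT labels are
    swapped relative to the first panel) for every population.
    """

    scenario: str  # "I" or "II"
    population_labels: list[str]
    table: pd.DataFrame
    n_dropped_allele_mismatch: int = 0

    def __len__(self) -> int:
        return len(self.table)

    def positions(self) -> set[tuple[str, int]]:
        return set(zip(self.table["chrom"], self.table["pos"]))


def common_markers(
    panels: list[HaplotypePanel], scenario: str = "I"
) -> CommonMarkerSet:
    """Match markers across panels by (chrom, pos) with allele verification.

    Scenario "I" intersects all given panels (two or three); Scenario "II"
    requires exactly two panels (call it once per pair).
    """
    scenario = scenario.upper()
    if scenario not in ("I", "II"):
        raise ValueError(f"scenario must be 'I' or 'II', got {scenario!r}")
    if scenario == "II" and len(panels) != 2:
        raise ValueError("Scenario II intersects exactly one panel pair")
    if len(panels) < 2:
        raise ValueError("need at least two panels")
    labels = [p.population_label or f"pop{k}" for k, p in enumerate(panels)]
    if len(set(labels)) != len(labels):
        raise ValueError("population labels must be distinct")

    maps = []
    for p in panels:
        maps.append(
            {(m.chrom, m.pos): (i, m) for i, m in enumerate(p.markers)}
        )
    keys = set(maps[0])
    for mp in maps[1:]:
        keys &= set(mp)
    rows = []
    n_mismatch = 0
    for key in keys:
        i0, m0 = maps[0][key]
        alleles0 = {m0.allele0, m0.allele1}
        rec = {"chrom": key[0], "pos": key[1],
               f"idx_{labels[0]}": i0, f"flip_{labels[0]}": False}
        ok = True
        for lab, mp in zip(labels[1:], maps[1:]):
            ik, mk = mp[key]
            if {mk.allele0, mk.allele1} != alleles0:
                ok = False
                break
            rec[f"idx_{lab}"] = ik
            rec[f"flip_{lab}"] = mk.allele0 != m0.allele0
        if ok:
            rows.append(rec)
        else:
            n_mismatch += 1
    if not rows:
        raise ValueError("no common markers between panels")
    if n_mismatch:
        logger.info("dropped %d common-position markers with mismatched alleles",
                    n_mismatch)
    table = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return CommonMarkerSet(
        scenario=scenario,
        population_labels=labels,
        table=table,
        n_dropped_allele_mismatch=n_mismatch,
    )


def phase_correlation(rA, rB) -> float:
    """Pearson correlation of matched signed-r vectors; NaN if degenerate."""
    rA = np.asarray(rA, dtype=float)
    rB = np.asarray(rB, dtype=float)
    if rA.shape != rB.shape:
        raise ValueError("r vectors must have equal length")
    if rA.size < 3:
        raise ValueError("need at least 3 matched pairs")
    if rA.std() == 0.0 or rB.std() == 0.0:
        return np.nan
    return float(np.corrcoef(rA, rB)[0, 1])


def _aligned(
    panelA: HaplotypePanel, panelB: HaplotypePanel, cms: CommonMarkerSet
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Matched marker table plus flip-corrected haplotype matrices.

    Sign flips are applied by relabeling panel-B alleles (h → 1 − h) at
    flipped markers, so both matrices share panel A's sign convention.
    Matched markers monomorphic in either population are dropped (their r
    is undefined); the drop count is logged.
    """
    labA, labB = panelA.population_label, panelB.population_label
    cols = cms.table.columns
    if f"idx_{labA}" not in cols or f"idx_{labB}" not in cols:
        raise ValueError(
            f"common-marker set does not cover populations {labA!r} and {labB!r}"
        )
    ia = cms.table[f"idx_{labA}"].to_numpy()
    ib = cms.table[f"idx_{labB}"].to_numpy()
    fa = cms.table[f"flip_{panelA.population_label}"].to_numpy()
    fb = cms.table[f"flip_{panelB.population_label}"].to_numpy()
    HA = _require_complete(panelA)[ia]
    HB = _require_complete(panelB)[ib]
    HA[fa] = 1.0 - HA[fa]
    HB[fb] = 1.0 - HB[fb]
    pA, pB = HA.mean(axis=1), HB.mean(axis=1)
    poly = (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
    if not poly.all():
        logger.info(
            "dropped %d matched markers monomorphic in %s or %s",
            int((~poly).sum()), labA, labB,
        )
    meta = cms.table.loc[poly, ["chrom", "pos"]].reset_index(drop=True)
    return meta, HA[poly], HB[poly]


@dataclass
class PhaseCurve:
    """cor(r_A, r_B) per distance bin.

    ``table`` columns: bin_lo, bin_hi, mid (Mb), cor_r (NaN when a bin has
    fewer than ``min_pairs`` pairs or degenerate variance), n_pairs.
    """

    table: pd.DataFrame
    population_pair: tuple[str, str]
    scenario: str
    bin_width: float = 0.1
    max_distance: float = 10.0


@dataclass
class LocalPhaseTrack:
    """Sliding-window cor(r_A, r_B) along chromosomes.

    ``table`` columns: chrom, window, mid_pos, cor_r, n_pairs.
    """

    table: pd.DataFrame
    window_size: int
    population_pair: tuple[str, str]
    scenario: str


def _pair_r_vectors(
    meta: pd.DataFrame, HA: np.ndarray, HB: np.ndarray, max_distance: float
):
    """Per-chromosome (d_bp, rA, rB) over matched-marker pairs within the cap."""
    cap_bp = int(round(max_distance * 1e6))
    for chrom, sub in meta.groupby("chrom", sort=False):
        rows = sub.index.to_numpy()
        m = rows.size
        if m < 2:
            continue
        pos = sub["pos"].to_numpy(dtype=np.int64)
        RA = _corr_matrix(HA[rows])
        RB = _corr_matrix(HB[rows])
        ii, jj = np.triu_indices(m, k=1)
        d_bp = np.abs(pos[jj] - pos[ii])
        keep = d_bp < cap_bp
        yield chrom, pos, d_bp[keep], RA[ii[keep], jj[keep]], RB[ii[keep], jj[keep]], RA, RB


def binned_phase_decay(
    panelA: HaplotypePanel,
    panelB: HaplotypePanel,
    cms: CommonMarkerSet,
    bin_width: float = 0.1,
    max_distance: float = 10.0,
    min_pairs: int = 3,
) -> PhaseCurve:
    """Distance-binned persistence of phase between two populations.

    Pairs are formed only between matched markers; distances come from the
    shared positions, so both populations contribute the same pair set.
    Bins are half-open [lo, hi) as in the decay module; bins with fewer
    than ``min_pairs`` pairs are flagged NaN.
    """
    meta, HA, HB = _aligned(panelA, panelB, cms)
    n_bins = int(round(max_distance / bin_width))
    bw_bp = int(round(bin_width * 1e6))
    rA_bins: list[list[float]] = [[] for _ in range(n_bins)]
    rB_bins: list[list[float]] = [[] for _ in range(n_bins)]
    for _, _, d_bp, ra, rb, _, _ in _pair_r_vectors(meta, HA, HB, max_distance):
        idx = d_bp // bw_bp
        for b in np.unique(idx):
            sel = idx == b
            rA_bins[b].extend(ra[sel])
            rB_bins[b].extend(rb[sel])
    lo = np.arange(n_bins) * bin_width
    cor = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        n[b] = len(rA_bins[b])
        if n[b] >= min_pairs:
            cor[b] = phase_correlation(rA_bins[b], rB_bins[b])
    table = pd.DataFrame(
        {"bin_lo": lo, "bin_hi": lo + bin_width, "mid": lo + bin_width / 2,
         "cor_r": cor, "n_pairs": n}
    )
    return PhaseCurve(
        table=table,
        population_pair=(panelA.population_label, panelB.population_label),
        scenario=cms.scenario,
        bin_width=bin_width,
        max_distance=max_distance,
    )


def local_phase(
    panelA: HaplotypePanel,
    panelB: HaplotypePanel,
    cms: CommonMarkerSet,
    N: int = 50,
) -> LocalPhaseTrack:
    """Sliding-window persistence of phase (window of N matched markers, step 1).

    The window correlation is Eq-style Pearson over all N(N−1)/2
    within-window pairs, recorded at the middle matched marker's position.
    Zero-variance windows are flagged NaN.
    """
    if N < 3:
        raise ValueError("window size must be >= 3")
    meta, HA, HB = _aligned(panelA, panelB, cms)
    iu, ju = np.triu_indices(N, k=1)
    records = []
    for chrom, sub in meta.groupby("chrom", sort=False):
        rows = sub.index.to_numpy()
        m = rows.size
        if m < N:
            logger.warning(
                "chromosome %s: %d matched markers < window %d; skipped", chrom, m, N
            )
            continue
        pos = sub["pos"].to_numpy(dtype=np.int64)
        RA = _corr_matrix(HA[rows])
        RB = _corr_matrix(HB[rows])
        for w in range(m - N + 1):
            sl = slice(w, w + N)
            ra = RA[sl, sl][iu, ju]
            rb = RB[sl, sl][iu, ju]
            cor = np.nan
            if ra.std() > 0 and rb.std() > 0:
                cor = float(np.corrcoef(ra, rb)[0, 1])
            records.append(
                {"chrom": chrom, "window": w, "mid_pos": int(pos[w + N // 2]),
                 "cor_r": cor, "n_pairs": ra.size}
            )
    table = pd.DataFrame.from_records(
        records, columns=["chrom", "window", "mid_pos", "cor_r", "n_pairs"]
    )
    return LocalPhaseTrack(
        table=table,
        window_size=N,
        population_pair=(panelA.population_label, panelB.population_label),
        scenario=cms.scenario,
    )
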