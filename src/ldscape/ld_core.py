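"""Pairwise LD from phased haplotypes: signed r and r².

For two biallelic markers with ALT-allele frequencies p_i, p_j and
haplotype-(1,1) frequency p_ij, the signed correlation is

    r = (p_ij - p_i p_j) / sqrt(p_i (1-p_i) p_j (1-p_j)),

and r² = r·r.  Because the panels are phased, p_ij is obtained by direct
haplotype counting — no EM composite-LD approximation.  The sign of r
follows the ALT-allele convention fixed in :mod:`ldscape.genotype_io`,
which is what makes r comparable between populations in the phase module.

Pairs are only ever formed within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, HaplotypePanel

PAIR_COLUMNS = [
    "chrom",
    "i",
    "j",
    "id_i",
    "id_j",
    "pos_i",
    "pos_j",
    "d",
    "r",
    "r2",
]


@dataclass
class LDPairTable:
    """Marker-pair LD records for one population.

    ``pairs`` columns: chrom, i, j (panel-wide marker indices, i < j),
    id_i, id_j, pos_i, pos_j, d (Mb), r, r2.
    """

    pairs: pd.DataFrame
    population_label: str = ""
    max_distance: float | None = None

    def __len__(self) -> int:
        return len(self.pairs)


def _require_complete(panel: HaplotypePanel) -> np.ndarray:
    H = panel.haplotypes
    if (H == MISSING).any():
        raise ValueError(
            "panel contains missing genotypes; run QC / provide complete data"
        )
    return H.astype(np.float64)


def alt_allele_freqs(panel: HaplotypePanel) -> np.ndarray:
    """Frequency of the ALT (code-1) allele per marker; requires complete data."""
    return _require_complete(panel).mean(axis=1)


def signed_r(panel: HaplotypePanel, i: int, j: int) -> tuple[float, float]:
    """(r, r²) for one marker pair from haplotype counts."""
    H = _require_complete(panel)
    hi, hj = H[i], H[j]
    p_i = hi.mean()
    p_j = hj.mean()
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        raise ValueError(f"monomorphic marker in pair ({i}, {j})")
    p_ij = (hi * hj).mean()
    denom = np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
    r = (p_ij - p_i * p_j) / denom
    return float(r), float(r * r)


def _corr_matrix(H: np.ndarray) -> np.ndarray:
    """Signed-r matrix between all marker rows of a complete 0/1 matrix."""
    p = H.mean(axis=1)
    if ((p == 0) | (p == 1)).any():
        bad = np.flatnonzero((p == 0) | (p == 1))
        raise ValueError(f"monomorphic markers present (rows {bad[:5]}...)")
    Z = (H - p[:, None]) / np.sqrt(p * (1 - p))[:, None]
    return (Z @ Z.T) / H.shape[1]


def _chrom_blocks(panel: HaplotypePanel) -> list[tuple[str, np.ndarray]]:
    """Contiguous row-index blocks per chromosome, in panel order."""
    chroms = panel.chroms
    blocks: list[tuple[str, np.ndarray]] = []
    start = 0
    for k in range(1, len(chroms) + 1):
        if k == len(chroms) or chroms[k] != chroms[start]:
            blocks.append((chroms[start], np.arange(start, k)))
            start = k
    return blocks


def _pair_frame(
    panel: HaplotypePanel,
    chrom: str,
    rows: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    r: np.ndarray,
) -> pd.DataFrame:
    gi, gj = rows[ii], rows[jj]
    ids = np.asarray([m.id for m in panel.markers], dtype=object)
    pos = panel.positions
    return pd.DataFrame(
        {
            "chrom": chrom,
            "i": gi,
            "j": gj,
            "id_i": ids[gi],
            "id_j": ids[gj],
            "pos_i": pos[gi],
            "pos_j": pos[gj],
            "d": np.abs(pos[gj] - pos[gi]) / 1e6,
            "r": r,
            "r2": r * r,
        }
    )


def pairwise_ld(panel: HaplotypePanel, max_distance: float = 10.0) -> LDPairTable:
    """All within-chromosome marker pairs with d ≤ ``max_distance`` Mb.

    Deterministic order: (chrom, i, j) ascending with i < j.
    """
    H = _require_complete(panel)
    pos = panel.positions
    frames = []
    for chrom, rows in _chrom_blocks(panel):
        m = rows.size
        if m < 2:
            continue
        R = _corr_matrix(H[rows])
        ii, jj = np.triu_indices(m, k=1)
        d_bp = np.abs(pos[rows][jj] - pos[rows][ii])
        keep = d_bp <= int(round(max_distance * 1e6))
        if not keep.any():
            continue
        frames.append(_pair_frame(panel, chrom, rows, ii[keep], jj[keep], R[ii[keep], jj[keep]]))
    pairs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=PAIR_COLUMNS)
    )
    return LDPairTable(
        pairs=pairs,
        population_label=panel.population_label,
        max_distance=max_distance,
    )


def adjacent_pairs(panel: HaplotypePanel) -> LDPairTable:
    """One LD record per consecutive marker pair within each chromosome."""
    H = _require_complete(panel)
    frames = []
    for chrom, rows in _chrom_blocks(panel):
        m = rows.size
        if m < 2:
            continue
        A, B = H[rows[:-1]], H[rows[1:]]
        pa, pb = A.mean(axis=1), B.mean(axis=1)
        mono = (pa % 1 == 0) | (pb % 1 == 0)
        if mono.any():
            raise ValueError("monomorphic markers present; run QC first")
        p11 = (A * B).mean(axis=1)
        r = (p11 - pa * pb) / np.sqrt(pa * (1 - pa) * pb * (1 - pb))
        ii = np.arange(m - 1)
        frames.append(_pair_frame(panel, chrom, rows, ii, ii + 1, r))
    pairs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=PAIR_COLUMNS)
    )
    return LDPairTable(pairs=pairs, population_label=panel.population_label)
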