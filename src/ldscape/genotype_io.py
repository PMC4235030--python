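"""Phased haplotype panels: the central data model and its file formats.

A :class:`HaplotypePanel` holds a matrix of phased biallelic haplotypes —
one row per marker, two columns per diploid individual — together with the
marker map (chromosome, physical position in bp, REF/ALT alleles).  All LD
statistics in this package are computed from these phased haplotypes by
direct counting, so the panel is the single in-memory container every other
module consumes.

Conventions
-----------
* Allele code 0 is the VCF REF allele, 1 the ALT allele; ``-1`` marks a
  missing allele.  Allele frequencies and the sign of r always refer to the
  ALT (code-1) allele.
* Positions are 1-based (VCF convention).  Inter-marker distances are
  ``|pos_i - pos_j|`` bp, divided by 1e6 when a distance in Mb is needed.
* Markers are kept sorted by (chromosome, position) with a natural
  chromosome order ("2" before "10").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1


def _chrom_key(chrom: str) -> tuple:
    """Natural sort key so chromosome '2' precedes '10'."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with its physical map position."""

    id: str
    chrom: str
    pos: int  # 1-based bp
    allele0: str  # REF
    allele1: str  # ALT

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: position must be >= 1, got {self.pos}")
        if self.allele0 == self.allele1:
            raise ValueError(f"marker {self.id}: alleles must differ")


@dataclass
class HaplotypePanel:
    """Phased haplotypes for one population.

    ``haplotypes`` has shape (n_markers, 2 * n_samples), dtype int8, values
    in {0, 1, -1}; columns (2k, 2k+1) are the two haplotypes of sample k.
    """

    markers: list[Marker]
    haplotypes: np.ndarray
    sample_ids: list[str]
    population_label: str = ""

    # ------------------------------------------------------------------ basic
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([m.pos for m in self.markers], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.asarray([m.chrom for m in self.markers], dtype=object)

    def chromosomes(self) -> list[str]:
        """Distinct chromosomes in natural order."""
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.chrom, None)
        return sorted(seen, key=_chrom_key)

    def has_missing(self) -> bool:
        return bool((self.haplotypes == MISSING).any())

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [m.id for m in self.markers],
                "chrom": [m.chrom for m in self.markers],
                "pos": self.positions,
                "allele0": [m.allele0 for m in self.markers],
                "allele1": [m.allele1 for m in self.markers],
            }
        )

    # -------------------------------------------------------------- validation
    def validate(self) -> None:
        H = self.haplotypes
        if H.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if H.shape[0] != self.n_markers:
            raise ValueError(
                f"{H.shape[0]} haplotype rows but {self.n_markers} markers"
            )
        if H.shape[1] != 2 * self.n_samples:
            raise ValueError(
                f"{H.shape[1]} haplotype columns but {self.n_samples} samples"
            )
        if H.shape[1] % 2 != 0:
            raise ValueError("haplotype column count must be even")
        codes = np.unique(H)
        if not np.isin(codes, (MISSING, 0, 1)).all():
            raise ValueError(f"invalid allele codes: {codes}")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids are not unique")
        keys = [(_chrom_key(m.chrom), m.pos) for m in self.markers]
        if any(a > b for a, b in zip(keys, keys[1:])):
            raise ValueError("markers are not sorted by (chrom, pos)")

    # ----------------------------------------------------------------- subsets
    def subset_markers(self, index: Sequence[int] | np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index, dtype=np.intp)
        return HaplotypePanel(
            markers=[self.markers[i] for i in index],
            haplotypes=self.haplotypes[index].copy(),
            sample_ids=list(self.sample_ids),
            population_label=self.population_label,
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index, dtype=np.intp)
        cols = np.empty(2 * index.size, dtype=np.intp)
        cols[0::2] = 2 * index
        cols[1::2] = 2 * index + 1
        return HaplotypePanel(
            markers=list(self.markers),
            haplotypes=self.haplotypes[:, cols].copy(),
            sample_ids=[self.sample_ids[i] for i in index],
            population_label=self.population_label,
        )

    def sorted(self) -> "HaplotypePanel":
        order = sorted(
            range(self.n_markers),
            key=lambda i: (_chrom_key(self.markers[i].chrom), self.markers[i].pos),
        )
        if order == list(range(self.n_markers)):
            return self
        return self.subset_markers(order)

    def genotype_counts(self, row: int) -> tuple[int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt) over samples with both alleles called."""
        h = self.haplotypes[row]
        a, b = h[0::2], h[1::2]
        called = (a != MISSING) & (b != MISSING)
        g = a[called] + b[called]
        return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.haplotypes, other.haplotypes)
        )


# ---------------------------------------------------------------------- VCF IO

def read_phased_vcf(path: str | Path, population_label: str = "") -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel`.

    Only biallelic SNP records with fully phased called genotypes are
    retained; multiallelic, non-SNP and records containing an unphased
    called genotype are skipped (counts logged).  Missing genotypes
    (``.|.`` or ``./.``) are allowed and coded ``-1``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{path}: VCF contains no samples")

    markers: list[Marker] = []
    rows: list[np.ndarray] = []
    n_multi = n_unphased = 0
    seen_ids: set[str] = set()
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_multi += 1
            continue
        row = np.empty(2 * len(sample_ids), dtype=np.int8)
        unphased = False
        for k, g in enumerate(v.genotypes):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                row[2 * k] = row[2 * k + 1] = MISSING
                continue
            if not g[2]:  # called but unphased
                unphased = True
                break
            row[2 * k] = a0
            row[2 * k + 1] = a1
        if unphased:
            n_unphased += 1
            continue
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        if mid in seen_ids:
            mid = f"{mid}_dup{len(markers)}"
        seen_ids.add(mid)
        markers.append(
            Marker(id=mid, chrom=v.CHROM, pos=v.POS, allele0=v.REF, allele1=v.ALT[0])
        )
        rows.append(row)

    if n_multi:
        logger.info("%s: skipped %d multiallelic/non-SNP records", path, n_multi)
    if n_unphased:
        logger.info("%s: skipped %d records with unphased genotypes", path, n_unphased)
    if not markers:
        raise ValueError(
            f"{path}: no phased biallelic SNP records retained "
            f"({n_multi} multiallelic/non-SNP, {n_unphased} unphased skipped)"
        )
    panel = HaplotypePanel(
        markers=markers,
        haplotypes=np.vstack(rows),
        sample_ids=sample_ids,
        population_label=population_label,
    ).sorted()
    panel.validate()
    return panel


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> Path:
    """Write a panel as a phased VCF 4.2 file (inverse of :func:`read_phased_vcf`)."""
    if panel.n_markers == 0:
        raise ValueError("cannot write empty panel (no markers)")
    if panel.n_samples == 0:
        raise ValueError("cannot write empty panel (no samples)")
    path = Path(path)
    H = panel.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldscape\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for i, m in enumerate(panel.markers):
            gts = []
            row = H[i]
            for k in range(panel.n_samples):
                a, b = row[2 * k], row[2 * k + 1]
                if a == MISSING or b == MISSING:
                    gts.append(".|.")
                else:
                    gts.append(f"{a}|{b}")
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.id}\t{m.allele0}\t{m.allele1}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


# ------------------------------------------------------------------- pedigree

def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a 3-column pedigree TSV (individual, sire, dam; unknown parent "0").

    Returns a DataFrame indexed by individual id with columns ``sire`` and
    ``dam`` (None where unknown).  A header row naming the columns is
    accepted but not required.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 3:
        raise ValueError(f"{path}: pedigree must have 3 columns, got {df.shape[1]}")
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if first[0] in ("individual", "id", "animal"):
        df = df.iloc[1:].reset_index(drop=True)
    df.columns = ["individual", "sire", "dam"]
    for col in ("sire", "dam"):
        df[col] = df[col].where(~df[col].isin(["0", "", "NA"]), None)
    if df["individual"].duplicated().any():
        dups = df["individual"][df["individual"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate individual ids in pedigree: {dups}")
    return df.set_index("individual")


# ------------------------------------------------------------ result table IO

def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write a result table as TSV with '#key=value' provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"#{key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
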