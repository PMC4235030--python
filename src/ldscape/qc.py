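"""Sample and SNP quality control for haplotype panels.

Filtering pipeline (in this order):

1. samples with a missing-genotype fraction above 10% are dropped;
2. markers are dropped by the first failing rule among
   call rate < 0.90  →  MAF < 0.05  →  HWE exact p < 1e-7;
3. family structure is removed from the sample list: parents of sampled
   animals are excluded, then one animal is kept at random per full-sib
   group.

The HWE test is the exact conditional test (probability of the observed
heterozygote count given the allele counts), not the chi-square
approximation: the 1e-7 threshold operates far in the tail where the
chi-square is unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Counts of what a QC step removed and the thresholds it used."""

    n_samples_in: int
    n_samples_out: int
    n_markers_in: int
    n_markers_out: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_samples_in", self.n_samples_in),
            ("n_samples_out", self.n_samples_out),
            ("n_markers_in", self.n_markers_in),
            ("n_markers_out", self.n_markers_out),
        ]
        rows += [(f"removed_{k}", v) for k, v in self.removed_by_rule.items()]
        rows += [(f"threshold_{k}", v) for k, v in self.thresholds.items()]
        return pd.DataFrame(rows, columns=["key", "value"])


# --------------------------------------------------------------------- samples

def filter_samples_by_missingness(
    panel: HaplotypePanel, max_missing_frac: float = 0.10
) -> tuple[HaplotypePanel, QCReport]:
    """Drop individuals missing genotypes at more than ``max_missing_frac`` of markers."""
    H = panel.haplotypes
    a, b = H[:, 0::2], H[:, 1::2]
    miss = ((a == MISSING) | (b == MISSING)).mean(axis=0)
    keep = np.flatnonzero(miss <= max_missing_frac)
    if keep.size == 0:
        raise ValueError("all samples removed by missingness filter")
    out = panel.subset_samples(keep)
    report = QCReport(
        n_samples_in=panel.n_samples,
        n_samples_out=keep.size,
        n_markers_in=panel.n_markers,
        n_markers_out=panel.n_markers,
        removed_by_rule={"sample_missingness": panel.n_samples - keep.size},
        thresholds={"max_missing_frac": max_missing_frac},
    )
    logger.info(
        "sample missingness filter: %d -> %d samples", panel.n_samples, keep.size
    )
    return out, report


# --------------------------------------------------------------------- markers

def _marker_stats(panel: HaplotypePanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (call_rate, maf, genotype counts [nAA, nAa, naa]).

    Genotype-level statistics treat a sample as called only when both of
    its alleles are called; allele frequencies use the called genotypes.
    """
    H = panel.haplotypes
    a, b = H[:, 0::2], H[:, 1::2]
    called = (a != MISSING) & (b != MISSING)
    n_called = called.sum(axis=1)
    call_rate = n_called / panel.n_samples
    g = np.where(called, a + b, 0)
    alt = (g * called).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, alt / (2 * n_called), np.nan)
    maf = np.minimum(p_alt, 1 - p_alt)
    n_het = ((g == 1) & called).sum(axis=1)
    n_hom_alt = ((g == 2) & called).sum(axis=1)
    n_hom_ref = n_called - n_het - n_hom_alt
    counts = np.stack([n_hom_ref, n_het, n_hom_alt], axis=1)
    return call_rate, maf, counts


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy–Weinberg test p-value.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count.  Monomorphic markers return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-allele bookkeeping handled below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    # het counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # P(het = h | n_A, n_a) ∝ 2^h * n! / (hom_common! h! hom_rare!)
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_common + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_Aa][0]
    pval = p[p <= p_obs * (1 + 1e-12)].sum()
    return float(min(pval, 1.0))


def filter_markers(
    panel: HaplotypePanel,
    min_call_rate: float = 0.90,
    min_maf: float = 0.05,
    hwe_p_threshold: float = 1e-7,
) -> tuple[HaplotypePanel, QCReport]:
    """Drop markers failing call rate, MAF, or HWE (attributed in that order).

    MAF exactly at ``min_maf`` is kept (the rule removes markers *below*
    the threshold).
    """
    call_rate, maf, counts = _marker_stats(panel)
    removed = {"call_rate": 0, "maf": 0, "hwe": 0}
    keep_idx = []
    for i in range(panel.n_markers):
        if call_rate[i] < min_call_rate:
            removed["call_rate"] += 1
        elif np.isnan(maf[i]) or maf[i] < min_maf - 1e-12:
            removed["maf"] += 1
        elif hwe_exact_test(*counts[i]) < hwe_p_threshold:
            removed["hwe"] += 1
        else:
            keep_idx.append(i)
    if not keep_idx:
        raise ValueError("all markers removed by marker filters")
    out = panel.subset_markers(np.asarray(keep_idx))
    report = QCReport(
        n_samples_in=panel.n_samples,
        n_samples_out=panel.n_samples,
        n_markers_in=panel.n_markers,
        n_markers_out=len(keep_idx),
        removed_by_rule=removed,
        thresholds={
            "min_call_rate": min_call_rate,
            "min_maf": min_maf,
            "hwe_p_threshold": hwe_p_threshold,
        },
    )
    logger.info(
        "marker filters: %d -> %d markers (call_rate %d, maf %d, hwe %d)",
        panel.n_markers,
        len(keep_idx),
        removed["call_rate"],
        removed["maf"],
        removed["hwe"],
    )
    return out, report


# -------------------------------------------------------------------- pedigree

def prune_relatives(
    sample_ids: list[str], pedigree: pd.DataFrame, seed: int
) -> list[str]:
    """Remove family structure from a sample list.

    Any sample that is recorded as sire or dam of another sample is removed
    first; then, among the remaining samples, full-sib groups (identical
    known sire *and* dam) are reduced to one member chosen uniformly at
    random with the given seed.  Samples absent from the pedigree are
    treated as founders with unknown parents.  Order of the input list is
    preserved.
    """
    in_panel = set(sample_ids)
    parents_of_samples: set[str] = set()
    for sid in sample_ids:
        if sid in pedigree.index:
            sire = pedigree.at[sid, "sire"]
            dam = pedigree.at[sid, "dam"]
            if sire is not None:
                parents_of_samples.add(str(sire))
            if dam is not None:
                parents_of_samples.add(str(dam))
    kept = [s for s in sample_ids if s not in parents_of_samples]

    groups: dict[tuple[str, str], list[str]] = {}
    singles: list[str] = []
    for sid in kept:
        sire = dam = None
        if sid in pedigree.index:
            sire = pedigree.at[sid, "sire"]
            dam = pedigree.at[sid, "dam"]
        if sire is None or dam is None:
            singles.append(sid)
        else:
            groups.setdefault((str(sire), str(dam)), []).append(sid)

    rng = np.random.default_rng(seed)
    chosen: set[str] = set(singles)
    for key in sorted(groups):
        members = groups[key]
        chosen.add(members[int(rng.integers(len(members)))])
    return [s for s in kept if s in chosen]


def apply_qc(
    panel: HaplotypePanel,
    pedigree: pd.DataFrame | None = None,
    max_missing_frac: float = 0.10,
    min_call_rate: float = 0.90,
    min_maf: float = 0.05,
    hwe_p_threshold: float = 1e-7,
    seed: int = 0,
    strict: bool = False,
) -> tuple[HaplotypePanel, QCReport]:
    """Full QC: sample missingness → marker rules → relative pruning.

    With ``strict=True`` a panel that still contains missing genotypes
    after QC is rejected — downstream LD estimation requires complete,
    phased haplotypes.
    """
    panel1, rep_s = filter_samples_by_missingness(panel, max_missing_frac)
    if pedigree is not None and len(pedigree):
        kept_ids = prune_relatives(panel1.sample_ids, pedigree, seed)
        idx = [panel1.sample_ids.index(s) for s in kept_ids]
        n_pruned = panel1.n_samples - len(idx)
        panel1 = panel1.subset_samples(np.asarray(idx, dtype=np.intp))
        rep_s.removed_by_rule["relatives"] = n_pruned
        rep_s.n_samples_out = panel1.n_samples
    panel2, rep_m = filter_markers(panel1, min_call_rate, min_maf, hwe_p_threshold)
    if strict and panel2.has_missing():
        raise ValueError(
            "panel still contains missing genotypes after QC; "
            "LD estimation requires complete phased haplotypes"
        )
    report = QCReport(
        n_samples_in=panel.n_samples,
        n_samples_out=panel2.n_samples,
        n_markers_in=panel.n_markers,
        n_markers_out=panel2.n_markers,
        removed_by_rule={**rep_s.removed_by_rule, **rep_m.removed_by_rule},
        thresholds={**rep_s.thresholds, **rep_m.thresholds},
    )
    return panel2, report
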