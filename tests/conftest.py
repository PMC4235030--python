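"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ldscape.genotype_io import HaplotypePanel, Marker


def make_panel(
    haplotypes: np.ndarray,
    positions: list[int] | np.ndarray,
    chroms: list[str] | None = None,
    label: str = "test",
) -> HaplotypePanel:
    """Panel from an explicit (markers x haplotypes) 0/1 matrix."""
    H = np.asarray(haplotypes, dtype=np.int8)
    m = H.shape[0]
    chroms = chroms or ["1"] * m
    markers = [
        Marker(id=f"m{k}", chrom=chroms[k], pos=int(positions[k]), allele0="A", allele1="G")
        for k in range(m)
    ]
    n_samples = H.shape[1] // 2
    panel = HaplotypePanel(
        markers=markers,
        haplotypes=H,
        sample_ids=[f"s{k}" for k in range(n_samples)],
        population_label=label,
    )
    panel.validate()
    return panel


def random_polymorphic_panel(
    rng: np.random.Generator, n_markers: int, n_haplotypes: int, span_bp: int = 5_000_000
) -> HaplotypePanel:
    """Random complete panel with every marker polymorphic (for oracles)."""
    H = rng.integers(0, 2, size=(n_markers, n_haplotypes)).astype(np.int8)
    p = H.mean(axis=1)
    for row in np.flatnonzero((p == 0) | (p == 1)):
        H[row, rng.integers(n_haplotypes)] ^= 1  # force polymorphism
    pos = np.sort(rng.choice(np.arange(1, span_bp), size=n_markers, replace=False))
    return make_panel(H, pos)


def brute_force_r(h_i: np.ndarray, h_j: np.ndarray) -> tuple[float, float]:
    """Independent counting implementation of haplotype-based signed r and r².

    Pure-Python tally of the four haplotype classes, kept deliberately
    separate from the package's vectorized path.
    """
    n = len(h_i)
    n11 = sum(1 for a, b in zip(h_i, h_j) if a == 1 and b == 1)
    n1_ = sum(1 for a in h_i if a == 1)
    n_1 = sum(1 for b in h_j if b == 1)
    p_i, p_j, p_ij = n1_ / n, n_1 / n, n11 / n
    denom = (p_i * (1 - p_i) * p_j * (1 - p_j)) ** 0.5
    r = (p_ij - p_i * p_j) / denom
    return r, r * r


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
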