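"""Synthetic multi-breed SNP haplotype panels with controllable LD structure.

Three generators, all deterministic under a fixed seed:

* :func:`gen_glm_pairs` — distribution-level (d, r²) samples with
  Gamma-distributed r² around the decay law E(r²) = 1/(1 + αd), for
  exercising the GLM fitter against a known truth.
* :func:`gen_mosaic_population` — a founder-mosaic haplotype panel: each
  sample haplotype is a recombinant patchwork of K founder haplotypes,
  switching founders between consecutive markers with probability
  1 − exp(−ρ·Δd), Δd in Mb.  K plays the role of an effective founder
  pool (background r² ≈ 1/K at long range) and ρ of a per-Mb
  recombination intensity, so within-population LD decays with physical
  distance at a controllable rate.
* :func:`gen_diverged_populations` — daughter populations evolved
  independently from one mosaic base by t generations of Wright–Fisher
  reproduction (drift + recombination, no mutation), giving a divergence
  knob for persistence of LD phase while keeping markers matched across
  populations by construction.

The mosaic model is deliberately not a coalescent simulator: it is
O(markers × haplotypes), its knobs map directly onto the quantities the
analysis estimates, and it is sufficient for decay/phase monotonicity and
end-to-end pipeline tests.  Exact recovery of α is tested at the
distribution level with gen_glm_pairs instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import HaplotypePanel, Marker

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Parameters of the mosaic simulator.

    Defaults emulate a desk-scale single-chromosome SNP panel: 3,000
    markers on a 300-Mb chromosome (pig chromosome 1 scale, ~100 kb mean
    spacing), recombination intensity ρ = 1 founder switch per Mb, and 100
    diploid individuals per population drawn from a Wright–Fisher pool of
    Ne = 100.  The founder pool K = 4 sets the short-range LD ceiling
    (r² ≈ 1/(K−1) for tightly linked pairs): a small pool emulates the
    strong within-breed LD of intensively selected livestock; about
    2·0.5^K of markers come out monomorphic and are dropped.
    """

    n_markers: int = 3000
    chrom_length_bp: int = 300_000_000
    chrom: str = "1"
    spacing: str = "uniform"  # or "exponential"
    spacing_mean_kb: float | None = None  # only for exponential spacing
    n_founders: int = 4
    rho: float = 1.0  # expected founder switches per Mb (accumulated history)
    c_per_mb: float = 0.01  # per-meiosis crossover rate (1 cM/Mb) for WF drift
    n_individuals: int = 100
    ne: int = 100  # Wright-Fisher diploid size for divergence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.rho < 0 or self.c_per_mb < 0:
            raise ValueError("recombination intensity must be >= 0")
        if min(self.n_markers, self.chrom_length_bp, self.n_individuals, self.ne) < 1:
            raise ValueError("counts must be positive")
        if self.spacing not in ("uniform", "exponential"):
            raise ValueError(f"unknown spacing model {self.spacing!r}")
        if self.n_individuals > self.ne:
            raise ValueError("cannot sample more individuals than the Wright-Fisher size")


def gen_glm_pairs(
    alpha: float,
    n: int,
    d_range: tuple[float, float] = (0.01, 10.0),
    gamma_shape: float = 1.0,
    seed: int = 0,
    noise_free: bool = False,
) -> pd.DataFrame:
    """(d, r2) samples with E(r² | d) = 1/(1 + αd).

    Distances are uniform on ``d_range``; r² is Gamma with shape
    ``gamma_shape`` and mean 1/(1 + αd).  ``noise_free=True`` is the
    shape → ∞ limit: r² equals its conditional mean exactly.
    """
    lo, hi = d_range
    if not (0 <= lo < hi):
        raise ValueError(f"invalid distance range {d_range}")
    if 1.0 + alpha * lo <= 0 or 1.0 + alpha * hi <= 0:
        raise ValueError("1 + alpha*d must stay positive over d_range")
    if gamma_shape <= 0:
        raise ValueError("gamma shape must be positive")
    rng = np.random.default_rng(seed)
    d = rng.uniform(lo, hi, size=n)
    mean = 1.0 / (1.0 + alpha * d)
    if noise_free:
        r2 = mean
    else:
        r2 = rng.gamma(shape=gamma_shape, scale=mean / gamma_shape, size=n)
    return pd.DataFrame({"d": d, "r2": r2})


# --------------------------------------------------------------------- helpers

def _positions(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.spacing == "uniform":
        L, n = spec.chrom_length_bp, spec.n_markers
        if L < n:
            raise ValueError("chromosome too short for requested marker count")
        cand = np.unique(rng.integers(1, L + 1, size=4 * n))
        while cand.size < n:  # only when L barely exceeds n
            extra = rng.integers(1, L + 1, size=4 * n)
            cand = np.unique(np.concatenate([cand, extra]))
        return np.sort(rng.choice(cand, size=n, replace=False)).astype(np.int64)
    mean_bp = (spec.spacing_mean_kb or spec.chrom_length_bp / spec.n_markers / 1e3) * 1e3
    gaps = np.maximum(1, rng.exponential(mean_bp, size=spec.n_markers)).astype(np.int64)
    pos = 1 + np.cumsum(gaps)
    return pos


def _switch_probs(pos: np.ndarray, rho: float) -> np.ndarray:
    gaps_mb = np.diff(pos) / 1e6
    return 1.0 - np.exp(-rho * gaps_mb)


def _mosaic_haplotypes(
    founders: np.ndarray, n_haplotypes: int, psw: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Recombinant founder mosaics: (m, n_haplotypes) int8 matrix."""
    K, m = founders.shape
    H = np.empty((m, n_haplotypes), dtype=np.int8)
    f = rng.integers(0, K, size=n_haplotypes)
    H[0] = founders[f, 0]
    for k in range(1, m):
        sw = rng.random(n_haplotypes) < psw[k - 1]
        n_sw = int(sw.sum())
        if n_sw:
            f[sw] = rng.integers(0, K, size=n_sw)
        H[k] = founders[f, k]
    return H


def _markers_from_positions(pos: np.ndarray, chrom: str) -> list[Marker]:
    return [
        Marker(id=f"snp_{chrom}_{p}", chrom=chrom, pos=int(p), allele0="A", allele1="G")
        for p in pos
    ]


def _drop_monomorphic(
    pos: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    p = H.mean(axis=1)
    keep = (p > 0) & (p < 1)
    return pos[keep], H[keep], int((~keep).sum())


def gen_mosaic_population(spec: SyntheticSpec) -> HaplotypePanel:
    """One population of founder-mosaic phased diploids.

    Founder haplotypes are i.i.d. Bernoulli(0.5) per site; each of the
    2·n_individuals sample haplotypes copies a founder, switching to a
    uniformly chosen founder between consecutive markers with probability
    1 − exp(−ρ·Δd).  Markers monomorphic in the sample are dropped (count
    logged).
    """
    rng = np.random.default_rng(spec.seed)
    pos = _positions(spec, rng)
    founders = rng.integers(0, 2, size=(spec.n_founders, pos.size), dtype=np.int8)
    psw = _switch_probs(pos, spec.rho)
    H = _mosaic_haplotypes(founders, 2 * spec.n_individuals, psw, rng)
    pos, H, n_mono = _drop_monomorphic(pos, H)
    if n_mono:
        logger.info("dropped %d monomorphic markers from mosaic panel", n_mono)
    panel = HaplotypePanel(
        markers=_markers_from_positions(pos, spec.chrom),
        haplotypes=H,
        sample_ids=[f"ind{k:04d}" for k in range(spec.n_individuals)],
        population_label="sim",
    )
    panel.validate()
    return panel


def _wf_generation(
    H: np.ndarray, psw: np.ndarray, ne: int, rng: np.random.Generator
) -> np.ndarray:
    """One Wright–Fisher generation: 2·ne recombinant gametes from ne diploids."""
    m, _ = H.shape
    n_gam = 2 * ne
    parent = rng.integers(0, ne, size=n_gam)
    start = rng.integers(0, 2, size=n_gam)
    switches = rng.random((m - 1, n_gam)) < psw[:, None]
    path = np.empty((m, n_gam), dtype=np.int64)
    path[0] = start
    np.cumsum(switches, axis=0, out=path[1:])
    path[1:] += start
    path &= 1
    cols = 2 * parent[None, :] + path
    return np.take_along_axis(H, cols, axis=1).astype(np.int8)


def gen_diverged_populations(
    spec: SyntheticSpec, split_design: list[tuple[str, int]]
) -> list[HaplotypePanel]:
    """Daughter populations drifted independently from one mosaic base.

    Each (label, t) entry evolves the base Wright–Fisher pool (size
    ``spec.ne`` diploids) for t generations of drift + recombination at
    the per-meiosis rate ``spec.c_per_mb`` (no mutation, so markers stay
    matched across populations), then samples
    ``spec.n_individuals`` diploids without replacement.  t = 0 reduces to
    resampling the base itself.  Population streams are independent
    substreams of ``spec.seed``.
    """
    if spec.ne < 2:
        raise ValueError("Wright-Fisher size must be >= 2")
    if any(t < 0 for _, t in split_design):
        raise ValueError("split times must be >= 0")
    root = np.random.SeedSequence(spec.seed)
    base_ss, *pop_ss = root.spawn(1 + len(split_design))
    rng = np.random.default_rng(base_ss)
    pos = _positions(spec, rng)
    founders = rng.integers(0, 2, size=(spec.n_founders, pos.size), dtype=np.int8)
    psw = _switch_probs(pos, spec.rho)
    base = _mosaic_haplotypes(founders, 2 * spec.ne, psw, rng)
    pos, base, n_mono = _drop_monomorphic(pos, base)
    if n_mono:
        logger.info("dropped %d markers monomorphic in the base population", n_mono)
    # drift generations recombine at the per-meiosis rate (~1 cM/Mb), not at
    # the accumulated mosaic intensity rho
    psw_meiosis = _switch_probs(pos, spec.c_per_mb)
    markers = _markers_from_positions(pos, spec.chrom)

    panels = []
    for (label, t), ss in zip(split_design, pop_ss):
        prng = np.random.default_rng(ss)
        H = base
        for _ in range(int(t)):
            H = _wf_generation(H, psw_meiosis, spec.ne, prng)
        ind = np.sort(prng.choice(spec.ne, size=spec.n_individuals, replace=False))
        cols = np.empty(2 * ind.size, dtype=np.intp)
        cols[0::2] = 2 * ind
        cols[1::2] = 2 * ind + 1
        panel = HaplotypePanel(
            markers=list(markers),
            haplotypes=H[:, cols].copy(),
            sample_ids=[f"{label}_ind{k:04d}" for k in range(spec.n_individuals)],
            population_label=label,
        )
        panel.validate()
        panels.append(panel)
    return panels


def spec_echo(spec: SyntheticSpec) -> pd.DataFrame:
    """Simulator parameters as a two-column table (for provenance output)."""
    return pd.DataFrame(
        [(k, v) for k, v in spec.__dict__.items()], columns=["parameter", "value"]
    )
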