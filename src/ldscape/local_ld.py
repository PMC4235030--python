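"""Local LD maps: the Gamma GLM E(r²) = 1/(1 + αd) in sliding windows.

Sved's drift model for an isolated randomly mating population gives
E(r²) = 1/(1 + 4cNe) at recombination fraction c and effective size Ne.
Replacing 4cNe by α·d — with d the physical distance in Mb — folds the
local recombination rate and local effective population size into one
decay-rate parameter α, estimable from marker data alone.  α is fitted as
a generalized linear model with Gamma-distributed r² and inverse link,

    η = 1 + α·d,   E(r²) = 1/η,

with the intercept *fixed* at 1 (the model has no free intercept: r² → 1
as d → 0).  Marker pairs with r² = 0 are excluded before fitting.

The LD map slides a window of N consecutive markers one marker at a time
along each chromosome, fits α on all N(N−1)/2 within-window pairs, and
records α̂ — plus the more interpretable transform 1/(1 + α̂·d) at a fixed
moderate distance d — at the middle marker's position.  A chromosome-level
α is estimated by repeatedly subsampling pairs (10,000 pairs × 1,000
replicates by default) and averaging the replicate fits.

The single-parameter fit solves the Gamma score equation
Σ d_k (1/η_k − r²_k) = 0, which is strictly decreasing in α on the feasible
region α > −1/d_max, by safeguarded Newton iterations (bisection fallback
inside a maintained bracket).  The Gamma shape parameter cancels from the
point estimate; a Pearson moment estimate of the dispersion enters only
the standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .genotype_io import HaplotypePanel
from .ld_core import _chrom_blocks, _corr_matrix, _require_complete

logger = logging.getLogger(__name__)

ZERO_R2_TOL = 1e-12  # guard for "r² = 0 pairs are excluded"


@dataclass
class AlphaFit:
    """One fitted decay rate α̂ (per Mb) with convergence metadata."""

    alpha_hat: float
    std_err: float
    converged: bool
    n_used: int
    deviance: float
    intercept: float = 1.0  # ≠ 1 only for the free-intercept diagnostic fit


@dataclass
class LDMapTrack:
    """Sliding-window α̂ and expected r² at a fixed distance.

    ``table`` columns: chrom, window (0-based per chromosome), mid_id,
    mid_pos (bp), alpha_hat, std_err, expected_r2, converged, n_used.
    """

    table: pd.DataFrame
    window_size: int
    d_fixed: float
    population_label: str = ""


@dataclass
class ChromosomeAlpha:
    """Replicate-subsampled chromosome-level α̂ (mean and sd over replicates)."""

    chrom: str
    mean_alpha: float
    sd_alpha: float
    n_pairs_per_replicate: int
    n_replicates: int
    seed: int
    alphas: np.ndarray | None = None


# ------------------------------------------------------------------ model form

def expected_r2(alpha: float, d):
    """E(r²) = 1/(1 + αd); requires 1 + αd > 0."""
    d = np.asarray(d, dtype=float)
    eta = 1.0 + alpha * d
    if np.any(eta <= 0):
        raise ValueError(f"1 + alpha*d must be positive (alpha={alpha})")
    out = 1.0 / eta
    return float(out) if out.ndim == 0 else out


def sved_expected_r2(c: float, Ne: float):
    """Sved's drift expectation E(r²) = 1/(1 + 4·c·Ne)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("recombination fraction must be nonnegative")
    if Ne <= 0:
        raise ValueError("effective population size must be positive")
    out = 1.0 / (1.0 + 4.0 * c * Ne)
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------------------------ the fitter

def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


def fit_alpha(
    d: Sequence[float],
    r2: Sequence[float],
    free_intercept: bool = False,
    alpha_max: float = 1e4,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlphaFit:
    """Fit α in E(r²) = 1/(1 + αd) by Gamma maximum likelihood.

    Pairs with r² = 0 (within a 1e-12 guard) are excluded; at least two
    usable pairs at two distinct distances are required.  Negative α̂ (LD
    rising with distance in a window) is returned as-is, never clamped.
    ``free_intercept=True`` fits η = β₀ + αd instead — a diagnostic only.
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(r2, dtype=float)
    if d.shape != y.shape:
        raise ValueError("d and r2 must have equal length")
    use = y > ZERO_R2_TOL
    d, y = d[use], y[use]
    n = y.size
    if n < 2:
        raise ValueError(f"need >= 2 pairs with r² > 0, got {n}")
    if np.unique(d).size < 2:
        raise ValueError("need >= 2 distinct distances")
    if free_intercept:
        return _fit_free_intercept(d, y, n)

    d_max = d.max()
    lo = (-1.0 + 1e-9) / d_max  # keep every η strictly positive
    hi = alpha_max

    def score(a: float) -> float:
        return float(np.sum(d * (1.0 / (1.0 + a * d) - y)))

    f_lo, f_hi = score(lo), score(hi)
    if f_lo <= 0.0:  # score decreasing: root at/below the feasible boundary
        return _finish(lo, d, y, n, converged=False)
    if f_hi >= 0.0:  # decay faster than the bracket allows
        return _finish(hi, d, y, n, converged=False)

    # moment start: solve 1/(1 + α d̄) = ȳ
    a = float(np.clip((1.0 / y.mean() - 1.0) / d.mean(), lo + 1e-12, hi - 1e-12))
    blo, bhi = lo, hi  # bracket with score(blo) > 0 > score(bhi)
    converged = False
    for _ in range(max_iter):
        eta = 1.0 + a * d
        f = float(np.sum(d * (1.0 / eta - y)))
        if f > 0:
            blo = a
        else:
            bhi = a
        fp = -float(np.sum((d / eta) ** 2))
        step = -f / fp
        a_new = a + step
        if not (blo < a_new < bhi):
            a_new = 0.5 * (blo + bhi)  # bisection fallback
        if abs(a_new - a) < tol:
            a = a_new
            converged = True
            break
        a = a_new
    return _finish(a, d, y, n, converged=converged)


def _finish(a: float, d: np.ndarray, y: np.ndarray, n: int, converged: bool) -> AlphaFit:
    eta = 1.0 + a * d
    mu = 1.0 / eta
    pearson = np.sum(((y - mu) / mu) ** 2)
    dispersion = pearson / max(n - 1, 1)
    info = np.sum((d / eta) ** 2)
    se = float(np.sqrt(dispersion / info)) if info > 0 else np.nan
    return AlphaFit(
        alpha_hat=float(a),
        std_err=se,
        converged=converged,
        n_used=n,
        deviance=_gamma_deviance(y, mu),
    )


def _fit_free_intercept(d: np.ndarray, y: np.ndarray, n: int) -> AlphaFit:
    """Diagnostic two-parameter fit η = β₀ + αd by Gamma deviance minimization."""

    def nll(theta: np.ndarray) -> float:
        eta = theta[0] + theta[1] * d
        if np.any(eta <= 0):
            return np.inf
        # Gamma log-likelihood kernel (shape cancels at the optimum)
        return float(np.sum(y * eta - np.log(eta)))

    a0 = max((1.0 / y.mean() - 1.0) / d.mean(), (-1.0 + 1e-6) / d.max())
    res = minimize(nll, x0=np.array([1.0, a0]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    b0, a = res.x
    eta = b0 + a * d
    mu = 1.0 / eta
    return AlphaFit(
        alpha_hat=float(a),
        std_err=np.nan,
        converged=bool(res.success),
        n_used=n,
        deviance=_gamma_deviance(y, mu),
        intercept=float(b0),
    )


# ----------------------------------------------------------------- sliding map

def ld_map(
    panel: HaplotypePanel,
    N: int = 100,
    d_fixed: float = 10.0,
    free_intercept: bool = False,
) -> LDMapTrack:
    """Sliding-window LD map: α̂ per window of N markers, step one marker.

    Each chromosome with at least N markers contributes m − N + 1 windows;
    shorter chromosomes are skipped with a warning.  The window's record is
    placed at its middle marker (index ⌊N/2⌋ within the window).
    expected_r2 is 1/(1 + α̂·d_fixed), NaN when 1 + α̂·d_fixed ≤ 0 or the
    window fit failed.
    """
    if N < 3:
        raise ValueError("window size must be >= 3")
    H = _require_complete(panel)
    pos = panel.positions
    ids = [m.id for m in panel.markers]
    iu, ju = np.triu_indices(N, k=1)
    records = []
    for chrom, rows in _chrom_blocks(panel):
        m = rows.size
        if m < N:
            logger.warning(
                "chromosome %s has %d markers < window size %d; skipped", chrom, m, N
            )
            continue
        R = _corr_matrix(H[rows])
        cpos = pos[rows]
        for w in range(m - N + 1):
            sl = slice(w, w + N)
            r2 = R[sl, sl][iu, ju] ** 2
            dwin = np.abs(cpos[sl][ju] - cpos[sl][iu]) / 1e6
            mid = rows[w + N // 2]
            rec = {
                "chrom": chrom,
                "window": w,
                "mid_id": ids[mid],
                "mid_pos": int(pos[mid]),
            }
            try:
                fit = fit_alpha(dwin, r2, free_intercept=free_intercept)
                a = fit.alpha_hat
                ok = fit.converged and (1.0 + a * d_fixed) > 0
                rec.update(
                    alpha_hat=a,
                    std_err=fit.std_err,
                    expected_r2=1.0 / (1.0 + a * d_fixed) if ok else np.nan,
                    converged=fit.converged,
                    n_used=fit.n_used,
                )
            except ValueError:
                rec.update(
                    alpha_hat=np.nan,
                    std_err=np.nan,
                    expected_r2=np.nan,
                    converged=False,
                    n_used=0,
                )
            records.append(rec)
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "chrom", "window", "mid_id", "mid_pos",
            "alpha_hat", "std_err", "expected_r2", "converged", "n_used",
        ],
    )
    return LDMapTrack(
        table=table,
        window_size=N,
        d_fixed=d_fixed,
        population_label=panel.population_label,
    )


# --------------------------------------------------------- chromosome-level α

def chromosome_alpha(
    panel: HaplotypePanel,
    chrom: str,
    n_pairs: int = 10_000,
    n_replicates: int = 1_000,
    seed: int = 0,
    max_distance: float | None = None,
    keep_replicates: bool = False,
) -> ChromosomeAlpha:
    """Chromosome-level α̂ by replicate subsampling of marker pairs.

    Per replicate, ``n_pairs`` pairs are drawn uniformly *without*
    replacement from all within-chromosome pairs (optionally capped at
    ``max_distance`` Mb) and α is fitted on them; the mean and sd of the
    replicate α̂ values are returned.  Replicates use independent
    substreams spawned from one seed, so results are fully reproducible.
    """
    H = _require_complete(panel)
    pos = panel.positions
    block = next((rows for c, rows in _chrom_blocks(panel) if c == chrom), None)
    if block is None or block.size < 2:
        raise ValueError(f"chromosome {chrom!r} has fewer than 2 markers")
    R = _corr_matrix(H[block])
    ii, jj = np.triu_indices(block.size, k=1)
    d_all = np.abs(pos[block][jj] - pos[block][ii]) / 1e6
    r2_all = R[ii, jj] ** 2
    if max_distance is not None:
        keep = d_all <= max_distance
        d_all, r2_all = d_all[keep], r2_all[keep]
    total = d_all.size
    if total == 0:
        raise ValueError(f"chromosome {chrom!r} has no usable pairs")
    k = n_pairs
    if total < n_pairs:
        logger.warning(
            "chromosome %s has %d pairs < requested %d; sampling all",
            chrom, total, n_pairs,
        )
        k = total
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    alphas = np.empty(n_replicates)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        idx = rng.choice(total, size=k, replace=False)
        alphas[rep] = fit_alpha(d_all[idx], r2_all[idx]).alpha_hat
    return ChromosomeAlpha(
        chrom=chrom,
        mean_alpha=float(alphas.mean()),
        sd_alpha=float(alphas.std(ddof=1)) if n_replicates > 1 else 0.0,
        n_pairs_per_replicate=k,
        n_replicates=n_replicates,
        seed=seed,
        alphas=alphas if keep_replicates else None,
    )


def chromosome_alpha_table(
    panel: HaplotypePanel,
    n_pairs: int = 10_000,
    n_replicates: int = 1_000,
    seed: int = 0,
    max_distance: float | None = None,
) -> pd.DataFrame:
    """mean(α̂) and sd(α̂) per chromosome (one subsampling run each)."""
    rows = []
    for k, chrom in enumerate(panel.chromosomes()):
        ca = chromosome_alpha(
            panel, chrom, n_pairs=n_pairs, n_replicates=n_replicates,
            seed=seed + k, max_distance=max_distance,
        )
        rows.append(
            {
                "chrom": chrom,
                "mean_alpha": ca.mean_alpha,
                "sd_alpha": ca.sd_alpha,
                "n_pairs": ca.n_pairs_per_replicate,
                "n_replicates": ca.n_replicates,
            }
        )
    return pd.DataFrame(rows)
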