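# Methods

## Data model and conventions

All statistics are computed from *phased* haplotype panels: a matrix with
one row per biallelic SNP and two columns per diploid individual, plus a
physical marker map. Allele 0 is the VCF REF allele and allele 1 the ALT
allele; allele frequencies and the sign of r always refer to the ALT
allele, which fixes a sign convention that makes signed r comparable
between populations once common markers are matched (below). Positions are
1-based; inter-marker distance is |posᵢ − posⱼ| bp, reported in Mb.
Panels may carry missing genotypes on input, but every LD operation
requires complete data: the package does not phase or impute, so callers
either supply imputed panels or let QC reject incomplete ones
(`apply_qc(strict=True)`).

## Quality control

Filters run in a fixed order, and each removed marker is attributed to the
first rule that fails, so the report's counts are unambiguous:

1. samples missing > 10% of genotypes are dropped;
2. markers with call rate < 0.90, then MAF < 0.05 (a marker at exactly
   0.05 is kept — the rule removes markers *below* the threshold), then
   Hardy–Weinberg exact p < 1e-7;
3. family structure: samples that are recorded parents of other samples
   are excluded, then one member per full-sib group is kept uniformly at
   random (seeded).

The HWE test is the exact conditional test — the probability of the
observed heterozygote count given the allele counts, summed over all
counts at most as probable — rather than a chi-square approximation,
because a 1e-7 threshold lives far in the tail where the chi-square is
unreliable. MAF and HWE are computed on observed (non-missing) genotypes.

## LD and persistence of phase

Signed r comes from haplotype counting (the panel is phased, so the
two-locus haplotype frequency p₁₁ is observed; no EM/composite-LD
estimation is needed), r² = r². Pairs are only formed within
chromosomes. Genome-wide decay curves pool all autosomal pairs into
half-open 100-kb distance bins from 0 to 10 Mb and average r² per bin;
binning is done on integer bp distances so boundary pairs are never
misassigned by floating-point division. A pair at exactly the cap is
excluded (the first bin is "distance < 100 kb", which fixes the half-open
convention). Per-chromosome "LD at D Mb" tables use the bin-local window
[D − 0.1, D) by default, with a cumulative (< D) mode behind a flag, since
the bin-local reading matches the decay-curve convention. Adjacent-pair
r² of two populations is compared with Welch's unequal-variance t-test;
the degenerate both-variances-zero case returns (0, 1) for equal means and
(±inf, 0) otherwise.

Persistence of phase between populations A and B is the Pearson
correlation of signed r over the same marker pairs in both populations.
Markers are matched across panels by (chromosome, position) with
allele-set verification — matching by SNP id is too fragile across panel
dialects. A marker whose REF/ALT labels are swapped between panels is kept
and its alleles relabeled (equivalently, its r values sign-flipped);
markers whose allele sets differ are dropped, which also removes
strand-ambiguous cases rather than guessing strand. Scenario I uses
markers common to all populations under study, Scenario II each pair's own
common set. Phase curves bin pairs exactly as decay curves do and compute
the correlation per bin (each bin uses its own means, as the correlation
is applied group-wise); bins with fewer than 3 pairs are flagged missing.
Matched markers monomorphic in either population are dropped (their r is
undefined) with a logged count.

## The local LD model

Sved's drift expectation for an isolated random-mating population is
E(r²) = 1/(1 + 4cNe). Lacking pedigree-based genetic distances, the decay
of r² with *physical* distance d (Mb) is modeled with the same functional
form, E(r²) = 1/(1 + αd): α merges local recombination rate and local
effective population size into a single per-Mb decay rate and is the
quantity the LD map tracks. It cannot be decomposed into c and Ne without
external assumptions, and the package does not attempt to.

The fit is a Gamma GLM with inverse link. The linear predictor is
η = 1 + α·d with the intercept *fixed* at 1 — the model has no free
intercept (r² → 1 as d → 0), so the 1 enters as an offset and α is the
single free parameter. The Gamma family reflects the roughly quadratic
mean–variance relationship of r² given d. Pairs with r² = 0 are excluded
before fitting (with a 1e-12 floating-point guard; exact zeros arise when
p₁₁ = p₁p₂ in rational haplotype counts).

Numerics: the shape parameter cancels from the score equation, leaving the
one-dimensional root problem Σ dₖ(1/ηₖ − r²ₖ) = 0, which is strictly
decreasing in α on the feasible region α > −1/d_max. The solver is
safeguarded Newton — every iterate is kept inside a maintained sign-change
bracket within (−1/d_max + ε, 1e4), with bisection fallback — so it
terminates for any input; convergence is |Δα| < 1e-10, at most 100
iterations. The standard error uses the Fisher information with a Pearson
moment estimate of the dispersion; the reported deviance is the Gamma
deviance. Negative α̂ (LD rising with distance in a window) is reported
as-is, never clamped — silent clamping would bias the map — and the
expected-r² transform is reported missing whenever 1 + α̂·d_fixed ≤ 0. A
free-intercept variant (η = β₀ + αd, Nelder–Mead on the Gamma deviance)
exists for diagnostics only. The fixed-offset fit agrees with a
generalized-linear-model reference implementation (Gamma family, inverse
link, offset 1) to ~1e-11 in both α̂ and its standard error; that check
lives in the test suite, not in the implementation.

### LD map and chromosome-level α

The LD map slides a window of N consecutive markers (default N = 100) one
marker at a time; each window fits α on all N(N−1)/2 within-window pairs
and records α̂ and 1/(1 + α̂·d) at a fixed moderate d (default 10 Mb) at
the middle marker, index ⌊N/2⌋ within the window (the upper-middle marker
for even N). A chromosome with m ≥ N markers yields m − N + 1 windows;
shorter chromosomes are skipped with a warning, and a failed window fit is
flagged and the track continues. A fixed marker count (not a fixed bp
length) keeps the per-window sample size constant; larger N smooths the
track toward the chromosome mean.

Chromosome-level α is the mean over replicates (default 1,000) of fits to
random subsamples (default 10,000 pairs, drawn uniformly *without*
replacement from all within-chromosome pairs; no distance cap by default,
one available as a flag). Replicates use independent child streams spawned
from one seed, so results are bit-reproducible. When fewer pairs exist
than requested, all pairs are used (warned), making the replicates
degenerate and sd(α̂) = 0.

## The synthetic generators

No genotype data of the kind this package analyzes are publicly
deposited, so the simulator defines the study conditions for all testing.

`gen_glm_pairs` draws d uniform over a range and r² ~ Gamma(shape,
mean = 1/(1 + αd)) — the fitter's own noise model with known truth; the
`noise_free` switch is the shape → ∞ limit. This is the distribution-level
loop-closure for α recovery (exact on noise-free data; unbiased within
Monte-Carlo error under Gamma noise, with sd(α̂) ∝ 1/√n).

`gen_mosaic_population` builds each sample haplotype as a recombinant
patchwork of K founder haplotypes (i.i.d. Bernoulli(0.5) per site),
switching to a uniformly chosen founder between consecutive markers with
probability 1 − exp(−ρ·Δd). K acts as an effective founder pool — tightly
linked pairs have E(r²) ≈ 1/(K−1) — and ρ as an accumulated per-Mb
recombination intensity. Defaults: 3,000 markers uniformly placed on one
300-Mb chromosome (~100 kb spacing, the scale of a large pig autosome on a
60K chip), K = 4 so that short-range r² ≈ 0.26 — the strong within-breed
LD regime of intensively selected livestock — ρ = 1/Mb, 100 diploids.
Monomorphic markers (≈ 2·0.5^K of them) are dropped with a logged count.

`gen_diverged_populations` evolves daughter populations independently from
one mosaic base by t generations of Wright–Fisher reproduction (Ne
diploids; each gamete recombines at the *per-meiosis* rate, default
0.01/Mb ≈ 1 cM/Mb — distinct from ρ, which stands for recombination
accumulated over the base population's whole history), then samples
individuals without replacement. There is no mutation, so markers stay
matched across daughters by construction; t = 0 reduces to resampling the
base. Divergence time t is the persistence-of-phase knob: phase
correlation decays with t through drift and recombination. The
three-population design used in testing (two daughters split ~10
generations ago, one ~300, Ne = 200) reproduces the qualitative pattern of
closely related breed pairs showing much higher phase persistence than
pairs involving a distant breed.

What the simulator does *not* emulate: mutation, selection, chip
ascertainment bias, genotyping error, assembly uncertainty, and the
absolute LD levels of any particular real panel (the mosaic short-range
ceiling 1/(K−1) stands in for them). Passing tests therefore demonstrate
correctness of the estimators and the expected qualitative behaviour of
the method — monotone decay, phase ordering by relatedness, parameter
recovery under the model's own noise — not quantitative agreement with any
specific real population.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run on scaled-down panels
(hundreds of markers on tens of Mb, 100–200 haplotypes; 5,000-pair ×
100-replicate chromosome subsampling) chosen so every distance bin stays
well populated while the whole suite completes in well under a minute of
compute per module; the estimators themselves are O(m²) per chromosome in
memory and handle chip-scale panels (tens of thousands of markers) without
algorithmic changes.

## Known limitations

* Phasing and imputation are out of scope; panels must arrive phased and,
  for LD estimation, complete.
* α is a visualization-oriented summary: the model targets the *pattern*
  of local LD, not optimal prediction of individual pair r², and α̂
  depends on window size N (smaller N → noisier, more local).
* The expected-r² track involves an arbitrary choice of the fixed distance
  d; tracks with different d are monotone transforms of the same α̂.
* Cross-population marker matching drops allele-set mismatches, including
  A/T–C/G strand ambiguities, rather than attempting strand inference.
* D′ is deliberately not implemented; r² is less allele-frequency
  sensitive and is the only LD measure used.
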