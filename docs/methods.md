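# Methods

## Model

### Genotype coding and relationship matrices

Phased diploid genotypes are stored haplotype-major as 0/1 allele
indicators (rows 2k, 2k+1 of the panel are the two haplotypes of
individual k); the −1/0/1 genotype coding is always derived from the
haplotypes, never stored redundantly, so phase and code cannot disagree.

The realized relationship matrix is the uncentered cross-product
`G = X'X`. Per locus, a pair contributes +1 for a shared homozygote, −1
for opposite homozygotes, 0 whenever either member is heterozygous; the
diagonal counts each individual's homozygous loci. No allele-frequency
centering or heterozygosity scaling is applied — the matrix is meant to
*measure inbreeding* for contribution optimization, not to maximize
prediction accuracy, and the raw locus-count scale is what makes the
mate-allocation identity below exact.

The He × Ho adjustment is `G* = G + βQ` with `Q_ij` the number of loci at
which exactly one of i, j is heterozygous (`Q_ii = 0`). This sets the
per-locus value of every He × Ho pair to β while leaving He × He pairs at
0. For contributions summing to one,

```
c'G*c = c'Gc + β c'Qc,        c'Qc = 2 He'Ho,
```

with `He_l = Σ_i c_i 1{X_li = 0}` and `Ho_l = 1 − He_l`. The factor 2
arises because the symmetric Q counts each unordered He × Ho pair twice;
since β is a free tuning parameter the factor is absorbable into it and
changes no qualitative behavior. Both identities are enforced by tests at
1e−10 against explicit pair-by-locus summation.

### Positive-definite projection

The contribution QP is strictly convex only if its matrix is positive
definite, and `G*` need not be (β < 0 subtracts a nonnegative matrix).
We use the spectral projection: eigenvalues below a floor are raised to
the floor, which is the closest PD matrix in spectral norm, at distance
`max(0, floor − λ_min)`. The floor defaults to `1e−8 · max(λ_max, 1)` —
relative so it scales with the locus count, strictly positive so the QP
has a unique solution. The projection feeds only the QP; mate-allocation
costs and all reported coancestries use the unprojected matrices.

### Contribution optimization

The scalarized program `min α c'Mc − (1−α) c'Y` over the capped simplex
(`Σc = 1`, `0 ≤ c ≤ 0.5`, optionally `d'c = 0.5` for a dioecious design
vector) is solved by a primal active-set method: exact KKT solves on the
free coordinates, blocking-constraint steps, multiplier-driven releases,
deterministic index tie-breaks, no random initialization. Every solution
carries a KKT residual computed independently of the solve path (the
stationarity violation minimized over the equality multipliers by a small
LP, so degenerate actives are not misreported); a SLSQP fallback engages
if the residual exceeds 1e−6, which has not been observed in testing.
`α = 0` is a pure LP with possibly non-unique optima; it is regularized
with a 1e−9 quadratic weight to keep the solution deterministic. The cap
0.5 prevents any parent from supplying more than half the gametes.

### Mate allocation

Contributions are discretized by largest-remainder rounding of
`2 · n_offspring · c` (ties to the larger contribution, then the lower
index; per-parent cap at `n_offspring` enforced by redistribution). The
allocator then minimizes `Σ n_ij cost_ij` subject to exact per-parent
gamete degrees over unordered pairs — a degree-constrained b-matching.
The LP relaxation (HiGHS) has half-integral vertex solutions whose
fractional support forms disjoint odd cycles, always an even number of
them by a parity argument; each pair of cycles is repaired to integers by
the cheapest combination of near-perfect matchings (unique once the
uncovered vertex of each odd cycle is chosen) plus one bridge edge
between the uncovered vertices, preserving degrees exactly. Tests verify
the repaired plan attains the exhaustive-enumeration integer optimum.

The cost matrix is the raw (unprojected) `G*`: the expected number of
homozygous loci of an offspring of i × j is `(L + G_ij)/2` under
Mendelian segregation, so minimizing total pair cost minimizes expected
progeny homozygosity; with the offspring count fixed by the
contributions, total and per-mating average are equivalent. Each unit of
the pair-count matrix is one mating event producing exactly one offspring
from independent meioses of both parents. The random-mating control draws
pairs with probability proportional to remaining gametes and repairs
stranded-gamete states by rewiring an existing mating, so degrees are
met exactly in both modes.

### Meiosis

Crossovers per chromosome are Poisson with mean equal to the map length
in Morgans, positions uniform in genetic distance, no interference and no
mutation — the Haldane model, chosen as the standard minimal assumption
because it gives the closed form `r = (1 − e^{−2d})/2` used to calibrate
the engine (verified at d = 1 Morgan on 1e5 gametes). Each gamete starts
from a fair-coin parental haplotype and switches at every crossover; a
zero-length chromosome transmits a parental haplotype intact. The map is
unisex and crossover positions beyond the last locus have no effect.

### Genomic evaluation

GEBVs come from ridge regression (RR-BLUP) of centered phenotypes on the
raw −1/0/1 coding — the adjusted matrix `G*` never enters evaluation.
Both the L × L primal normal equations and the n × n dual form are
implemented (the smaller system is used; they agree to 1e−8 in tests).
The penalty defaults to the variance-ratio plug-in
`λ = ((1−h²)/h²) Σ_l 2p_l(1−p_l)`, appropriate because the simulator
treats h² as known; frequencies are taken from the cumulative reference
at each refit. The reference grows by appending every newly phenotyped
generation and the model is refit from scratch each generation for
reproducibility.

### Phenotypes

`y = TBV + e`, `e ~ N(0, (1−h²)σ_g²)` with `σ_g²` the TBV variance. By
default σ_g² is recomputed from the *current* generation's TBV so the
realized heritability stays near nominal as genetic variance erodes; a
`founder_fixed` switch uses the founder variance throughout instead. h²
defaults to 0.5134 (the trunk-circumference heritability of the poplar
breeding population these simulations are calibrated to).

## The simulator loop

Per generation, in order: phenotype the candidates; append them to the
reference and refit the evaluation; build G, Q, G* on the candidates and
project; solve the QP on the GEBVs (never on TBVs — those are reserved
for metrics); discretize and allocate mates; create the next generation
by meiosis at constant population size. Recorded per generation: mean and
sd of TBV, gain (mean TBV minus the founder mean — both the absolute
level and the delta are recoverable), contribution-weighted coancestry on
G* and on G, population coancestry with uniform weights, breeding
potential, evaluation accuracy (cor(GEBV, TBV)), and the fixed-locus
count. All coancestries are divided by the locus count so they land on a
[0, 1]-like per-locus scale (≈0.1 for the synthetic founders, →1 at full
fixation); the raw quadratic form is also exposed. "True" coancestry is
always the G-based quantity, whatever β drove selection — the code path
is asserted in tests.

**Breeding potential** is the mean over individuals of
`Σ_{l not fixed} a_l X_li`, with a locus counted as fixed when every
individual carries the same homozygote. True effects are used (estimated
effects are a config option): the metric is a simulator-side measure of
remaining selectable variation and true effects keep it noise-free.

**Randomness.** One root seed per run; every replicate × generation ×
operation stream is derived from it through named `SeedSequence` spawn
keys, so any single generation is replayable and trajectories are
byte-identical across reruns of the same configuration.

## Synthetic founders

The generator emulates the statistical features of a dense, structured
breeding population that matter here: MAF-filtered markers (default
> 0.05, strict), LD decaying with map distance, and subpopulation
differentiation. Each founder haplotype is a mosaic over a small pool of
ancestral haplotypes (default 6 per subpopulation, drawn from
per-subpopulation locus frequencies ~ U(0.1, 0.9)), switching pool
members at exponential genetic distances (default rate 0.02/cM, mean
segment 50 cM). A mosaic generator was chosen over coalescent simulation
because it gives direct, testable control of LD and structure at trivial
runtime. Defaults: 100 individuals, 500 loci on 5 × 100 cM chromosomes,
3 subpopulations. Trait architectures are sparse Normal effects,
optionally rescaled so the founder TBV standard deviation hits a target
exactly (the pipeline default of 25.9 matches the founder spread of the
calibration population).

What the generator does *not* emulate: coalescent site-frequency spectra,
mutation, demographic history, sex chromosomes, genotyping error, and the
realistic marker density of array data (desk-scale runs use ~500 of the
~5000 markers a real panel would carry). Passing tests therefore
demonstrate the method's internal correctness and its qualitative
dynamics (gain/coancestry trade-off in α, diversity preservation by
negative β), not quantitative transferability of any particular number to
a real population.

## Numerical choices and degenerate inputs

- QP tolerances: KKT residual ≤ 1e−6 enforced; active-set iteration cap
  50(N+5) with SLSQP fallback; contributions below 1e−12 snapped to zero
  and renormalized before discretization.
- LP half-integrality detection at 1e−4; repaired plans re-validated
  against their degree constraints (hard failure, not a warning).
- Ridge refuses n < 2 or λ ≤ 0; an all-equal phenotype vector yields zero
  effects with a warning (arises legitimately at full fixation).
- `maf_filter` returns the kept-locus index set so map and effects are
  subset explicitly by the caller; silent reindexing is forbidden.
- Monomorphic loci: shuffling leaves them unchanged; LD measures skip
  them; fixation tests treat "all heterozygous" as segregating (both
  alleles present).
- Unphased or missing VCF genotypes are rejected with a clear error —
  phase is load-bearing for meiosis.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full
suite completes in minutes on one core: 100 founders × ~500 markers,
10-generation programs, 8–10 replicates per scenario, 3 × 3 × 2 scenario
grids; component calibrations use 1e4–1e5 Monte-Carlo draws. The
simulator itself has no hard-coded scale; `ProgramConfig` accepts the
20-generation, 9 × 3 × 2 × 100-replicate layout of a full study directly.

## Known limitations

- Pedigree-based (numerator-matrix) OCS, dominance in evaluation,
  time-varying α/β schedules, overlapping generations, introgression and
  logistic mating constraints beyond no-selfing are out of scope.
- The dioecious constraint `d'c = 0.5` is implemented in the QP, but the
  mate-allocation LP does not enforce opposite-sex pairing.
- The α = 0 limit relies on the 1e−9 regularization for uniqueness;
  exactly tied breeding values there resolve by candidate index.
- Half-integral LP repair assumes a vertex solution from the simplex
  solver; interior solutions (not produced by HiGHS simplex) would be
  rejected rather than repaired.
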