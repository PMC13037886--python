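# Methods

## Model

`landgen` models a species as a rectangular grid of demes (locally panmictic
subpopulations) under the classic multideme Wright–Fisher model: rook
(4-neighbor) adjacency, a single per-edge backward migration probability *m*
(a lineage's parent lived in a given adjacent deme with probability *m*;
`m × degree < 1`), diploid deme sizes *N_i*, and a per-lineage per-generation
mutation rate *u*. Habitat loss removes demes; restoration re-adds them.
Grid coordinates are 0-based `(row, col)` with row 0 = north, so the
"south-to-north" extinction scheme and edge choices are unambiguous.

### The pairwise-identity recursion

Nucleotide diversity is a second-moment functional of allele frequencies, so
it is tracked exactly through the matrix `F` of probabilities of identity in
state for pairs of lineages drawn from every deme pair. One generation of
drift, migration, and infinite-alleles mutation gives the exact linear
recursion

    F' = (1 − u)² · B G Bᵀ,
    G[k,l] = F[k,l]  (k ≠ l),   G[k,k] = 1/(2N_k) + (1 − 1/(2N_k)) F[k,k]

with `B` the row-stochastic backward migration matrix. Per-site π is
`H = 1 − F`; species-wide π weights deme pairs by census share
(`π_species = Σ w_i w_j H_ij`, `w_i = N_i/ΣN`, within-deme pairs included),
and local π is the unweighted mean of the diagonal (the grid-cell average).
For a single deme the recursion's fixed point reproduces the classical
`H* = 4Nu/(1+4Nu)`, and in the small-θ limit `E[π] = 4N_e u`.

Because the recursion is linear, the non-trivial equilibrium (`u > 0`) is a
single direct solve. With uniform per-edge migration `B` is symmetric, so
the D²-dimensional pair system collapses in the eigenbasis of `B`: given the
vector `d_k = (1 − F_kk)/(2N_k)` the off-diagonal solution is closed-form,
and only the D within-deme identities couple — one D × D solve. A sparse LU
on the vectorized D² system covers non-symmetric migration (the "absorb"
boundary mode). The returned equilibrium reproduces itself under one
recursion step to ~1e−14, far inside the 1e−10 contract.

### Habitat change

`apply_loss` restricts `F` to the surviving demes (the surviving block is
the exact initial condition) and migration is rebuilt on the survivors.
Migration mass that pointed at destroyed demes returns to the source deme by
default ("renormalize", a reflecting boundary — individuals cannot disperse
into uninhabitable ground); an "absorb" mode (emigrants lost, rows rescaled
proportionally) is provided for sensitivity analysis. `apply_restore` founds
re-added demes either from their live neighbors (rows are neighbor averages;
within-deme identity the neighbor-pair average) or by landscape-wide
translocation (size-weighted average identity).

### Horizons

* **short** — one generation after loss.
* **mid** — `⌈N_ref/2⌉` generations, `N_ref` the pre-loss total census
  (2,500 for the default landscape). Census size stands in for effective
  size; an independently estimated N_e can be supplied via
  `mid_generations`.
* **long** — the ~20,000-generation horizon (`long_mode="horizon"`,
  default), i.e. the far-future window a forecast can meaningfully speak to;
  for a connected, weakly structured system this has converged to the new
  equilibrium. `long_mode="equilibrium"` solves the true t→∞ limit
  directly. The two differ materially for strongly structured or
  fragmented systems: once fragments are fully isolated their between-
  fragment heterozygosity keeps rising on the mutational (1/u-generation)
  timescale, so the "equilibrium" of a disconnected landscape (H_between = 1)
  is astronomically far away and not a useful forecast. Fragmentation
  outcomes are therefore always reported at the horizon.

### Calibration and fitting

Population structure is summarized as Hudson-style F_ST per deme pair,
`1 − mean(H_ii, H_jj)/H_ij`, averaged over unordered pairs.
`calibrate_migration` Brent-solves `log m` against a target average F_ST
(monotone decreasing in *m*); targets below the attainable minimum (~0.011
on the default grid, set by the `m × 4 < 1` bound) or above the maximum
return the boundary rate with a warning. Note this deme-pair estimator reads
higher than ADMIXTURE-style species-level F_ST on comparable data; F_ST
inputs taken from model-based ancestry analyses are not on exactly the same
scale. `fit_to_trajectory` recovers `(u, m, time-scale)` from an observed
π_species trajectory by derivative-free (Powell) least squares with deme
sizes fixed.

## Default parameters

| parameter | default | units | why |
|---|---|---|---|
| grid | 10 × 10 | demes | canonical landscape partition |
| deme size N_i | 50 | diploids | total census ΣN = 5,000 |
| u | 1e−6 | per lineage per generation | small-θ regime (θ_species = 0.02) with workable equilibrium π |
| mid horizon | ⌈ΣN/2⌉ = 2,500 | generations | drift erodes most of the long-run loss within ~N_e/2 generations |
| long horizon | 20,000 | generations | ≈ 4 ΣN; convergence for connected weakly structured systems |
| calibration tol | 1e−3 | F_ST | bisection stopping rule |
| equilibrium residual | ≤ 1e−10 | identity units | one-step self-consistency contract |

## Forward simulator

The stochastic cross-check is a discrete multideme Wright–Fisher simulator
over unlinked biallelic sites: deterministic migration mixing `x ← Bx`,
symmetric mutation `x ← u + (1−2u)x`, then binomial resampling of 2N_k
allele copies per deme. Unlinked sites are exact for π and S, which need no
linkage information. Genotypes are materialized only at sampling time
(dosages `Binomial(2, x_k)`, coordinates at the deme's cell center plus
jitter; monomorphic sites retained to avoid ascertainment bias). Two
analytic bridges connect it to the moment engine: symmetric biallelic
mutation decays identity as `(1−2u)^{2T}`, i.e. the infinite-alleles engine
at rate 2u (heterozygosity halved); and the `n/(n−1)`-corrected π estimator
overestimates population heterozygosity by `(2n−1)/(2n−2)` at sample size n
per deme, which deflates genotype-based F_ST. The synthetic-genotype
generator applies both corrections when calibrating toward a target F_ST.

## Empirical-side estimators

`nucleotide_diversity` implements
`π = (n/(n−1)) (1/L) Σ 2p_i(1−p_i)` with `p_i` the mean dosage / 2. The
`n/(n−1)` convention makes it the average expected difference over all
ordered individual pairs — within-individual comparisons included — divided
by `n(n−1)`; the test suite pins this against a brute-force all-pairs
oracle. Missing genotypes are refused (imputation/filtering is an upstream
concern), multiallelic or missing VCF records are rejected with counts.
Extinction simulation erodes an equal-area grid laid over the samples'
bounding box; area loss is counted against occupied cells only. "North"
means larger y; the south-north front removes cells by descending cell-center
y, ties left-to-right, one cell at a time.

## Power laws and landscape metrics

GDAR: `π_lost = 1 − (1 − A_lost)^z`. The fit is least squares through the
origin on `log(1−loss) = z·log(1−A_lost)` (the functional form forces zero
loss at zero area loss; points at A_lost = 0 carry no information), with R²
reported on the untransformed loss scale — log-scale R² would differ.
Landscape summaries are FRAGSTATS-style on the 0/1 grid: rook patches,
perimeter counting map-boundary faces, core cells (all four neighbors
habitat), patch/edge density, and patch cohesion; a CONNECT-style
within-distance joining fraction was considered and left out in favor of
cohesion, which is the formula reported in outputs.

## Indicator pipeline

Red List categories map to the arithmetic mean of the population-decline
range behind the A-criterion thresholds (CR 80–95% → 87.5%; EN 50–80; VU
30–50; NT 15–30 as a documented heuristic just below the VU threshold; the
table is configuration, overridable via CSV). LPI series reduce to
`N_present/(N_past+1)` per population (the +1 guards zero baselines — the
source formula's grouping is ambiguous, so this reading is flagged and
configurable), averaged across populations; non-declining species are
flagged for exclusion. GBF Indicator 2 is `(past − present)/past`
populations. Species without measured genetic parameters draw F_ST from a
truncated normal (mean 0.270, SD 0.211 on [0, 1)) and z_GDAR by resampling
an empirical exponent table (fallback: Beta(0.5, 7) scaled to [0, 0.45],
mean 0.03). Short-term contraction predictions use GDAR; all other
horizon × scenario cells are nearest-bin lookups in a precomputed engine
table, with fragmentation forecasts reporting *local* π loss (species-wide
π is misleading under fragmentation and is emitted alongside). The
population-loss = habitat-loss proxy is recorded as an assumption in every
output row. Out-of-range area losses either raise (default) or clamp to the
table's edge bin with a flag (`clamp=True`; the CLI clamps).

## Synthetic data

Genotypes: migration calibrated to a target F_ST (with the two analytic
corrections above), forward burn-in, then geo-referenced sampling; the
default scale is 5 × 5 demes of 25 with u = 1e−4, which reaches diversity
equilibrium in a few thousand generations while leaving hundreds of
segregating sites. Indicator tables draw per-species losses from
distributions moment-matched to published summaries: LPI losses
Beta(0.926, 0.510) (mean 64%, quartiles ≈ 40/93%); GBF losses a 40% zero
mass plus Beta(0.970, 2.158) (mean 18.6%, upper quartile ≈ 33%). The
distribution families are choices (only summaries are published) and are
recorded in the spec JSON written next to each dataset.

What the generators deliberately do not emulate: linkage and genome
structure, continuous-space dispersal kernels, overlapping generations,
selection, and real sampling geographies. Tests passing on these inputs
show the pipeline is internally consistent and that the moment engine
matches its own model class; they do not validate the WF idealization
against continuous-space, age-structured populations.

## Study-scale choices and known gaps

The forward-simulation cross-checks run at a reduced scale (6 × 6 demes of
10, u = 1e−4, 300–400 sites, horizons scaled as ~4 × total census to mirror
20,000 generations at census 5,000), sizes chosen so replicate Monte-Carlo
error sits well below the across-scenario signal. Two known gaps are worth
stating plainly: the engine drifts at census rate (N_e = N_c), so systems
with emergent N_e below census decay faster than the engine at a fixed
horizon; and the deme-pair Hudson F_ST used for calibration is not the same
scale as ADMIXTURE-based species F_ST, so structure levels quoted from such
analyses map onto stronger deme-pair structure here. Both gaps shift
fixed-horizon comparisons; equilibrium quantities and the power-law/ordering
behaviors are insensitive to them.
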