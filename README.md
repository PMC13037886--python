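# landgen

Spatiotemporal forecasting of nucleotide diversity (π) under habitat loss.

Habitat destruction erodes a species' genetic diversity, but slowly and
unevenly: the immediate π loss after losing half a range can be a few
percent, while genetic drift keeps eroding diversity for thousands of
generations afterwards, and fragmentation can even *inflate* species-wide π
(Wahlund-type divergence among isolated remnants) while within-patch
diversity collapses. `landgen` is for population geneticists and
conservation scientists who need to turn habitat- or population-loss
numbers — including indicator data such as IUCN Red List categories, Living
Planet Index censuses, or GBF Indicator-2 population counts — into
quantitative short-, mid-, and long-term forecasts of π loss.

## What's inside

* **Moment engine** — a multideme Wright–Fisher model on a deme grid,
  tracked through the exact linear recursion for pairwise identity
  probabilities, `F' = (1−u)² B G Bᵀ`. Equilibria are direct linear solves;
  transients after habitat change are iterated exactly. Yields π_species,
  π_local, Hudson-style pairwise F_ST, migration calibration to a target
  F_ST, and trajectory fitting.
* **Habitat scenarios** — edge contraction, seeded random fragmentation,
  gradual schedules, restoration (natural recolonization or translocation).
* **Forward simulator** — a discrete Wright–Fisher allele-frequency
  simulator over unlinked sites: the stochastic cross-check for the engine
  and the source of spatially structured synthetic genotypes.
* **GDAR** — the genetic diversity–area relationship
  `π_lost = 1 − (1 − A_lost)^z`, fitted and inverted; the short-term
  back-of-envelope companion to the engine (the analog of the
  mutations–area relationship for allelic richness).
* **Empirical statistics** — π, segregating sites, grid-cell π_local, and
  Hudson F_ST on genotype matrices (VCF + coordinate TSV), plus in-silico
  extinction (random and south→north schemes) producing loss curves.
* **Landscape metrics** — FRAGSTATS-style patch, perimeter, core-area and
  cohesion summaries of habitat grids, and their regressions against
  diversity outcomes.
* **Indicator pipeline** — Red List / LPI / GBF tables → per-species
  area-loss proxies → forecasts via GDAR and precomputed engine lookup
  tables, with seeded sampling of unmeasured F_ST / z parameters and global
  mean + IQR aggregates.

## Worked example

The critically endangered Torrey pine has lost an estimated ~80% of its
habitat; extinction simulation on its genotype data gives a GDAR exponent
of z ≈ 0.028:

```console
$ landgen forecast --loss 0.8 --z 0.02809
pi loss (GDAR, z=0.02809): 4.4%
```

Despite an 80% range loss, the immediate π loss is only ~4.4% — spatial
structure this weak stores most diversity redundantly across the range.
The moment engine extends this over time. For a strongly structured species
(average pairwise deme F_ST = 0.9) losing 50% of its range by edge
contraction:

```console
$ landgen forecast --loss 0.5 --fst 0.9 --horizon short
pi loss (short, contraction, F_ST=0.9, seed=0): species 11.0%  local 0.1%
$ landgen forecast --loss 0.5 --fst 0.9 --horizon long
pi loss (long, contraction, F_ST=0.9, seed=0): species 22.9%  local 24.2%
```

One generation after the loss the species has already lost 11% of its π
(the destroyed demes held divergent variants), and drift roughly doubles
the damage by the ~20,000-generation horizon. `landgen calibrate` exposes
the structure → migration mapping behind these forecasts:

```console
$ landgen calibrate --fst 0.3
m = 0.00744285  (realized average pairwise F_ST = 0.3000)
```

The same machinery is available as a library:

```python
from landgen.forecast import forecast
r = forecast(0.5, 0.3, horizon="mid", scenario="fragmentation", seed=1)
print(r.loss_species, r.loss_local)
```

For batch use, `landgen table` precomputes a lookup table over an
F_ST × area-loss grid and `landgen indicators` joins it with Red List, LPI,
and GBF CSVs to produce per-species predictions and global aggregates;
`landgen synth` generates statistically matched synthetic inputs for all of
these, so the whole pipeline runs without any external data.

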