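"""Forward multideme Wright-Fisher simulator over unlinked biallelic sites.

Serves as the stochastic oracle for the moment engine and as the generator
of spatially structured genotype data.  Each generation and site undergoes
deterministic migration mixing (``x <- B x``), symmetric mutation
(``x <- u + (1 - 2u) x``), and binomial resampling of ``2 N_k`` allele
copies per deme.  Sites are unlinked (free recombination), which is exact
for the diversity statistics tracked here (pi and segregating sites need no
linkage information); genotypes are only materialized when sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .habitat import Habitat
from .moments import Trajectory, backward_migration

__all__ = ["SimState", "simulate", "burn_in", "restrict_state", "sample_genotypes"]


@dataclass
class SimState:
    """Allele frequencies ``x`` (demes x sites) plus bookkeeping."""

    x: np.ndarray
    sizes: np.ndarray
    demes: np.ndarray
    u: float
    generation: int
    rng: np.random.Generator
    stable: bool = True

    @property
    def n_sites(self) -> int:
        return self.x.shape[1]

    def pi_species(self) -> float:
        """Mean over sites of pooled heterozygosity ``2 xbar (1 - xbar)``,
        with demes weighted by size (the frequency-space analog of averaging
        pairwise differences over all individuals)."""
        w = self.sizes / self.sizes.sum()
        xbar = w @ self.x
        return float(np.mean(2.0 * xbar * (1.0 - xbar)))

    def pi_local(self) -> float:
        """Unweighted over-deme mean of within-deme heterozygosity."""
        return float(np.mean(2.0 * self.x * (1.0 - self.x)))


def _init_state(habitat: Habitat, u: float, L: int, rng: np.random.Generator) -> SimState:
    live = habitat.live
    x0 = np.full((live.size, L), 0.5)
    return SimState(
        x=x0,
        sizes=habitat.sizes[live].astype(int),
        demes=live,
        u=u,
        generation=0,
        rng=rng,
    )


def _advance(state: SimState, B: np.ndarray, generations: int, record_every: int):
    gens, pis, locs = [state.generation], [state.pi_species()], [state.pi_local()]
    n_copies = (2 * state.sizes)[:, None]
    for t in range(1, generations + 1):
        xt = B @ state.x
        if state.u > 0:
            xt = state.u + (1.0 - 2.0 * state.u) * xt
        state.x = state.rng.binomial(n_copies, xt) / n_copies
        state.generation += 1
        if t % record_every == 0 or t == generations:
            gens.append(state.generation)
            pis.append(state.pi_species())
            locs.append(state.pi_local())
    return Trajectory(np.array(gens), np.array(pis), np.array(locs))


def simulate(
    habitat: Habitat,
    u: float,
    L: int,
    generations: int,
    seed: int,
    record_every: int = 1,
    state: SimState | None = None,
) -> tuple[SimState, Trajectory]:
    """Run the forward simulation, recording diversity summaries.

    Starts from ``state`` if given (its deme set must match the habitat's
    live demes), otherwise from all sites at frequency 0.5.  The seed fully
    determines the outcome.
    """
    if L < 1:
        raise ValueError("need at least one site")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if state is None:
        state = _init_state(habitat, u, L, np.random.default_rng(seed))
    else:
        state = SimState(
            x=state.x.copy(),
            sizes=habitat.sizes[habitat.live].astype(int),
            demes=habitat.live,
            u=u,
            generation=state.generation,
            rng=np.random.default_rng(seed),
            stable=state.stable,
        )
        if state.x.shape[0] != habitat.live.size:
            raise ValueError("state deme count does not match the habitat's live demes")
    B = backward_migration(habitat)
    traj = _advance(state, B, generations, record_every)
    return state, traj


def restrict_state(state: SimState, habitat_after: Habitat) -> SimState:
    """Keep only the frequencies of demes surviving a habitat change."""
    pos = {int(g): k for k, g in enumerate(state.demes)}
    keep = np.array([pos[int(g)] for g in habitat_after.live])
    return SimState(
        x=state.x[keep].copy(),
        sizes=habitat_after.sizes[habitat_after.live].astype(int),
        demes=habitat_after.live,
        u=state.u,
        generation=0,
        rng=state.rng,
        stable=state.stable,
    )


def burn_in(
    habitat: Habitat,
    u: float,
    L: int,
    seed: int,
    stability_window: int = 500,
    tol: float = 0.02,
    max_generations: int = 100_000,
    check_every: int = 100,
) -> SimState:
    """Run until species-wide pi is stable over a sliding window.

    Stability means the window mean of pi changes by less than ``tol``
    (relative) between consecutive windows.  If ``max_generations`` is hit
    first the state is returned flagged ``stable=False``.
    """
    rng = np.random.default_rng(seed)
    state = _init_state(habitat, u, L, rng)
    B = backward_migration(habitat)
    window = max(1, stability_window // check_every)
    history: list[float] = []
    if not np.isfinite(tol):
        _advance(state, B, stability_window, record_every=stability_window)
        return state
    while state.generation < max_generations:
        _advance(state, B, check_every, record_every=check_every)
        history.append(state.pi_species())
        if len(history) >= 2 * window:
            prev = np.mean(history[-2 * window : -window])
            cur = np.mean(history[-window:])
            if prev > 0 and abs(cur - prev) / prev < tol:
                return state
    warnings.warn("burn-in hit the generation cap before pi stabilized")
    state.stable = False
    return state


def sample_genotypes(state: SimState, habitat: Habitat, n_per_deme: int, seed: int):
    """Draw a geo-referenced genotype matrix from the current frequencies.

    Each sampled diploid's dosage at a site is ``Binomial(2, x_k)`` for its
    deme ``k``.  Samples get planar coordinates at their deme's unit grid
    cell center (``y`` increasing toward the north, row 0) plus seeded
    sub-cell jitter.  Monomorphic sites are retained: downstream estimators
    expect unfiltered (unascertained) site sets.
    """
    from .metrics import GenotypeMatrix

    rng = np.random.default_rng(seed)
    live = habitat.live
    if not np.array_equal(live, state.demes):
        raise ValueError("habitat live demes do not match the simulation state")
    if n_per_deme < 1:
        raise ValueError("n_per_deme must be >= 1")
    if np.any(n_per_deme > state.sizes):
        raise ValueError("cannot sample more individuals than a deme holds")
    D, L = state.x.shape
    n = D * n_per_deme
    G = np.empty((n, L), dtype=np.int8)
    coords = np.empty((n, 2))
    labels = np.empty(n, dtype=object)
    for k, g in enumerate(live):
        sl = slice(k * n_per_deme, (k + 1) * n_per_deme)
        G[sl] = rng.binomial(2, state.x[k], size=(n_per_deme, L))
        r, c = habitat.coord(int(g))
        cx = c + 0.5
        cy = (habitat.rows - 1 - r) + 0.5  # row 0 = north = largest y
        jitter = rng.uniform(-0.45, 0.45, size=(n_per_deme, 2))
        coords[sl, 0] = cx + jitter[:, 0]
        coords[sl, 1] = cy + jitter[:, 1]
        labels[sl] = [f"deme{int(g)}" for _ in range(n_per_deme)]
    sample_ids = [f"s{i:04d}" for i in range(n)]
    return GenotypeMatrix(
        G=G.astype(np.int16),
        coords=coords,
        sample_ids=sample_ids,
        groups=labels.astype(str),
    )
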