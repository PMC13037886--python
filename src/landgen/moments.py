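"""Exact moment recursions for nucleotide diversity in a multideme Wright-Fisher model.

The state is the matrix ``F`` of expected probabilities of identity in state:
``F[i, j]`` is the probability that two distinct lineages, one sampled from
deme ``i`` and one from deme ``j``, carry identical alleles at a neutral site.
Expected heterozygosity, the model's per-site nucleotide diversity, is
``H = 1 - F``.  Under drift, conservative migration, and infinite-alleles
mutation at rate ``u`` per lineage per generation, ``F`` obeys the exact
one-generation linear recursion

    F' = (1 - u)^2 * B G B^T,
    G[k, l] = F[k, l]                          (k != l)
    G[k, k] = 1/(2 N_k) + (1 - 1/(2 N_k)) F[k, k]

where ``B`` is the row-stochastic backward migration matrix (``B[i, k]`` =
probability that a lineage now in deme ``i`` had its parent in deme ``k``)
and ``N_k`` are diploid deme sizes.  Because the recursion is linear, the
non-trivial equilibrium is obtained by a single sparse linear solve, and
transient dynamics after habitat change by iterating the recursion.

For a single deme this reproduces the classical infinite-alleles equilibrium
``H* = 4Nu / (1 + 4Nu)`` and, in the small-``theta`` limit, ``E[pi] = 4 N_e u``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq, minimize

from .habitat import Habitat

__all__ = [
    "PairIdentityState",
    "Trajectory",
    "backward_migration",
    "init_state",
    "step",
    "equilibrium",
    "equilibrium_state",
    "pi_species",
    "pi_local",
    "pairwise_fst",
    "apply_loss",
    "apply_restore",
    "propagate",
    "calibrate_migration",
    "fit_to_trajectory",
]


@dataclass
class PairIdentityState:
    """Pairwise identity probabilities over the live demes of a habitat.

    ``F`` is symmetric with entries in ``[0, 1]``; ``demes`` records which
    grid positions the rows/columns refer to; ``u`` is the per-lineage
    per-generation mutation rate; ``generation`` counts recursion steps since
    the state's reference event (e.g. a habitat change).
    """

    F: np.ndarray
    demes: np.ndarray
    u: float
    generation: int = 0

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.demes = np.asarray(self.demes, dtype=int)
        if self.F.shape != (self.demes.size, self.demes.size):
            raise ValueError("F must be D x D for D live demes")

    @property
    def H(self) -> np.ndarray:
        """Expected heterozygosity (per-site pi) for every deme pair."""
        return 1.0 - self.F

    @property
    def n_demes(self) -> int:
        return self.demes.size

    def copy(self) -> "PairIdentityState":
        return PairIdentityState(self.F.copy(), self.demes.copy(), self.u, self.generation)


@dataclass
class Trajectory:
    """Time series of diversity summaries recorded while iterating the recursion."""

    generations: np.ndarray
    pi_species: np.ndarray
    pi_local: np.ndarray

    def __post_init__(self):
        self.generations = np.asarray(self.generations)
        self.pi_species = np.asarray(self.pi_species, dtype=float)
        self.pi_local = np.asarray(self.pi_local, dtype=float)
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be strictly increasing")


def backward_migration(habitat: Habitat, lost_mode: str = "renormalize") -> np.ndarray:
    """Backward migration matrix over the habitat's live demes.

    ``B[i, k] = m`` for each live rook neighbor ``k`` of ``i`` and the
    remaining mass sits on the diagonal.  When neighbors have been destroyed,
    ``lost_mode`` decides where their migration mass goes:

    - ``"renormalize"`` (default): returned to the source deme (reflecting
      boundary) -- ``B[i, i] = 1 - m * live_degree(i)``.
    - ``"absorb"``: emigrants toward destroyed demes are lost and the row is
      rescaled proportionally, ``B[i, .] / row_sum`` with
      ``B[i, i] = 1 - m * base_degree(i)``.
    """
    live = habitat.live
    m = habitat.migration_rate
    D = live.size
    pos = {int(g): k for k, g in enumerate(live)}
    B = np.zeros((D, D))
    if lost_mode == "absorb":
        base = Habitat(
            rows=habitat.rows,
            cols=habitat.cols,
            sizes=habitat.base_sizes,
            migration_rate=m,
        )
        base_deg = base.degrees()
    for k, g in enumerate(live):
        nbrs = habitat.neighbors(int(g))
        for j in nbrs:
            B[k, pos[j]] = m
        if lost_mode == "renormalize":
            B[k, k] = 1.0 - m * len(nbrs)
        elif lost_mode == "absorb":
            B[k, k] = 1.0 - m * base_deg[g]
        else:
            raise ValueError("lost_mode must be 'renormalize' or 'absorb'")
    if lost_mode == "absorb":
        B /= B.sum(axis=1, keepdims=True)
    return B


def init_state(habitat: Habitat, u: float, F0: float | np.ndarray = 0.0) -> PairIdentityState:
    live = habitat.live
    D = live.size
    F = np.full((D, D), float(F0)) if np.isscalar(F0) else np.asarray(F0, float).copy()
    return PairIdentityState(F=F, demes=live, u=u)


def _coalescent_G(F: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    c = 1.0 / (2.0 * sizes)
    G = F.copy()
    np.fill_diagonal(G, c + (1.0 - c) * np.diag(F))
    return G


def step(state: PairIdentityState, B: np.ndarray, sizes: np.ndarray) -> PairIdentityState:
    """One generation of the identity recursion ``F' = (1-u)^2 B G B^T``."""
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("zero-size demes must be removed via apply_loss before stepping")
    if B.shape[0] != state.n_demes or sizes.size != state.n_demes:
        raise ValueError("state, migration matrix, and sizes have mismatched dimensions")
    a = (1.0 - state.u) ** 2
    G = _coalescent_G(state.F, sizes)
    Fp = a * (B @ G @ B.T)
    Fp = 0.5 * (Fp + Fp.T)  # kill round-off asymmetry
    return PairIdentityState(F=Fp, demes=state.demes, u=state.u, generation=state.generation + 1)


def equilibrium(B: np.ndarray, sizes: np.ndarray, u: float) -> np.ndarray:
    """Direct solve of the linear fixed point ``F = (1-u)^2 B G(F) B^T``.

    Requires ``u > 0`` (at ``u = 0`` the system is singular: the only
    equilibrium is complete fixation, ``F = 1``).

    For the symmetric migration matrices produced by a uniform per-edge rate
    the D^2 pair system collapses: writing ``d_k = (1 - F[k,k]) / (2 N_k)``,
    the fixed point is ``F = a B F B + a B diag(d) B`` (``a = (1-u)^2``),
    which in the eigenbasis of ``B`` is diagonal given ``d``; only the D
    within-deme identities couple, so a single D x D solve suffices.  A
    sparse LU on the vectorized D^2 system handles non-symmetric ``B``.
    """
    if u <= 0:
        raise ValueError(
            "equilibrium requires u > 0; with u = 0 only F = 1 is stationary "
            "(use propagate() for transient dynamics)"
        )
    sizes = np.asarray(sizes, dtype=float)
    D = sizes.size
    a = (1.0 - u) ** 2
    c = 1.0 / (2.0 * sizes)
    if np.allclose(B, B.T, atol=1e-12):
        lam, Q = np.linalg.eigh(B)
        M = (a * np.outer(lam, lam)) / (1.0 - a * np.outer(lam, lam))
        # T[k, l] = (q_k * q_l)^T M (q_k * q_l) maps d to diag(F)
        T = np.empty((D, D))
        for k in range(D):
            Ck = Q * Q[k]  # rows: q_l * q_k elementwise
            T[k] = np.einsum("li,li->l", Ck @ M, Ck)
        d = np.linalg.solve(np.eye(D) + c[:, None] * T, c)
        Dt = Q.T @ (d[:, None] * Q)
        F = Q @ (M * Dt) @ Q.T
    else:
        K = sp.kron(sp.csr_matrix(B), sp.csr_matrix(B), format="csr")
        diag_pos = np.arange(D) * D + np.arange(D)
        dvec = np.zeros(D * D)
        dvec[diag_pos] = c
        M = a * (K @ sp.diags(1.0 - dvec, format="csr"))
        p0 = np.zeros(D * D)
        p0[diag_pos] = c
        rhs = a * (K @ p0)
        f = spla.spsolve((sp.identity(D * D, format="csr") - M).tocsc(), rhs)
        F = f.reshape(D, D)
    return 0.5 * (F + F.T)


def equilibrium_state(habitat: Habitat, u: float, lost_mode: str = "renormalize") -> PairIdentityState:
    """Equilibrium :class:`PairIdentityState` for a habitat's live demes."""
    live = habitat.live
    B = backward_migration(habitat, lost_mode=lost_mode)
    F = equilibrium(B, habitat.sizes[live], u)
    return PairIdentityState(F=F, demes=live, u=u)


# -- diversity summaries -------------------------------------------------

def pi_species(state: PairIdentityState, sizes: np.ndarray) -> float:
    """Size-weighted species-wide pi: ``sum_ij w_i w_j H[i, j]`` with
    ``w_i = N_i / sum N`` (ordered pairs, within-deme pairs included)."""
    sizes = np.asarray(sizes, dtype=float)
    total = sizes.sum()
    if total <= 0:
        raise ValueError("live sizes must sum to a positive total")
    w = sizes / total
    return float(w @ state.H @ w)


def pi_local(state: PairIdentityState, sizes: np.ndarray | None = None) -> float:
    """Unweighted mean within-deme pi over live demes (grid-cell average)."""
    if state.n_demes == 0:
        raise ValueError("no live demes")
    return float(np.mean(np.diag(state.H)))


def pairwise_fst(state: PairIdentityState) -> tuple[np.ndarray, float]:
    """Hudson-style F_ST per deme pair from model heterozygosities.

    ``F_ST(i, j) = 1 - mean(H[i,i], H[j,j]) / H[i,j]`` where defined; the
    average is over unordered pairs ``i < j``.
    """
    D = state.n_demes
    if D < 2:
        raise ValueError("F_ST needs at least two demes")
    H = state.H
    within = np.diag(H)
    fst = np.zeros((D, D))
    vals = []
    for i in range(D):
        for j in range(i + 1, D):
            hb = H[i, j]
            if hb > 0:
                v = 1.0 - 0.5 * (within[i] + within[j]) / hb
            else:
                if within[i] > 0 or within[j] > 0:
                    warnings.warn(f"deme pair ({i},{j}) has zero between-pi; skipped")
                    continue
                v = 0.0
            fst[i, j] = fst[j, i] = v
            vals.append(v)
    return fst, float(np.mean(vals)) if vals else 0.0


# -- habitat change ------------------------------------------------------

def apply_loss(
    state: PairIdentityState, habitat_after: Habitat, mode: str = "renormalize"
) -> PairIdentityState:
    """Restrict the identity state to the demes surviving a habitat change.

    The surviving block of ``F`` becomes the initial condition of the
    post-loss system; the caller rebuilds migration from ``habitat_after``
    (``backward_migration(habitat_after, lost_mode=mode)``).
    """
    survivors = habitat_after.live
    if survivors.size == 0:
        raise ValueError("habitat change destroyed every deme")
    pos = {int(g): k for k, g in enumerate(state.demes)}
    try:
        keep = np.array([pos[int(g)] for g in survivors])
    except KeyError as e:
        raise ValueError(f"surviving deme {e} is not part of the current state") from None
    return PairIdentityState(
        F=state.F[np.ix_(keep, keep)].copy(), demes=survivors, u=state.u, generation=0
    )


def apply_restore(
    state: PairIdentityState, habitat_after: Habitat, founding: str = "from_neighbors"
) -> PairIdentityState:
    """Extend the state to newly restored demes.

    ``from_neighbors``: each new deme is founded by a sample of its live
    neighbors -- its ``F`` row is the neighbor average and its within-deme
    identity the average over neighbor pairs.  ``translocation``: founders are
    drawn landscape-wide, so rows take the size-weighted landscape average.
    A restored deme without live old neighbors falls back to translocation.
    """
    if founding not in ("from_neighbors", "translocation"):
        raise ValueError("founding must be 'from_neighbors' or 'translocation'")
    old = state.demes
    new_live = habitat_after.live
    old_pos = {int(g): k for k, g in enumerate(old)}
    added = [int(g) for g in new_live if int(g) not in old_pos]
    if not added:
        return state.copy()
    D_new = new_live.size
    sizes_old = habitat_after.sizes[old]
    w = sizes_old / sizes_old.sum()
    F_new = np.zeros((D_new, D_new))
    new_pos = {int(g): k for k, g in enumerate(new_live)}
    # carry over the existing block
    for gi in old:
        for gj in old:
            F_new[new_pos[int(gi)], new_pos[int(gj)]] = state.F[old_pos[int(gi)], old_pos[int(gj)]]
    landscape_row = w @ state.F  # F between a landscape-average founder and each old deme
    landscape_avg = float(w @ state.F @ w)

    founder_rows = {}  # new deme -> (row over old demes, within-identity)
    for g in added:
        nbrs = [j for j in habitat_after.neighbors(g) if j in old_pos]
        if founding == "from_neighbors" and not nbrs:
            warnings.warn(
                f"restored deme {g} has no live pre-existing neighbor; using translocation founding"
            )
        if founding == "from_neighbors" and nbrs:
            idx = [old_pos[j] for j in nbrs]
            row = state.F[idx].mean(axis=0)
            within = float(state.F[np.ix_(idx, idx)].mean())
        else:
            row = landscape_row
            within = landscape_avg
        founder_rows[g] = (row, within)

    for g in added:
        row, within = founder_rows[g]
        k = new_pos[g]
        for gj in old:
            F_new[k, new_pos[int(gj)]] = F_new[new_pos[int(gj)], k] = row[old_pos[int(gj)]]
        F_new[k, k] = within
    # between two restored demes: founders are independent draws from their sources
    for gi in added:
        for gj in added:
            if gi == gj:
                continue
            row_i, _ = founder_rows[gi]
            row_j, _ = founder_rows[gj]
            # identity between a founder of i and a founder of j ~ cross average
            if founding == "from_neighbors":
                nb_j = [old_pos[x] for x in habitat_after.neighbors(gj) if x in old_pos]
                val = float(row_i[nb_j].mean()) if nb_j else float(row_i @ w)
            else:
                val = float(row_i @ w)
            F_new[new_pos[gi], new_pos[gj]] = val
    F_new = 0.5 * (F_new + F_new.T)
    return PairIdentityState(F=F_new, demes=new_live, u=state.u, generation=0)


def propagate(
    state: PairIdentityState,
    B: np.ndarray,
    sizes: np.ndarray,
    generations: int,
    record_every: int = 1,
) -> tuple[PairIdentityState, Trajectory]:
    """Iterate the recursion, recording pi summaries every ``record_every`` steps."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    sizes = np.asarray(sizes, dtype=float)
    gens = [state.generation]
    pis = [pi_species(state, sizes)]
    locs = [pi_local(state, sizes)]
    cur = state
    for t in range(1, generations + 1):
        cur = step(cur, B, sizes)
        if t % record_every == 0 or t == generations:
            gens.append(cur.generation)
            pis.append(pi_species(cur, sizes))
            locs.append(pi_local(cur, sizes))
    return cur, Trajectory(np.array(gens), np.array(pis), np.array(locs))


# -- calibration and fitting --------------------------------------------

def _avg_fst_at(habitat: Habitat, m: float, u: float) -> float:
    hab = replace(habitat, migration_rate=m)
    return pairwise_fst(equilibrium_state(hab, u))[1]


def calibrate_migration(
    habitat: Habitat,
    u: float,
    target_fst: float,
    tol: float = 1e-3,
    m_min: float = 1e-10,
) -> float:
    """Migration rate whose equilibrium average pairwise F_ST matches a target.

    Average pairwise F_ST is monotone decreasing in ``m``, so the root is
    bracketed on ``log m`` between ``m_min`` and the largest admissible rate
    (``m * max_degree < 1``).  If the target lies outside the attainable
    range the boundary rate is returned with a warning.
    """
    if not 0 <= target_fst < 1:
        raise ValueError("target F_ST must be in [0, 1)")
    max_deg = max(int(habitat.degrees().max()), 1)
    m_max = (1.0 - 1e-9) / max_deg
    f_hi = _avg_fst_at(habitat, m_max, u)  # smallest attainable F_ST
    if target_fst <= f_hi:
        if target_fst < f_hi - tol:
            warnings.warn(
                f"target F_ST {target_fst:.4g} below attainable minimum {f_hi:.4g}; "
                "returning maximum migration rate"
            )
        return m_max
    f_lo = _avg_fst_at(habitat, m_min, u)  # largest attainable F_ST
    if target_fst >= f_lo:
        warnings.warn(
            f"target F_ST {target_fst:.4g} above attainable maximum {f_lo:.4g}; "
            "returning minimum migration rate"
        )
        return m_min
    log_m = brentq(
        lambda lm: _avg_fst_at(habitat, 10.0 ** lm, u) - target_fst,
        np.log10(m_min),
        np.log10(m_max),
        xtol=1e-4,
        rtol=1e-12,
    )
    return 10.0 ** log_m


@dataclass
class TrajectoryFit:
    u: float
    m: float
    time_scale: float
    residual: float
    converged: bool


def fit_to_trajectory(
    observed: Trajectory,
    habitat: Habitat,
    loss_fraction: float = 0.0,
    edge: str = "north",
    x0: tuple[float, float, float] | None = None,
    maxiter: int = 200,
) -> TrajectoryFit:
    """Least-squares fit of the moment model to an observed pi trajectory.

    The model is the habitat's edge-contraction scenario: equilibrium at
    parameters ``(u, m)``, contraction by ``loss_fraction``, then transient
    species-wide pi evaluated at ``generation * time_scale``.  Minimization is
    derivative-free (Powell) over ``(log10 u, log10 m, log10 time_scale)``
    with the deme sizes (hence N_e) held fixed.
    """
    from .habitat import edge_contraction

    if observed.generations.size < 3:
        raise ValueError("need at least 3 observed timepoints")
    obs_g = observed.generations.astype(float)
    obs_pi = observed.pi_species
    if x0 is None:
        x0 = (1e-6, habitat.migration_rate, 1.0)
    max_deg = max(int(habitat.degrees().max()), 1)

    def model_pi(u: float, m: float, scale: float) -> np.ndarray:
        hab = replace(habitat, migration_rate=m)
        pre = equilibrium_state(hab, u)
        hab2 = edge_contraction(hab, loss_fraction, edge) if loss_fraction > 0 else hab
        post = apply_loss(pre, hab2)
        sizes = hab2.sizes[hab2.live]
        B = backward_migration(hab2)
        t_max = int(np.ceil(obs_g.max() * scale)) + 1
        rec = max(1, t_max // 400)
        _, traj = propagate(post, B, sizes, t_max, record_every=rec)
        return np.interp(obs_g * scale, traj.generations, traj.pi_species)

    def objective(x: np.ndarray) -> float:
        u, m, scale = 10.0 ** x
        if u >= 0.5 or m * max_deg >= 1.0 or scale > 1e3:
            return 1e6
        return float(np.sum((model_pi(u, m, scale) - obs_pi) ** 2))

    res = minimize(
        objective,
        np.log10(np.array(x0)),
        method="Powell",
        options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-8},
    )
    u, m, scale = 10.0 ** res.x
    if not res.success:
        warnings.warn("trajectory fit did not converge; returning best parameters so far")
    return TrajectoryFit(u=u, m=m, time_scale=scale, residual=float(res.fun), converged=bool(res.success))
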