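"""Canonical landscape experiments: contraction grids, fragmentation
ensembles, and forward-simulation cross-checks.

These functions package the study designs the library exists to run --
short/mid/long-term loss grids over population-structure levels, ensembles
of random fragmentation maps with landscape metrics, and engine-vs-simulator
comparisons -- at configurable scale.  They are used both programmatically
and by the reproduction script.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .forecast import ModelConfig, calibrated_habitat, forecast
from .forward import restrict_state, simulate
from .gdar import fit_power_law, predict_loss
from .habitat import build_grid_habitat, edge_contraction, random_fragmentation
from .landscape import summarize
from .moments import (
    apply_loss,
    backward_migration,
    equilibrium_state,
    pairwise_fst,
    pi_local,
    pi_species,
    propagate,
)

__all__ = [
    "gdar_engine_grid",
    "fragmentation_ensemble",
    "oracle_contraction",
    "oracle_fragmentation",
]

DEFAULT_FSTS = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.75, 0.9)
DEFAULT_LOSSES = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))


def gdar_engine_grid(
    fsts=DEFAULT_FSTS,
    losses=DEFAULT_LOSSES,
    config: ModelConfig = ModelConfig(),
):
    """Short-term contraction losses over an F_ST x area-loss grid, with a
    GDAR power law fitted per structure level.

    Returns ``(points, fits, pooled_r2)``: the long-format loss table, the
    per-F_ST :class:`~landgen.gdar.PowerLawFit`, and the pooled coefficient
    of determination of the fitted power laws on the untransformed loss
    scale across all points.
    """
    rows = []
    for fst in fsts:
        for loss in losses:
            r = forecast(loss, fst, "short", "contraction", config=config)
            rows.append({"fst": fst, "loss": loss,
                         "short_loss": max(0.0, r.loss_species)})
    points = pd.DataFrame(rows)
    fits = {}
    ss_res = ss_tot = 0.0
    all_y = points["short_loss"].to_numpy()
    for fst, g in points.groupby("fst"):
        fit = fit_power_law(np.column_stack([g["loss"], g["short_loss"]]))
        fits[fst] = fit
        pred = predict_loss(fit.z, g["loss"].to_numpy())
        ss_res += float(np.sum((g["short_loss"].to_numpy() - pred) ** 2))
    ss_tot = float(np.sum((all_y - all_y.mean()) ** 2))
    pooled_r2 = 1.0 - ss_res / ss_tot
    return points, fits, pooled_r2


def fragmentation_ensemble(
    n_maps: int = 60,
    loss_range: tuple[float, float] = (0.06, 0.93),
    fixed_loss: float | None = None,
    seed: int = 0,
    fst: float = 0.0,
    config: ModelConfig = ModelConfig(),
) -> pd.DataFrame:
    """Random fragmentation maps with diversity outcomes and landscape metrics.

    Each map destroys a random deme subset (loss fractions spread over
    ``loss_range``, or all at ``fixed_loss``); the moment engine tracks
    species-wide and mean local pi at the short (1 generation), mid
    (``config.mid_gens()``), and long (``config.long_generations``) horizons,
    all relative to the pre-loss equilibrium of the calibrated base model.
    FRAGSTATS-style metrics of each surviving map are attached.
    """
    hab = calibrated_habitat(fst, config)
    pre = equilibrium_state(hab, config.u)
    sizes0 = hab.sizes[hab.live]
    pi0 = pi_species(pre, sizes0)
    loc0 = pi_local(pre)
    mid_g = config.mid_gens()
    long_g = config.long_generations
    rows = []
    for k in range(n_maps):
        frac = fixed_loss if fixed_loss is not None else (
            loss_range[0] + (loss_range[1] - loss_range[0]) * k / max(n_maps - 1, 1)
        )
        hf = random_fragmentation(hab, frac, seed=seed + k)
        realized = 1.0 - hf.live.size / hab.live.size
        post = apply_loss(pre, hf)
        sizes = hf.sizes[hf.live]
        B = backward_migration(hf)
        st_short, _ = propagate(post, B, sizes, 1)
        st_mid, _ = propagate(st_short, B, sizes, mid_g - 1, record_every=10**9)
        st_long, _ = propagate(st_mid, B, sizes, long_g - mid_g, record_every=10**9)
        summ = summarize(hf.mask)
        rows.append(
            {
                "map_seed": seed + k,
                "a_lost": realized,
                "all_isolated": bool(hf.degrees().max() == 0),
                "pi_species_short": pi_species(st_short, sizes) / pi0,
                "pi_species_mid": pi_species(st_mid, sizes) / pi0,
                "pi_species_long": pi_species(st_long, sizes) / pi0,
                "pi_local_short": pi_local(st_short) / loc0,
                "pi_local_mid": pi_local(st_mid) / loc0,
                "pi_local_long": pi_local(st_long) / loc0,
                "n_patches": summ.n_patches,
                "edge_density": summ.edge_density,
                "cohesion": summ.cohesion,
                "total_core_area": summ.total_core_area,
            }
        )
    return pd.DataFrame(rows)


def _scaled_system(rows=6, cols=6, deme_size=10, m=0.05, u=1e-4):
    return build_grid_habitat(rows, cols, deme_size, m), u


def oracle_contraction(
    loss_levels=DEFAULT_LOSSES,
    n_replicates: int = 9,
    seed: int = 0,
    rows: int = 6,
    cols: int = 6,
    deme_size: int = 10,
    m: float = 0.05,
    u: float = 1e-4,
    L: int = 400,
    burn_factor: int = 4,
):
    """Engine vs forward-simulated short-term contraction losses.

    Burns in ``n_replicates`` independent forward simulations of a scaled
    landscape, applies each edge-contraction level to each replicate, and
    compares the one-generation pi loss against the moment-engine
    prediction.  Returns ``(frame, r2)`` where the regression pools every
    replicate run (``len(loss_levels) * n_replicates`` points).
    """
    hab, _ = _scaled_system(rows, cols, deme_size, m, u)
    eng_pre = equilibrium_state(hab, u)
    pi0 = pi_species(eng_pre, hab.sizes[hab.live])
    burn = burn_factor * rows * cols * deme_size
    states = []
    for r in range(n_replicates):
        st, _ = simulate(hab, u, L, burn, seed=seed * 1000 + r, record_every=burn)
        states.append(st)
    rows_out = []
    for frac in loss_levels:
        h2 = edge_contraction(hab, frac, "north")
        post = apply_loss(eng_pre, h2)
        sizes2 = h2.sizes[h2.live]
        B2 = backward_migration(h2)
        st1, _ = propagate(post, B2, sizes2, 1)
        eng_loss = 1.0 - pi_species(st1, sizes2) / pi0
        for r, st in enumerate(states):
            pre_pi = st.pi_species()
            sub = restrict_state(st, h2)
            sub2, _ = simulate(h2, u, L, 1, seed=seed * 1000 + 500 + r, state=sub)
            rows_out.append(
                {"loss": frac, "replicate": r, "engine": eng_loss,
                 "sim": 1.0 - sub2.pi_species() / pre_pi}
            )
    frame = pd.DataFrame(rows_out)
    reg = stats.linregress(frame["engine"], frame["sim"])
    return frame, float(reg.rvalue**2)


def oracle_fragmentation(
    n_maps: int = 50,
    n_replicates: int = 2,
    seed: int = 0,
    loss_range: tuple[float, float] = (0.06, 0.93),
    rows: int = 6,
    cols: int = 6,
    deme_size: int = 10,
    m: float = 0.05,
    u: float = 1e-4,
    L: int = 300,
    burn_factor: int = 4,
    horizon_factor: int = 4,
):
    """Engine vs forward-simulated long-horizon pi across fragmentation maps.

    The long horizon is scaled with the landscape (``horizon_factor`` times
    the total census size, mirroring ~20,000 generations for a census of
    5,000).  Returns ``(frame, r2)`` with per-map engine and replicate-mean
    simulated species-wide pi relative to pre-loss.
    """
    hab, _ = _scaled_system(rows, cols, deme_size, m, u)
    n_total = rows * cols * deme_size
    horizon = horizon_factor * n_total
    eng_pre = equilibrium_state(hab, u)
    pi0 = pi_species(eng_pre, hab.sizes[hab.live])
    burn = burn_factor * n_total
    states = []
    for r in range(n_replicates):
        st, _ = simulate(hab, u, L, burn, seed=seed * 997 + r, record_every=burn)
        states.append(st)
    rows_out = []
    for k in range(n_maps):
        frac = loss_range[0] + (loss_range[1] - loss_range[0]) * k / max(n_maps - 1, 1)
        hf = random_fragmentation(hab, frac, seed=seed + 7000 + k)
        post = apply_loss(eng_pre, hf)
        sizes = hf.sizes[hf.live]
        B = backward_migration(hf)
        st_long, _ = propagate(post, B, sizes, horizon, record_every=10**9)
        eng_pi = pi_species(st_long, sizes) / pi0
        sims = []
        for r, st in enumerate(states):
            pre_pi = st.pi_species()
            sub = restrict_state(st, hf)
            sub2, _ = simulate(hf, u, L, horizon, seed=seed * 131 + 100 * k + r,
                               state=sub, record_every=horizon)
            sims.append(sub2.pi_species() / pre_pi)
        rows_out.append(
            {"a_lost": 1.0 - hf.live.size / hab.live.size,
             "engine": eng_pi, "sim": float(np.mean(sims))}
        )
    frame = pd.DataFrame(rows_out)
    reg = stats.linregress(frame["engine"], frame["sim"])
    return frame, float(reg.rvalue**2)
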