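"""Deme landscapes and habitat-change scenarios.

A habitat is a rectangular grid of demes (locally panmictic subpopulations)
with rook (4-neighbor) adjacency and a single per-edge migration rate.
Habitat change is expressed by switching demes off (size -> 0, edges removed)
or back on.  Grid coordinates are 0-based ``(row, col)`` with row 0 = north.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Habitat",
    "ScenarioSchedule",
    "build_grid_habitat",
    "edge_contraction",
    "random_fragmentation",
    "gradual_schedule",
    "restore",
    "mask_to_csv",
    "mask_from_csv",
]

EDGES = ("north", "south", "east", "west")


@dataclass(frozen=True)
class Habitat:
    """A grid of demes with per-deme diploid sizes and nearest-neighbor migration.

    Parameters
    ----------
    rows, cols
        Grid dimensions; ``rows == 1`` gives a 1-D stepping-stone chain.
    sizes
        Length ``rows*cols`` array of diploid census sizes ``N_i``; a size of
        zero marks a destroyed (non-habitat) deme.
    migration_rate
        Per-generation probability ``m`` that a lineage's parent lived in one
        given adjacent deme.  Total emigration per deme is ``m * degree``.
    """

    rows: int
    cols: int
    sizes: np.ndarray
    migration_rate: float
    base_sizes: np.ndarray = field(default=None)  # original sizes, for restore

    def __post_init__(self):
        sizes = np.asarray(self.sizes, dtype=float)
        if sizes.shape != (self.rows * self.cols,):
            raise ValueError("sizes must have length rows*cols")
        if np.any(sizes < 0):
            raise ValueError("deme sizes must be non-negative")
        if self.migration_rate < 0:
            raise ValueError("migration rate must be non-negative")
        object.__setattr__(self, "sizes", sizes)
        if self.base_sizes is None:
            object.__setattr__(self, "base_sizes", sizes.copy())
        max_deg = self.degrees().max(initial=0)
        if max_deg and self.migration_rate * max_deg >= 1.0:
            raise ValueError(
                f"invalid migration: m*degree = {self.migration_rate * max_deg:.3g} >= 1"
            )

    # -- indexing helpers ------------------------------------------------
    @property
    def n_demes(self) -> int:
        return self.rows * self.cols

    def index(self, row: int, col: int) -> int:
        return row * self.cols + col

    def coord(self, i: int) -> tuple[int, int]:
        return divmod(i, self.cols)

    @property
    def live(self) -> np.ndarray:
        """Indices of live (non-destroyed) demes, in row-major order."""
        return np.flatnonzero(self.sizes > 0)

    @property
    def mask(self) -> np.ndarray:
        """Binary ``rows x cols`` occupancy grid (1 = live habitat)."""
        return (self.sizes > 0).astype(int).reshape(self.rows, self.cols)

    def neighbors(self, i: int) -> list[int]:
        """Live rook neighbors of deme ``i`` (itself need not be live)."""
        r, c = self.coord(i)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.rows and 0 <= cc < self.cols:
                j = self.index(rr, cc)
                if self.sizes[j] > 0:
                    out.append(j)
        return out

    def degrees(self) -> np.ndarray:
        """Number of live neighbors per live deme (zeros for dead demes)."""
        deg = np.zeros(self.n_demes, dtype=int)
        for i in np.flatnonzero(self.sizes > 0):
            deg[i] = len(self.neighbors(i))
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency among all grid positions, restricted to live demes."""
        A = np.zeros((self.n_demes, self.n_demes), dtype=int)
        for i in self.live:
            for j in self.neighbors(i):
                A[i, j] = 1
        return A

    def is_connected(self) -> bool:
        """Flood fill over live demes under rook adjacency."""
        live = self.live
        if live.size == 0:
            return True
        seen = {int(live[0])}
        stack = [int(live[0])]
        while stack:
            for j in self.neighbors(stack.pop()):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == live.size


@dataclass(frozen=True)
class ScenarioSchedule:
    """Ordered habitat-change events: ``(generation_offset, deme_ids, action)``."""

    events: tuple
    total_fraction: float

    def __post_init__(self):
        offsets = [e[0] for e in self.events]
        if any(b < a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("event offsets must be non-decreasing")

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_fraction": self.total_fraction,
                "events": [
                    {"offset": int(o), "demes": [int(d) for d in ds], "action": a}
                    for o, ds, a in self.events
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSchedule":
        obj = json.loads(text)
        events = tuple(
            (e["offset"], tuple(e["demes"]), e["action"]) for e in obj["events"]
        )
        return cls(events=events, total_fraction=obj["total_fraction"])


def build_grid_habitat(
    rows: int, cols: int, deme_size: float, migration_rate: float
) -> Habitat:
    """Uniform ``rows x cols`` grid of demes with rook adjacency.

    ``migration_rate`` is the per-adjacent-deme backward migration probability;
    it must satisfy ``m * 4 < 1`` (interior demes have four neighbors; for 1-D
    habitats the constraint is checked against the actual maximum degree).
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    if deme_size <= 0:
        raise ValueError("deme_size must be positive")
    sizes = np.full(rows * cols, float(deme_size))
    return Habitat(rows=rows, cols=cols, sizes=sizes, migration_rate=migration_rate)


def _edge_order(habitat: Habitat, edge: str) -> np.ndarray:
    """Grid indices sorted edge-inward, row-major ties within each line."""
    if edge not in EDGES:
        raise ValueError(f"edge must be one of {EDGES}")
    idx = np.arange(habitat.n_demes)
    r, c = np.divmod(idx, habitat.cols)
    if edge == "north":
        key = (r, c)
    elif edge == "south":
        key = (habitat.rows - 1 - r, c)
    elif edge == "west":
        key = (c, r)
    else:  # east
        key = (habitat.cols - 1 - c, r)
    return idx[np.lexsort((key[1], key[0]))]


def edge_contraction(habitat: Habitat, fraction: float, edge: str = "north") -> Habitat:
    """Remove ``floor(fraction * D)`` live demes line-by-line from one edge.

    Whole rows (or columns, for east/west) are removed edge-inward; a partial
    final line is removed in row-major reading order.  The remaining habitat
    stays rook-connected for any ``fraction < 1``.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1): all-habitat destruction is not a scenario")
    live = habitat.live
    n_remove = int(np.floor(fraction * live.size))
    order = [i for i in _edge_order(habitat, edge) if habitat.sizes[i] > 0]
    doomed = set(order[:n_remove])
    sizes = habitat.sizes.copy()
    sizes[list(doomed)] = 0.0
    return replace(habitat, sizes=sizes)


def random_fragmentation(habitat: Habitat, fraction: float, seed: int) -> Habitat:
    """Destroy a uniformly random subset of ``round(fraction * D)`` live demes.

    The seed fully determines the map; survivors may be disconnected.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    live = habitat.live
    n_remove = int(round(fraction * live.size))
    doomed = rng.choice(live, size=n_remove, replace=False)
    sizes = habitat.sizes.copy()
    sizes[doomed] = 0.0
    return replace(habitat, sizes=sizes)


def gradual_schedule(
    habitat: Habitat,
    total_fraction: float,
    step_fraction: float,
    interval: int,
    edge: str = "north",
) -> ScenarioSchedule:
    """Spread an edge contraction over time: ``ceil(total/step)`` removal
    events spaced ``interval`` generations apart, each removing
    ``round(step_fraction * D)`` demes edge-inward (the final event removes
    whatever remains of the target)."""
    if step_fraction <= 0 and total_fraction > 0:
        raise ValueError("step_fraction must be positive when total_fraction > 0")
    if step_fraction > total_fraction:
        raise ValueError("step_fraction cannot exceed total_fraction")
    if interval < 1:
        raise ValueError("interval must be >= 1 generation")
    live = habitat.live
    d0 = live.size
    n_total = int(np.floor(total_fraction * d0))
    per_step = max(1, int(round(step_fraction * d0)))
    order = [i for i in _edge_order(habitat, edge) if habitat.sizes[i] > 0]
    events = []
    taken = 0
    k = 0
    while taken < n_total:
        chunk = order[taken : min(taken + per_step, n_total)]
        events.append((k * interval, tuple(int(i) for i in chunk), "remove"))
        taken += len(chunk)
        k += 1
    return ScenarioSchedule(events=tuple(events), total_fraction=n_total / d0 if d0 else 0.0)


def restore(habitat: Habitat, deme_set) -> Habitat:
    """Re-add previously destroyed demes with their original sizes and edges.

    Restoring a deme that is already live is a no-op with a warning.  How the
    restored demes are founded genetically is decided by the moments engine
    (``apply_restore``), not here.
    """
    sizes = habitat.sizes.copy()
    for i in deme_set:
        if sizes[i] > 0:
            warnings.warn(f"deme {i} is already live; restore is a no-op", stacklevel=2)
            continue
        sizes[i] = habitat.base_sizes[i]
    return replace(habitat, sizes=sizes)


# -- CSV mask round trip -------------------------------------------------

def mask_to_csv(habitat: Habitat, path) -> None:
    np.savetxt(path, habitat.mask, fmt="%d", delimiter=",")


def mask_from_csv(path, deme_size: float, migration_rate: float) -> Habitat:
    mask = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    sizes = (mask.ravel() > 0) * float(deme_size)
    base = np.full(mask.size, float(deme_size))
    return Habitat(
        rows=mask.shape[0],
        cols=mask.shape[1],
        sizes=sizes,
        migration_rate=migration_rate,
        base_sizes=base,
    )
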