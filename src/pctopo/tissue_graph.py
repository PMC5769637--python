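"""Graph model of cell divisions in a boundary-free epithelium.

Cells are nodes; two cells are linked when they share a wall.  Because
four-way cell junctions are excluded, the tissue is a trivalent map and a
cell's neighbour number equals its side number.  A bare graph cannot say
which neighbours are *contiguous* along a cell's boundary, so the model
stores a rotation system: for every cell, the counter-clockwise cyclic
order of its neighbours.  That is exactly the structure needed to divide a
cell: the new wall cuts two of the mother's interfaces, the two cut
neighbours ("junction neighbours") end up bordering both daughters, and the
remaining n - 2 neighbours are split into two contiguous arcs.

Three topological division rules set the arc split a (a daughter keeping a
arc neighbours has a + 3 neighbours):

- ``equal``:  a = (n-2)/2, ties for odd n broken uniformly;
- ``random``: a uniform on {0, ..., n-2};
- ``pascal``: a = 1 + Binomial(n-4, 1/2) — the binomially weighted split in
  which the new wall never cuts two adjacent walls, so each daughter keeps
  at least one intact wall and has at least four sides (the kernel
  P(k|n) = C(n-4, k-4) / 2^(n-4) on k in [4, n]).  A 3-sided mother, where
  that kernel is undefined, splits into daughters {3, 4} (the only
  possibility); a 4-sided mother into {4, 4}.

Every division conserves deg(d1) + deg(d2) = n + 4 and raises the summed
neighbour count over the mother's former neighbours by exactly 2 (the two
junction neighbours gain one each).  On a torus initialisation the mean
neighbour number stays exactly 6 (Euler's relation for trivalent maps).

Divisions are scheduled either *without replacement* (every cell divides
exactly once per round, in shuffled order, each division seeing the updated
graph) or *with replacement* (the divider is drawn uniformly at every
event).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np

from .topology_stats import NeighborDistribution

__all__ = [
    "TissueGraph",
    "DivisionRule",
    "DivisionRecord",
    "SimulationConfig",
    "SimulationResult",
    "make_hex_torus",
    "divide_cell",
    "run_round_without_replacement",
    "run_events_with_replacement",
    "simulate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DivisionRule:
    """Topological division rule: how the mother's non-junction neighbours split.

    ``name`` is one of ``equal``, ``random``, ``pascal``; it fully determines
    the law of the arc split a.  For odd n under ``equal`` the two nearest
    splits are chosen with probability 1/2 each (``tie_break='uniform'``);
    the unordered daughter pair is the same either way.
    """

    name: str
    tie_break: str = "uniform"

    def __post_init__(self):
        if self.name not in ("equal", "random", "pascal"):
            raise ValueError(f"unknown rule {self.name!r}; use equal, random or pascal")
        if self.tie_break != "uniform":
            raise ValueError("only the uniform tie-break is defined")

    def draw_split(self, n: int, rng: np.random.Generator) -> int:
        """Draw the arc split a in {0, ..., n-2} for a mother with n neighbours."""
        if self.name == "equal":
            if n % 2 == 0:
                return (n - 2) // 2
            return int(rng.choice([(n - 3) // 2, (n - 1) // 2]))
        if self.name == "random":
            return int(rng.integers(0, n - 1))  # uniform on 0..n-2
        # pascal: binomial over the n-4 walls that may side with either
        # daughter once the two cut walls are required to be non-adjacent
        if n == 3:
            return int(rng.integers(0, 2))
        return 1 + int(rng.binomial(n - 4, 0.5))


@dataclass
class DivisionRecord:
    """Audit record of one division, measured on the graph as it happened."""

    mother: int
    daughters: tuple[int, int]
    mother_n: int
    daughter_n: tuple[int, int]
    neighbourhood_pre: int   # sum of degrees over the mother's neighbours, before
    neighbourhood_post: int  # same cells, after the division
    gained_one: int          # former neighbours whose degree rose by exactly 1
    changed_other: int       # former neighbours with any other degree change
    round: int | None = None
    replicate: int | None = None


class TissueGraph:
    """Rotation-system representation of a boundary-free cellular tissue.

    ``order[c]`` is the counter-clockwise cyclic sequence of the neighbours
    of cell ``c``; ``generation[c]`` counts the divisions in c's ancestry.
    """

    def __init__(self, order: dict[int, list[int]], generation: dict[int, int] | None = None):
        self.order = order
        self.generation = generation if generation is not None else {c: 0 for c in order}
        self._next_id = max(order, default=-1) + 1

    # -- basic queries ----------------------------------------------------

    @property
    def cells(self) -> Iterable[int]:
        return self.order.keys()

    @property
    def n_cells(self) -> int:
        return len(self.order)

    def degree(self, cell: int) -> int:
        return len(self.order[cell])

    def neighbour_counts(self) -> np.ndarray:
        return np.fromiter((len(v) for v in self.order.values()), dtype=np.int64,
                           count=len(self.order))

    def distribution(self) -> NeighborDistribution:
        return NeighborDistribution.from_counts(self.neighbour_counts())

    def copy(self) -> "TissueGraph":
        return TissueGraph({c: list(v) for c, v in self.order.items()},
                           dict(self.generation))

    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    # -- consistency ------------------------------------------------------

    def validate(self, faces: bool = False) -> None:
        """Check the rotation-system invariants; raise on corruption.

        Verifies symmetric adjacency, single occurrence of each neighbour in
        every cycle, and minimum degree 3.  With ``faces=True`` additionally
        traces every face of the embedding and requires them all to be
        triangles — i.e. every junction of the tissue is tricellular and the
        cyclic orders are globally orientation-consistent.
        """
        for c, nbrs in self.order.items():
            if len(nbrs) < 3:
                raise ValueError(f"cell {c} has {len(nbrs)} < 3 neighbours")
            if len(set(nbrs)) != len(nbrs):
                raise ValueError(f"cell {c} lists a neighbour more than once")
            for v in nbrs:
                if v == c:
                    raise ValueError(f"cell {c} is its own neighbour")
                if v not in self.order or c not in self.order[v]:
                    raise ValueError(f"asymmetric adjacency {c} -> {v}")
        if faces:
            for length in self._face_lengths():
                if length != 3:
                    raise ValueError(f"non-tricellular junction: face of length {length}")

    def _face_lengths(self) -> list[int]:
        """Trace all faces of the embedding (next edge after u->v leaves v
        towards the successor of u in v's rotation)."""
        succ = {}
        for v, nbrs in self.order.items():
            k = len(nbrs)
            for i, u in enumerate(nbrs):
                succ[(u, v)] = (v, nbrs[(i + 1) % k])
        seen = set()
        lengths = []
        for start in succ:
            if start in seen:
                continue
            e, steps = start, 0
            while True:
                seen.add(e)
                e = succ[e]
                steps += 1
                if e == start:
                    break
            lengths.append(steps)
        return lengths


def make_hex_torus(rows: int, cols: int, seed: int | None = None) -> TissueGraph:
    """Boundary-free hexagonal lattice on a torus: every cell has 6 neighbours.

    Cells sit on a triangular lattice with axial coordinates (r, c) taken
    modulo (rows, cols); the six neighbour offsets are stored in
    counter-clockwise order, giving a consistent rotation system whose faces
    are all triangles.  Dimensions below 3 are rejected: wrap-around would
    make two offsets coincide, so a cell would meet the same cell across two
    walls (or itself) and the lattice would not have six distinct
    neighbours per cell.

    ``seed``, if given, randomly permutes the cell ids (the topology is
    deterministic regardless).
    """
    # CCW axial directions on the triangular lattice
    dirs = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]
    offs = {( (dr % rows), (dc % cols) ) for dr, dc in dirs}
    if rows * cols < 8:
        raise ValueError(f"{rows}x{cols} torus too small: need at least 8 cells")
    if len(offs) != 6 or (0, 0) in offs:
        raise ValueError(
            f"{rows}x{cols} torus too small: wrap-around would duplicate walls "
            "or make a cell its own neighbour (need rows >= 3 and cols >= 3)")
    ids = np.arange(rows * cols)
    if seed is not None:
        ids = np.random.default_rng(seed).permutation(ids)
    idmap = {(r, c): int(ids[r * cols + c]) for r in range(rows) for c in range(cols)}
    order = {}
    for (r, c), i in idmap.items():
        order[i] = [idmap[((r + dr) % rows, (c + dc) % cols)] for dr, dc in dirs]
    return TissueGraph(order)


def divide_cell(g: TissueGraph, cell: int, rule: DivisionRule,
                rng: np.random.Generator,
                division_log: list[DivisionRecord] | None = None) -> tuple[int, int]:
    """Divide ``cell`` in place; return the two daughter ids.

    A starting interface i is drawn uniformly over the mother's n walls; the
    rule draws the arc split a.  The junction neighbours are the cells cut
    by the new wall's endpoints (cyclic positions i and i+a+1); they become
    adjacent to both daughters, inserted next to the new daughter-daughter
    edge with the global orientation preserved.  Daughter 1 keeps the a
    neighbours after the first junction, daughter 2 the other n - 2 - a.
    """
    if cell not in g.order:
        raise KeyError(f"no such cell: {cell}")
    cyc = g.order[cell]
    n = len(cyc)
    if len(set(cyc)) != n:
        raise ValueError(f"corrupted rotation order at cell {cell}")
    pre_deg = {v: len(g.order[v]) for v in cyc} if division_log is not None else None

    i = int(rng.integers(n))
    a = rule.draw_split(n, rng)
    j1 = cyc[i]
    j2 = cyc[(i + a + 1) % n]
    arc1 = [cyc[(i + k) % n] for k in range(1, a + 1)]
    arc2 = [cyc[(i + a + 1 + k) % n] for k in range(1, n - a - 1)]

    d1 = g.new_id()
    d2 = g.new_id()
    del g.order[cell]
    g.order[d1] = [j1, *arc1, j2, d2]
    g.order[d2] = [j2, *arc2, j1, d1]

    for v in arc1:
        g.order[v][g.order[v].index(cell)] = d1
    for v in arc2:
        g.order[v][g.order[v].index(cell)] = d2
    # junction neighbours: the mother entry becomes two consecutive entries,
    # ordered so that the cyclic orders stay globally counter-clockwise
    k1 = g.order[j1].index(cell)
    g.order[j1][k1:k1 + 1] = [d1, d2]
    k2 = g.order[j2].index(cell)
    g.order[j2][k2:k2 + 1] = [d2, d1]

    gen = g.generation.pop(cell) + 1
    g.generation[d1] = gen
    g.generation[d2] = gen

    if division_log is not None:
        deltas = [len(g.order[v]) - pre_deg[v] for v in cyc]
        division_log.append(DivisionRecord(
            mother=cell, daughters=(d1, d2), mother_n=n,
            daughter_n=(len(g.order[d1]), len(g.order[d2])),
            neighbourhood_pre=sum(pre_deg.values()),
            neighbourhood_post=sum(pre_deg[v] + dv for v, dv in zip(cyc, deltas)),
            gained_one=sum(dv == 1 for dv in deltas),
            changed_other=sum(dv not in (0, 1) for dv in deltas)))
    return d1, d2


def run_round_without_replacement(g: TissueGraph, rule: DivisionRule,
                                  rng: np.random.Generator,
                                  division_log: list[DivisionRecord] | None = None) -> TissueGraph:
    """One synchronous round: every cell present at the start divides once.

    Divisions happen asynchronously in uniformly shuffled order, each seeing
    the graph as left by the previous ones.  The cell count doubles.
    """
    cells = np.fromiter(g.order.keys(), dtype=np.int64, count=g.n_cells)
    rng.shuffle(cells)
    for c in cells:
        divide_cell(g, int(c), rule, rng, division_log)
    return g


def run_events_with_replacement(g: TissueGraph, rule: DivisionRule, n_events: int,
                                rng: np.random.Generator,
                                division_log: list[DivisionRecord] | None = None) -> TissueGraph:
    """``n_events`` divisions of uniformly drawn cells (daughters re-enter the pool)."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    pool = list(g.order)
    index = {c: k for k, c in enumerate(pool)}
    for _ in range(n_events):
        c = pool[int(rng.integers(len(pool)))]
        d1, d2 = divide_cell(g, c, rule, rng, division_log)
        k = index.pop(c)
        pool[k] = d1
        index[d1] = k
        index[d2] = len(pool)
        pool.append(d2)
    return g


@dataclass
class SimulationConfig:
    """Configuration of a division-rule simulation.

    ``rounds`` applies to the without-replacement scheme, ``n_events`` to
    the with-replacement scheme.  Replicate r runs with seed ``seed + r``.
    """

    rule: DivisionRule
    replacement: str = "without"          # 'without' | 'with'
    init: tuple[int, int] = (8, 8)        # hex-torus rows x cols
    rounds: int = 10
    n_events: int | None = None
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.rule, str):
            self.rule = DivisionRule(self.rule)
        if self.replacement not in ("without", "with"):
            raise ValueError("replacement must be 'with' or 'without'")
        if self.replacement == "without" and self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.replacement == "with" and (self.n_events is None or self.n_events < 0):
            raise ValueError("with-replacement runs need n_events >= 0")
        if self.init[0] * self.init[1] < 8:
            raise ValueError("initial lattice must have at least 8 cells")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SimulationResult:
    """Pooled final neighbour distribution, per-round summaries and event log."""

    config: SimulationConfig
    distribution: NeighborDistribution
    snapshots: "pd.DataFrame"             # replicate, round, n_cells, mu1, mu2
    events: list[DivisionRecord]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the configured simulation; fully reproducible from the seed.

    Aggregates the final neighbour-number distribution over replicates and
    logs every division (mother and daughter neighbour numbers plus the
    neighbourhood sums) for division-matrix estimation.
    """
    import pandas as pd

    events: list[DivisionRecord] = []
    pooled: list[int] = []
    snap_rows = []
    for r in range(config.replicates):
        rng = np.random.default_rng(config.seed + r)
        g = make_hex_torus(*config.init)
        if config.replacement == "without":
            for rnd in range(config.rounds):
                start = len(events)
                run_round_without_replacement(g, config.rule, rng, events)
                for ev in events[start:]:
                    ev.round, ev.replicate = rnd, r
                d = g.distribution()
                snap_rows.append((r, rnd, g.n_cells, d.mu1, d.mu2))
                log.info("replicate %d round %d: %d cells, mu1=%.4f mu2=%.4f",
                         r, rnd, g.n_cells, d.mu1, d.mu2)
        else:
            start = len(events)
            run_events_with_replacement(g, config.rule, config.n_events, rng, events)
            for ev in events[start:]:
                ev.replicate = r
            d = g.distribution()
            snap_rows.append((r, 0, g.n_cells, d.mu1, d.mu2))
            log.info("replicate %d: %d cells, mu1=%.4f mu2=%.4f",
                     r, g.n_cells, d.mu1, d.mu2)
        pooled.extend(int(x) for x in g.neighbour_counts())
    snapshots = pd.DataFrame(snap_rows, columns=["replicate", "round", "n_cells", "mu1", "mu2"])
    return SimulationResult(config, NeighborDistribution.from_counts(pooled), snapshots, events)
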