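"""Synthetic segmented tissues with ground truth, for pipeline testing.

No microscopy data ships with this package; every pipeline input can be
generated here instead, always together with its ground truth:

- :func:`voronoi_frame` rasterises a (optionally Lloyd-relaxed) Voronoi
  tessellation of random seed points into a label image.  Ground-truth
  adjacency is built with an independent region-adjacency-graph
  implementation (4-connected wall contact) and ground-truth areas by
  direct pixel tabulation; wall pairs absent from the generating Delaunay
  triangulation — rasterisation artefacts of near-degenerate four-cell
  junctions, where the raster must pick one diagonal — are reported
  separately in ``degenerate_walls``.  An optional linear density gradient
  mimics the graded cell sizes of a growing leaf.
- :func:`divide_frame` produces a second frame in which a chosen fraction
  of cells divide by a straight wall through the centroid at a uniformly
  random orientation (the geometric counterpart of the equal split under
  isotropic conditions), emitting the lineage map and the true division
  events; neighbour co-divisions ("contamination") can be injected at a
  stated rate and are flagged in the truth log.
- :func:`rule_event_stream` draws i.i.d. division events straight from a
  rule's analytic per-daughter distribution, for estimator tests that need
  no imaging at all.

The tessellations are convex — deliberately so: the statistics implemented
here are purely topological/areal and do not require lobed cell outlines.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from skimage.measure import label as cc_label

from .segmentation_topology import SegmentedFrame, analyse_frame, build_adjacency
from .topology_stats import analytic_division_matrix

__all__ = [
    "SyntheticFrameSpec",
    "SyntheticDivisionSpec",
    "SyntheticFrame",
    "SyntheticEvent",
    "voronoi_frame",
    "divide_frame",
    "rule_event_stream",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticFrameSpec:
    """Recipe for one rasterised Voronoi tissue.

    ``lloyd`` centroidal-relaxation iterations round the cells (0 keeps the
    raw Poisson-Voronoi mosaic); ``gradient`` g >= 0 makes the seed density
    increase linearly by a factor (1 + g) from top to bottom, emulating a
    tip-to-base cell-size gradient.  ``on_empty`` controls what happens when
    a seed ends up with no pixels: ``resample`` redraws it (with a warning),
    ``error`` raises.
    """

    n_seeds: int = 150
    shape: tuple[int, int] = (400, 400)
    lloyd: int = 2
    gradient: float = 0.0
    seed: int = 0
    on_empty: str = "resample"

    def __post_init__(self):
        if self.n_seeds < 4:
            raise ValueError("need at least 4 seeds")
        if self.lloyd < 0:
            raise ValueError("lloyd iterations must be >= 0")
        if self.gradient < 0:
            raise ValueError("gradient must be >= 0")
        if self.on_empty not in ("resample", "error"):
            raise ValueError("on_empty must be 'resample' or 'error'")


@dataclass(frozen=True)
class SyntheticDivisionSpec:
    """Recipe for a two-frame division time-lapse.

    ``fraction`` of the eligible (neighbour-complete) cells divide.  Base
    mothers are chosen mutually non-adjacent, so that without injected
    contamination every division is isolated; ``contamination`` is the
    expected fraction of *events* whose mother has a co-dividing neighbour,
    realised by making selected mothers drag one neighbour into dividing
    with the matching per-mother probability.  Contaminated events are
    flagged in the truth log.
    """

    fraction: float = 0.2
    contamination: float = 0.0
    plane_rule: str = "random-orientation-through-centroid"
    min_daughter_area: int = 4
    max_retries: int = 30
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        if not 0 <= self.contamination <= 1:
            raise ValueError("contamination must be in [0, 1]")
        if self.plane_rule != "random-orientation-through-centroid":
            raise ValueError("only the random-orientation-through-centroid rule is defined")


@dataclass
class SyntheticFrame:
    """A generated frame plus its ground truth."""

    frame: SegmentedFrame
    seeds: np.ndarray                       # (n, 2) seed coordinates (y, x)
    truth_adjacency: dict[int, list[int]]
    truth_areas: dict[int, int]             # pixel counts
    degenerate_walls: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SyntheticEvent:
    """Ground-truth division event of :func:`divide_frame`."""

    mother: int
    mother_n: int
    daughters: tuple[int, int]
    daughter_n: tuple[int, int]
    contaminated: bool


def _sample_seeds(spec: SyntheticFrameSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape
    x = rng.uniform(0, w, spec.n_seeds)
    u = rng.uniform(0, 1, spec.n_seeds)
    g = spec.gradient
    if g == 0:
        y = u * h
    else:
        # inverse CDF of the linear density 1 + g*y/h (up to normalisation)
        y = h * (np.sqrt(1 + u * g * (g + 2)) - 1) / g
    return np.stack([y, x], axis=1)


def _rasterise(seeds: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.stack([yy.ravel() + 0.5, xx.ravel() + 0.5], axis=1)
    _, idx = cKDTree(seeds).query(pts)
    return (idx + 1).reshape(shape).astype(np.int32)


def voronoi_frame(spec: SyntheticFrameSpec) -> SyntheticFrame:
    """Generate a rasterised Voronoi tissue with ground-truth metadata.

    Labels are 1..n_seeds (seed order); the image is space-filling (no
    background).  Ground-truth adjacency pairs are labels sharing a
    4-connected wall in the raster, built via scikit-image's region
    adjacency graph; pairs not present in the Delaunay graph of the seeds
    are listed in ``degenerate_walls``.  Ground-truth areas are per-label
    pixel counts.
    """
    rng = np.random.default_rng(spec.seed)
    seeds = _sample_seeds(spec, rng)
    labels = _rasterise(seeds, spec.shape)
    for attempt in range(10):
        counts = np.bincount(labels.ravel(), minlength=spec.n_seeds + 1)
        empty = np.flatnonzero(counts[1:] == 0)
        if empty.size == 0:
            break
        if spec.on_empty == "error":
            raise ValueError(f"{empty.size} seed(s) produced no pixels")
        warnings.warn(f"resampling {empty.size} seed(s) with empty regions", stacklevel=2)
        h, w = spec.shape
        seeds[empty] = np.stack([rng.uniform(0, h, empty.size),
                                 rng.uniform(0, w, empty.size)], axis=1)
        labels = _rasterise(seeds, spec.shape)
    else:
        raise ValueError("could not place all seeds with non-empty regions")

    for _ in range(spec.lloyd):
        yy, xx = np.mgrid[0:spec.shape[0], 0:spec.shape[1]]
        flat = labels.ravel()
        cy = np.bincount(flat, weights=yy.ravel() + 0.5)[1:]
        cx = np.bincount(flat, weights=xx.ravel() + 0.5)[1:]
        cnt = np.bincount(flat)[1:]
        seeds = np.stack([cy / cnt, cx / cnt], axis=1)
        labels = _rasterise(seeds, spec.shape)
        if (np.bincount(labels.ravel(), minlength=spec.n_seeds + 1)[1:] == 0).any():
            raise ValueError("Lloyd relaxation emptied a region; reduce seed density")

    tri = Delaunay(seeds)
    delaunay_pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]) + 1, int(simplex[(a + 1) % 3]) + 1
            delaunay_pairs.add((min(i, j), max(i, j)))
    # independent adjacency oracle: scikit-image's region adjacency graph
    from skimage.graph import RAG

    rag = RAG(labels, connectivity=1)
    truth = {int(i): [] for i in range(1, spec.n_seeds + 1)}
    degenerate = []
    for i, j in rag.edges:
        i, j = int(min(i, j)), int(max(i, j))
        if i == 0:
            continue
        truth[i].append(j)
        truth[j].append(i)
        if (i, j) not in delaunay_pairs:
            degenerate.append((i, j))
    truth = {i: sorted(v) for i, v in truth.items()}
    counts = np.bincount(labels.ravel(), minlength=spec.n_seeds + 1)
    areas = {int(i): int(counts[i]) for i in range(1, spec.n_seeds + 1)}
    return SyntheticFrame(SegmentedFrame(labels), seeds, truth, areas, degenerate)


def _split_pixels(labels: np.ndarray, mother: int, centroid: tuple[float, float],
                  angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of the two halves of a straight cut through the centroid."""
    ys, xs = np.nonzero(labels == mother)
    cy, cx = centroid
    side = (xs + 0.5 - cx) * -np.sin(angle) + (ys + 0.5 - cy) * np.cos(angle) >= 0
    m1 = np.zeros_like(labels, dtype=bool)
    m2 = np.zeros_like(labels, dtype=bool)
    m1[ys[side], xs[side]] = True
    m2[ys[~side], xs[~side]] = True
    return m1, m2


def _local_degrees(labels: np.ndarray, ids: tuple[int, ...],
                   bbox: tuple[int, int, int, int]) -> dict[int, int]:
    y0, y1, x0, x1 = bbox
    crop = labels[max(0, y0 - 1):y1 + 1, max(0, x0 - 1):x1 + 1]
    adj = build_adjacency(crop)
    return {i: len(adj.get(i, [])) for i in ids}


def divide_frame(frame: SyntheticFrame | SegmentedFrame,
                 spec: SyntheticDivisionSpec) -> tuple[SegmentedFrame, pd.DataFrame, list[SyntheticEvent]]:
    """Divide a fraction of cells; return the next frame, lineage map, truth log.

    Mothers are drawn among neighbour-complete cells and split by a straight
    wall through the centroid at a uniform random angle.  A cut is retried
    (fresh angle) when a daughter would fall below the minimum pixel area or
    be disconnected, or when — for a mother with no co-dividing neighbour —
    the cut degenerates through a junction so that the daughters' neighbour
    counts would not sum to mother + 4; after ``max_retries`` the mother is
    skipped.  The lineage map links every surviving cell to itself and every
    mother to its two daughters.
    """
    seg = frame.frame if isinstance(frame, SyntheticFrame) else frame
    if seg.cells is None:
        analyse_frame(seg)
    rng = np.random.default_rng(spec.seed)
    pre_adj = seg.adjacency
    eligible = sorted(seg.valid_ids("neighbour-complete"))
    n_div = int(round(spec.fraction * len(eligible)))
    # base mothers form an independent set of the adjacency graph: without
    # injected contamination every division is isolated
    pool = list(eligible)
    rng.shuffle(pool)
    mothers: set[int] = set()
    for c in pool:
        if len(mothers) == n_div:
            break
        if not any(v in mothers for v in pre_adj[c]):
            mothers.add(int(c))
    if len(mothers) < n_div:
        log.warning("only %d of %d requested mothers fit as isolated divisions",
                    len(mothers), n_div)
    # each injected co-division pair yields two flagged events among
    # n_base*(1+q) total, so per-mother probability q = c/(2-c) gives an
    # expected flagged-event fraction of c
    q = spec.contamination / (2 - spec.contamination) if spec.contamination else 0.0
    for m in sorted(mothers):
        if q and rng.uniform() < q:
            nbrs = [v for v in pre_adj[m] if v in eligible and v not in mothers
                    and not any(u in mothers and u != m for u in pre_adj[v])]
            if nbrs:
                mothers.add(int(nbrs[int(rng.integers(len(nbrs)))]))

    contaminated = {m for m in mothers if any(v in mothers for v in pre_adj[m])}
    labels = seg.labels.copy()
    next_id = int(labels.max()) + 1
    cells = seg.cells.set_index("id")
    placed: list[tuple[int, tuple[int, int]]] = []
    for m in sorted(mothers):
        cy, cx = float(cells.loc[m, "centroid_y"]), float(cells.loc[m, "centroid_x"])
        ys, xs = np.nonzero(labels == m)
        bbox = (ys.min(), ys.max() + 1, xs.min(), xs.max() + 1)
        pre_n = _local_degrees(labels, (m,), bbox)[m]
        done = False
        for _ in range(spec.max_retries):
            angle = rng.uniform(0, np.pi)
            m1, m2 = _split_pixels(labels, m, (cy, cx), angle)
            if m1.sum() < spec.min_daughter_area or m2.sum() < spec.min_daughter_area:
                continue
            if cc_label(m1, connectivity=1).max() != 1 or cc_label(m2, connectivity=1).max() != 1:
                continue
            d1, d2 = next_id, next_id + 1
            trial = labels.copy()
            trial[m1], trial[m2] = d1, d2
            deg = _local_degrees(trial, (d1, d2), bbox)
            if deg[d1] < 3 or deg[d2] < 3:
                continue
            if m not in contaminated and deg[d1] + deg[d2] != pre_n + 4:
                continue  # cut ran through a junction pixel; re-orient
            labels = trial
            next_id += 2
            placed.append((m, (d1, d2)))
            done = True
            break
        if not done:
            log.warning("cell %d skipped: no admissible division plane found", m)

    new_frame = analyse_frame(SegmentedFrame(labels, pixel_size=seg.pixel_size))
    post_deg = {i: len(v) for i, v in new_frame.adjacency.items()}
    divided = {m for m, _ in placed}
    links = [(0, int(i), 1, int(i)) for i in seg.label_ids if int(i) not in divided]
    events = []
    for m, (d1, d2) in placed:
        links.append((0, m, 1, d1))
        links.append((0, m, 1, d2))
        events.append(SyntheticEvent(
            mother=m, mother_n=len(pre_adj[m]), daughters=(d1, d2),
            daughter_n=(post_deg[d1], post_deg[d2]),
            contaminated=any(v in divided for v in pre_adj[m])))
    lineage = pd.DataFrame(sorted(links), columns=["frame_t", "cell_id_t", "frame_t1", "cell_id_t1"])
    return new_frame, lineage, events


def rule_event_stream(rule, mother_degrees, n_events: int, seed: int = 0,
                      contamination: float = 0.0) -> list[SyntheticEvent]:
    """I.i.d. division events drawn from a rule's analytic split law.

    ``mother_degrees`` is either a sequence of mother neighbour numbers to
    draw from uniformly, or a mapping ``n -> probability``.  With
    probability ``contamination`` an event has one daughter's neighbour
    count perturbed by ±1 (a neighbour dividing within the observation
    interval) and is flagged.
    """
    rng = np.random.default_rng(seed)
    if isinstance(mother_degrees, dict):
        ns = np.array(sorted(mother_degrees))
        ps = np.array([mother_degrees[n] for n in ns], dtype=float)
        ps = ps / ps.sum()
    else:
        ns = np.asarray(list(mother_degrees))
        ps = None
    matrix = analytic_division_matrix(rule, n_max=int(ns.max()))
    events = []
    for i in range(n_events):
        n = int(rng.choice(ns, p=ps))
        row = matrix.row(n)
        k1 = int(rng.choice(row.index.to_numpy(), p=row.to_numpy()))
        k2 = n + 4 - k1
        flag = bool(contamination and rng.uniform() < contamination)
        if flag:
            which = int(rng.integers(2))
            delta = int(rng.choice([-1, 1]))
            pair = [k1, k2]
            pair[which] = max(3, pair[which] + delta)
            k1, k2 = pair
        events.append(SyntheticEvent(mother=i, mother_n=n, daughters=(2 * i, 2 * i + 1),
                                     daughter_n=(k1, k2), contaminated=flag))
    return events
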