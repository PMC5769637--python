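"""Topology and topology-geometry statistics for 2-D cellular mosaics.

This module quantifies the neighbour-number ("topological") structure of a
planar tissue: the distribution P(n) of cells with n neighbours and its
moments mu1 and mu2, the Lemaitre-type single parameter alpha linking P(6)
to mu2, the Aboav-Weaire relation between a cell's neighbour number and the
mean neighbour number of its neighbours, Lewis' law relating neighbour
number to mean cell area, per-cell normalised areas, and division matrices
giving the probability that a mother with n neighbours produces a daughter
with k neighbours (analytic, per division rule, and empirical from tracked
or simulated division events).

All estimators operate on plain containers (dicts, DataFrames) so they
apply equally to simulated graphs and to cell tables extracted from
segmented images.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Collection, Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "NeighborDistribution",
    "DivisionMatrix",
    "AboavCurve",
    "LewisCurve",
    "NormalisedAreaResult",
    "distribution_from_counts",
    "alpha_statistic",
    "analytic_division_matrix",
    "empirical_division_matrix",
    "aboav_curve",
    "aboav_reference",
    "lewis_curve",
    "lewis_reference",
    "normalised_area_relations",
]

#: Division rules understood by :func:`analytic_division_matrix`.
RULE_NAMES = ("equal", "random", "pascal")


def _rule_name(rule) -> str:
    """Accept either a rule object with a ``name`` attribute or a string."""
    name = getattr(rule, "name", rule)
    if name not in RULE_NAMES:
        raise ValueError(f"unknown division rule {name!r}; expected one of {RULE_NAMES}")
    return name


# ---------------------------------------------------------------------------
# Neighbour-number distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeighborDistribution:
    """Distribution of neighbour numbers over the cells of a tissue.

    Attributes
    ----------
    counts
        Mapping ``n -> number of cells with n neighbours``.  Every key is an
        integer >= 3; a cell with fewer than three neighbours cannot occur in
        a mosaic without four-way junctions and indicates an upstream error.
    """

    counts: Mapping[int, int]

    def __post_init__(self):
        if not self.counts:
            raise ValueError("empty neighbour-count input")
        for n, c in self.counts.items():
            if n < 3:
                raise ValueError(f"neighbour count {n} < 3 (offending class n={n})")
            if c < 0 or int(c) != c:
                raise ValueError(f"count for n={n} must be a non-negative integer")
        object.__setattr__(self, "counts", dict(sorted(self.counts.items())))

    @classmethod
    def from_counts(cls, neighbour_counts: Iterable[int]) -> "NeighborDistribution":
        counts = Counter()
        for i, n in enumerate(neighbour_counts):
            if n < 3:
                raise ValueError(f"cell #{i} has {n} < 3 neighbours")
            counts[int(n)] += 1
        return cls(counts)

    @property
    def n_cells(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[int, float]:
        total = self.n_cells
        return {n: c / total for n, c in self.counts.items()}

    def p(self, n: int) -> float:
        """Frequency P(n) of n-sided cells (0 if the class is absent)."""
        return self.counts.get(n, 0) / self.n_cells

    @property
    def mu1(self) -> float:
        """Mean neighbour number <n>."""
        return sum(n * c for n, c in self.counts.items()) / self.n_cells

    @property
    def mu2(self) -> float:
        """Population variance <n^2> - <n>^2 of the neighbour number."""
        m1 = self.mu1
        m2 = sum(n * n * c for n, c in self.counts.items()) / self.n_cells
        return m2 - m1 * m1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": list(self.counts),
                "count": list(self.counts.values()),
                "frequency": [self.p(n) for n in self.counts],
            }
        )

    def total_variation(self, other: "NeighborDistribution") -> float:
        """Total-variation distance between two distributions."""
        ns = set(self.counts) | set(other.counts)
        return 0.5 * sum(abs(self.p(n) - other.p(n)) for n in ns)


def distribution_from_counts(neighbour_counts: Iterable[int]) -> NeighborDistribution:
    """Build a :class:`NeighborDistribution` from raw per-cell neighbour counts."""
    return NeighborDistribution.from_counts(neighbour_counts)


def alpha_statistic(dist: NeighborDistribution) -> float:
    """Single parameter linking the hexagon frequency to the distribution spread.

    Computes ``alpha = mu2 * P(6)**2`` (the Le Caer-Delannay / Lemaitre
    relation for 2-D cellular structures).  Raises if P(6) = 0, where the
    relation is undefined.
    """
    p6 = dist.p(6)
    if p6 == 0:
        raise ValueError("alpha statistic undefined: P(6) = 0")
    return dist.mu2 * p6 * p6


# ---------------------------------------------------------------------------
# Division matrices
# ---------------------------------------------------------------------------


@dataclass
class DivisionMatrix:
    """Per-daughter post-mitotic neighbour-number probabilities.

    ``probs`` is indexed by the pre-mitotic neighbour number of the mother
    (rows) and the post-mitotic neighbour number of a daughter (columns);
    entry (n, k) is the probability that a daughter of an n-sided mother has
    k neighbours.  Defined rows sum to one; rows with no observed events are
    NaN (undefined, not zero).  ``row_events`` gives the number of division
    events behind each row (NaN for analytic matrices).
    """

    probs: pd.DataFrame
    row_events: pd.Series
    anomalies: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["mother_n", "daughter_n"])
    )

    def row(self, n: int) -> pd.Series:
        return self.probs.loc[n]

    def total_variation(self, other: "DivisionMatrix") -> pd.Series:
        """Row-wise total-variation distance on the shared defined rows."""
        rows = [
            n
            for n in self.probs.index.intersection(other.probs.index)
            if not (self.probs.loc[n].isna().all() or other.probs.loc[n].isna().all())
        ]
        cols = self.probs.columns.union(other.probs.columns)
        a = self.probs.reindex(index=rows, columns=cols).fillna(0.0)
        b = other.probs.reindex(index=rows, columns=cols).fillna(0.0)
        return (a - b).abs().sum(axis=1) / 2.0


def analytic_division_matrix(rule, n_max: int = 12) -> DivisionMatrix:
    """Closed-form per-daughter division matrix for a topological rule.

    For a mother with n neighbours the new wall cuts two interfaces, whose
    owners ("junction neighbours") border both daughters; the remaining
    n - 2 neighbours split into contiguous arcs of a and n - 2 - a cells, so
    a daughter keeping a of them ends with k = a + 3 neighbours.  The rule
    fixes the law of a:

    - ``equal``:  a = (n-2)/2 for even n; for odd n one of the two nearest
      integers with probability 1/2 each.
    - ``random``: a uniform on {0, ..., n-2}, i.e. P(k) = 1/(n-1) on
      k in [3, n+1].
    - ``pascal``: the binomially weighted split in which the new wall never
      cuts two adjacent walls, so each daughter keeps at least one intact
      wall: P(k) = C(n-4, k-4) / 2^(n-4) on k in [4, n].  For n = 3 the
      only possible split {3, 4} is used (probability 1/2 per daughter
      class); n = 4 forces {4, 4}.
    """
    name = _rule_name(rule)
    if n_max < 3:
        raise ValueError("n_max must be >= 3")
    rows = range(3, n_max + 1)
    cols = range(3, n_max + 2)
    probs = pd.DataFrame(0.0, index=pd.Index(rows, name="mother_n"),
                         columns=pd.Index(cols, name="daughter_n"))
    for n in rows:
        if name == "equal":
            if n % 2 == 0:
                probs.loc[n, n // 2 + 2] = 1.0
            else:
                probs.loc[n, (n + 3) // 2] = 0.5
                probs.loc[n, (n + 5) // 2] = 0.5
        elif name == "random":
            for k in range(3, n + 2):
                probs.loc[n, k] = 1.0 / (n - 1)
        else:  # pascal
            if n == 3:
                probs.loc[3, 3] = 0.5
                probs.loc[3, 4] = 0.5
            else:
                for k in range(4, n + 1):
                    probs.loc[n, k] = math.comb(n - 4, k - 4) / 2 ** (n - 4)
    row_events = pd.Series(np.nan, index=probs.index)
    return DivisionMatrix(probs, row_events)


def _event_triplet(event) -> tuple[int, int, int]:
    """Extract (mother_n, d1_n, d2_n) from an event object or tuple."""
    if hasattr(event, "mother_n"):
        d = getattr(event, "daughter_n", None)
        if d is None:
            d = (event.d1_n, event.d2_n)
        return int(event.mother_n), int(d[0]), int(d[1])
    m, d1, d2 = event
    return int(m), int(d1), int(d2)


def empirical_division_matrix(events: Iterable, n_max: int | None = None) -> DivisionMatrix:
    """Estimate a per-daughter division matrix from observed division events.

    Each event contributes two daughter observations; row n, column k is
    (# daughters with k neighbours) / (2 * # events with an n-sided mother).
    Rows without events are NaN.  Daughter counts outside the single-division
    range [3, n+1] (possible in tracked data when a neighbour divided within
    the imaging interval) are retained in the matrix but listed in
    ``anomalies``.
    """
    triplets = [_event_triplet(e) for e in events]
    if not triplets:
        raise ValueError("no division events supplied")
    mothers = [m for m, _, _ in triplets]
    daughters = [k for _, d1, d2 in triplets for k in (d1, d2)]
    if n_max is None:
        n_max = max(max(mothers), max(daughters) - 1)
    rows = pd.Index(range(3, n_max + 1), name="mother_n")
    cols = pd.Index(range(3, max(n_max + 2, max(daughters) + 1)), name="daughter_n")
    counts = pd.DataFrame(0.0, index=rows, columns=cols)
    n_events = pd.Series(0, index=rows, dtype=float)
    anomalies = []
    for m, d1, d2 in triplets:
        n_events[m] += 1
        for k in (d1, d2):
            counts.loc[m, k] += 1
            if not 3 <= k <= m + 1:
                anomalies.append({"mother_n": m, "daughter_n": k})
    probs = counts.div(2.0 * n_events, axis=0)
    probs[n_events == 0] = np.nan
    return DivisionMatrix(probs, n_events, pd.DataFrame(anomalies, columns=["mother_n", "daughter_n"]))


# ---------------------------------------------------------------------------
# Aboav-Weaire
# ---------------------------------------------------------------------------


@dataclass
class AboavCurve:
    """Mean neighbour count of the neighbours of n-sided cells, per n.

    ``table`` has columns ``n``, ``m_n`` (mean over valid n-sided cells of
    the average neighbour count of their neighbours) and ``cells`` (sample
    size).  ``reference`` holds the superimposed law, by default Aboav's
    approximate form m_n = 5 + 8/n.
    """

    table: pd.DataFrame
    reference: pd.DataFrame


def aboav_reference(ns: Sequence[int], form: str = "aboav",
                    a: float = 1.0, mu2: float | None = None) -> pd.DataFrame:
    """Reference Aboav-Weaire curve.

    ``form='aboav'`` gives the original approximate law m_n = 5 + 8/n;
    ``form='weaire'`` gives m_n = (6 - a) + (6a + mu2)/n, which requires the
    distribution variance ``mu2``.
    """
    ns = np.asarray(sorted(set(int(n) for n in ns)))
    if form == "aboav":
        m = 5.0 + 8.0 / ns
    elif form == "weaire":
        if mu2 is None:
            raise ValueError("the Weaire form requires mu2")
        m = (6.0 - a) + (6.0 * a + mu2) / ns
    else:
        raise ValueError(f"unknown Aboav reference form {form!r}")
    return pd.DataFrame({"n": ns, "m_n": m})


def aboav_curve(adjacency: Mapping, valid: Collection | None = None,
                reference_form: str = "aboav", a: float = 1.0) -> AboavCurve:
    """Compute the empirical Aboav-Weaire curve from a neighbour map.

    Parameters
    ----------
    adjacency
        Mapping ``cell id -> sequence of neighbour ids``.  Neighbour numbers
        are taken as the number of *distinct* neighbours.
    valid
        Cells eligible as central cells (e.g. neighbour-complete cells from a
        segmentation).  Every neighbour of a central cell must itself have an
        entry in ``adjacency``; by default all cells with such complete
        neighbourhoods are used.
    """
    deg = {c: len(set(nbrs)) for c, nbrs in adjacency.items()}
    if valid is None:
        valid = [c for c, nbrs in adjacency.items() if all(v in deg for v in nbrs)]
    per_cell = []
    mu2 = None
    for c in valid:
        nbrs = set(adjacency[c])
        missing = [v for v in nbrs if v not in deg]
        if missing:
            raise ValueError(f"cell {c} has neighbours without defined neighbourhoods: {missing}")
        per_cell.append((deg[c], np.mean([deg[v] for v in nbrs])))
    if not per_cell:
        raise ValueError("no valid central cells for the Aboav-Weaire curve")
    df = pd.DataFrame(per_cell, columns=["n", "mean_nbr_deg"])
    table = (
        df.groupby("n")["mean_nbr_deg"]
        .agg(m_n="mean", cells="size")
        .reset_index()
    )
    if reference_form == "weaire":
        mu2 = distribution_from_counts([deg[c] for c in valid]).mu2
    ref = aboav_reference(table["n"], form=reference_form, a=a, mu2=mu2)
    return AboavCurve(table, ref)


# ---------------------------------------------------------------------------
# Lewis' law and normalised areas
# ---------------------------------------------------------------------------


@dataclass
class LewisCurve:
    """Mean (normalised) area of n-sided cells with the Lewis reference.

    ``table`` columns: ``n``, ``mean_area``, ``cells``.  ``reference``: the
    classical Lewis law A_n = (A0/N) * (n-2)/4 evaluated at the same n, where
    A0/N is replaced by the mean of the supplied areas when ``normalised``
    (so the reference passes through the data's own scale at n = 6).
    """

    table: pd.DataFrame
    reference: pd.DataFrame
    total_area: float
    n_cells: int


def lewis_reference(ns: Sequence[int], scale: float) -> pd.DataFrame:
    ns = np.asarray(sorted(set(int(n) for n in ns)))
    return pd.DataFrame({"n": ns, "mean_area": scale * (ns - 2) / 4.0})


def lewis_curve(cells: pd.DataFrame, normalised: bool = False,
                total_area: float | None = None, n_cells: int | None = None) -> LewisCurve:
    """Empirical Lewis curve from a per-cell table with columns ``n``, ``area``.

    ``total_area`` / ``n_cells`` default to the table's own sums, but can be
    supplied from the whole frame when ``cells`` is a validity-filtered
    subset.  With ``normalised=True`` the areas are taken to be already
    normalised and the reference scale is their mean instead of A0/N.
    """
    if cells.empty:
        raise ValueError("empty cell table")
    if (cells["area"] <= 0).any():
        raise ValueError("non-positive cell areas")
    table = (
        cells.groupby("n")["area"].agg(mean_area="mean", cells="size").reset_index()
    )
    a0 = float(cells["area"].sum()) if total_area is None else float(total_area)
    n_tot = len(cells) if n_cells is None else int(n_cells)
    scale = float(cells["area"].mean()) if normalised else a0 / n_tot
    return LewisCurve(table, lewis_reference(table["n"], scale), a0, n_tot)


@dataclass
class NormalisedAreaResult:
    """Per-cell normalised areas and the four topology-geometry regressions.

    ``table`` columns: id, n, area, norm_area (area over the mean area of
    the cell's neighbours) and nbr_mean_norm_area (mean over the neighbours
    of their own normalised areas, each computed excluding the central cell
    from that neighbour's neighbourhood).  ``fits`` maps panel name ->
    dict(slope, intercept, r2, n_points); a zero-variance predictor or
    response yields NaN statistics and a ``degenerate`` flag.
    """

    table: pd.DataFrame
    fits: dict[str, dict[str, float]]


def _ols(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("fewer than 3 valid cells for regression")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"slope": np.nan, "intercept": np.nan, "r2": np.nan,
                "n_points": int(x.size), "degenerate": True}
    fit = _scipy_stats.linregress(x, y)
    return {"slope": fit.slope, "intercept": fit.intercept,
            "r2": fit.rvalue ** 2, "n_points": int(x.size), "degenerate": False}


def normalised_area_relations(adjacency: Mapping, areas: Mapping,
                              valid: Collection | None = None,
                              second_order_valid: Collection | None = None) -> NormalisedAreaResult:
    """Normalised-area statistics linking cell size to local topology.

    Parameters
    ----------
    adjacency, areas
        Neighbour map and per-cell areas (same ids).
    valid
        Cells whose normalised area is defined (all neighbours have areas);
        defaults to every such cell.
    second_order_valid
        Cells for which the neighbour-mean normalised area is defined (their
        neighbours' neighbours all have areas); defaults to every such cell.
    """
    have = set(areas)

    def _norm_area(c, exclude=None):
        nbrs = [v for v in set(adjacency[c]) if v != exclude]
        if not nbrs or any(v not in have for v in nbrs):
            return np.nan
        return areas[c] / float(np.mean([areas[v] for v in nbrs]))

    if valid is None:
        valid = [c for c in adjacency if all(v in have for v in set(adjacency[c]))]
    valid = list(valid)
    if second_order_valid is None:
        vset = set(valid)
        second_order_valid = [
            c for c in valid if all(v in vset or all(u in have for u in set(adjacency[v]))
                                    for v in set(adjacency[c]))
        ]
    so = set(second_order_valid)

    rows = []
    for c in valid:
        nbrs = set(adjacency[c])
        norm = _norm_area(c)
        if c in so:
            # each neighbour's normalisation excludes the central cell itself
            nbr_norm = float(np.mean([_norm_area(v, exclude=c) for v in nbrs]))
        else:
            nbr_norm = np.nan
        rows.append({"id": c, "n": len(nbrs), "area": areas[c],
                     "norm_area": norm, "nbr_mean_norm_area": nbr_norm})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("fewer than 3 valid cells for regression")
    fits = {
        "area_vs_n": _ols(table["n"].to_numpy(float), table["area"].to_numpy(float)),
        "norm_area_vs_area": _ols(table["area"].to_numpy(float), table["norm_area"].to_numpy(float)),
        "norm_area_vs_n": _ols(table["n"].to_numpy(float), table["norm_area"].to_numpy(float)),
        "nbr_norm_vs_norm_area": _ols(table["norm_area"].to_numpy(float),
                                      table["nbr_mean_norm_area"].to_numpy(float)),
    }
    return NormalisedAreaResult(table, fits)
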