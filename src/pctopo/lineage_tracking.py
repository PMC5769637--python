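"""Division-event detection from tracked segmented frames.

Input is a pair (or series) of analysed label frames plus a tracking table
linking cell ids across consecutive frames (four columns: frame_t,
cell_id_t, frame_t1, cell_id_t1 — any tracker can be adapted to this
schema).  A mother linked to exactly two daughters is a candidate division;
one-to-one links are persistence; one-to-many (>2) or many-to-one links are
anomalies, reported and excluded.  Each detected event records the mother's
pre-mitotic neighbour number and both daughters' post-mitotic numbers, and
is valid only when mother and daughters are neighbour-complete in their
frames.  Events whose mother had a neighbour that also divided in the same
interval are flagged as contaminated: their daughters' counts include walls
contributed by the neighbour's division, which broadens the empirical
division matrix relative to the matrix of isolated divisions — both the
flag-filtered and the unfiltered matrices are therefore available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .segmentation_topology import SegmentedFrame, analyse_frame
from .topology_stats import DivisionMatrix, empirical_division_matrix

__all__ = [
    "LineageMap",
    "DivisionEvent",
    "read_tracking",
    "extract_division_events",
    "events_to_matrix",
]

log = logging.getLogger(__name__)

LINK_COLUMNS = ["frame_t", "cell_id_t", "frame_t1", "cell_id_t1"]


@dataclass
class LineageMap:
    """Validated cell links between consecutive frames.

    ``links`` holds the accepted rows; ``anomalies`` the rejected ones
    (mothers with more than two daughters, daughters with more than one
    mother) with a reason column.
    """

    links: pd.DataFrame
    anomalies: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=LINK_COLUMNS + ["reason"]))

    def candidate_divisions(self) -> pd.DataFrame:
        """One row per mother with exactly two daughters: frame_t, frame_t1,
        mother, daughter1, daughter2."""
        rows = []
        for (ft, m, ft1), grp in self.links.groupby(["frame_t", "cell_id_t", "frame_t1"]):
            if len(grp) == 2:
                d = sorted(grp["cell_id_t1"])
                rows.append((ft, ft1, m, d[0], d[1]))
        return pd.DataFrame(rows, columns=["frame_t", "frame_t1", "mother",
                                           "daughter1", "daughter2"])

    def persistence(self) -> pd.DataFrame:
        counts = self.links.groupby(["frame_t", "cell_id_t", "frame_t1"]).size()
        keep = counts[counts == 1].index
        return self.links.set_index(["frame_t", "cell_id_t", "frame_t1"]).loc[keep].reset_index()


def _validate_links(links: pd.DataFrame) -> LineageMap:
    links = links[LINK_COLUMNS].copy()
    bad = pd.Series(False, index=links.index)
    reasons = pd.Series("", index=links.index)
    mother_counts = links.groupby(["frame_t", "cell_id_t", "frame_t1"])["cell_id_t1"].transform("size")
    m = mother_counts > 2
    bad |= m
    reasons[m] = "mother with more than two daughters"
    daughter_counts = links.groupby(["frame_t1", "cell_id_t1", "frame_t"])["cell_id_t"].transform("nunique")
    m = daughter_counts > 1
    reasons[m & ~bad] = "daughter with more than one mother"
    bad |= m
    anomalies = links[bad].assign(reason=reasons[bad])
    if len(anomalies):
        log.warning("excluded %d anomalous tracking links", len(anomalies))
    return LineageMap(links[~bad].reset_index(drop=True), anomalies.reset_index(drop=True))


def read_tracking(path) -> LineageMap:
    """Read and validate a four-column tracking CSV."""
    df = pd.read_csv(path)
    missing = [c for c in LINK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing tracking columns {missing}")
    return _validate_links(df)


@dataclass
class DivisionEvent:
    """One tracked division: pre-mitotic mother, post-mitotic daughters."""

    frame_t: int
    frame_t1: int
    mother: int
    mother_n: int | None
    daughters: tuple[int, int]
    daughter_n: tuple[int | None, int | None]
    valid: bool
    reason: str = ""
    contaminated: bool = False


def extract_division_events(frames: dict[int, SegmentedFrame],
                            lineage: LineageMap) -> list[DivisionEvent]:
    """Assemble division events from analysed frames and a lineage map.

    An event is valid only when the mother and both daughters exist in
    their frames and are neighbour-complete, so that every recorded
    neighbour number is fully defined.  Contamination (a neighbour of the
    mother also dividing between the same two frames) is flagged, not
    dropped.
    """
    for f in frames.values():
        if f.cells is None:
            analyse_frame(f)
    events: list[DivisionEvent] = []
    cand = lineage.candidate_divisions()
    mothers_by_pair = {
        pair: set(grp["mother"]) for pair, grp in cand.groupby(["frame_t", "frame_t1"])
    }
    for row in cand.itertuples(index=False):
        ft, ft1 = int(row.frame_t), int(row.frame_t1)
        f0, f1 = frames.get(ft), frames.get(ft1)
        if f0 is None or f1 is None:
            raise KeyError(f"tracking refers to missing frame {ft if f0 is None else ft1}")
        mother, ds = int(row.mother), (int(row.daughter1), int(row.daughter2))
        deg0 = {i: len(v) for i, v in f0.adjacency.items()}
        deg1 = {i: len(v) for i, v in f1.adjacency.items()}
        if mother not in deg0:
            events.append(DivisionEvent(ft, ft1, mother, None, ds, (None, None),
                                        False, "mother missing from frame"))
            continue
        if any(d not in deg1 for d in ds):
            events.append(DivisionEvent(ft, ft1, mother, deg0[mother], ds, (None, None),
                                        False, "daughter missing from frame"))
            continue
        nc0 = set(f0.valid_ids("neighbour-complete"))
        nc1 = set(f1.valid_ids("neighbour-complete"))
        valid = mother in nc0 and all(d in nc1 for d in ds)
        reason = "" if valid else "mother or daughter not neighbour-complete"
        others = mothers_by_pair[(ft, ft1)] - {mother}
        contaminated = any(v in others for v in f0.adjacency[mother])
        events.append(DivisionEvent(ft, ft1, mother, deg0[mother], ds,
                                    (deg1[ds[0]], deg1[ds[1]]), valid, reason, contaminated))
    return events


def events_to_matrix(events, n_max: int | None = None,
                     include_contaminated: bool = True) -> DivisionMatrix:
    """Empirical division matrix from tracked events (valid events only)."""
    kept = [e for e in events if getattr(e, "valid", True)
            and (include_contaminated or not getattr(e, "contaminated", False))]
    return empirical_division_matrix(kept, n_max=n_max)
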