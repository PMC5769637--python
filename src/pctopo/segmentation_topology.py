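"""Per-cell topology and geometry from segmented label images.

A segmented frame is a 2-D integer image in which each cell carries a unique
positive label and 0 marks background.  From it we extract the region
adjacency graph (two cells are neighbours when they share a wall, i.e. some
pixel of one is 4-connected to a pixel of the other — corner-only contact is
not adjacency, mirroring the exclusion of four-way junctions), per-cell
geometry (area, centroid, ellipse-equivalent axes, anisotropy), and nested
validity tiers used to exclude cells whose neighbourhood is not fully
contained in the segmented region:

``interior``
    the cell touches neither the image border nor background;
``neighbour-complete``
    interior, and all neighbours interior — required wherever a statistic
    consumes the full neighbourhood (m_n, normalised areas);
``second-order-complete``
    neighbour-complete, and all neighbours neighbour-complete — required for
    neighbour-of-neighbour statistics.

Segmentations that separate cells by a one-pixel background membrane are
supported via ``membrane=1``, which also links labels facing each other
across a single orthogonal background pixel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.measure import regionprops_table

__all__ = [
    "SegmentedFrame",
    "read_label_image",
    "build_adjacency",
    "classify_validity",
    "geometry",
    "analyse_frame",
    "export_heatmap",
    "HEATMAP_QUANTITIES",
]

log = logging.getLogger(__name__)

TIERS = ("none", "interior", "neighbour-complete", "second-order-complete")


@dataclass
class SegmentedFrame:
    """A label image together with its per-cell records.

    ``cells`` (filled by :func:`analyse_frame`) has one row per label with
    columns: id, n, area, centroid_y, centroid_x, major, minor, anisotropy,
    degenerate, touches_border, touches_background, tier.
    """

    labels: np.ndarray
    pixel_size: float = 1.0
    timestamp: float | None = None
    cells: pd.DataFrame | None = None
    adjacency: dict[int, list[int]] = field(default_factory=dict)

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def valid_ids(self, tier: str = "neighbour-complete") -> list[int]:
        """Cells at or above a validity tier (tiers are nested)."""
        if self.cells is None:
            raise ValueError("frame not analysed yet; call analyse_frame")
        rank = {t: i for i, t in enumerate(TIERS)}
        want = rank[tier]
        return [int(i) for i, t in zip(self.cells["id"], self.cells["tier"])
                if rank[t] >= want]


def read_label_image(path, pixel_size: float = 1.0,
                     timestamp: float | None = None) -> SegmentedFrame:
    """Read a TIFF/PNG label image, preserving labels bit-exactly.

    Accepts 2-D integer images (or paletted PNGs, whose indices are the
    labels).  Float-valued or RGB images are rejected: a lossy colour
    rendering cannot be mapped back to cell ids.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path.name}: RGB/multichannel image is not a label image "
            "(save labels as single-channel integer TIFF/PNG)")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path.name}: label image must be integer-valued, got {arr.dtype}")
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D image, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError(f"{path.name}: negative labels are not allowed")
    if not (arr > 0).any():
        warnings.warn(f"{path.name}: image contains no labelled cells", stacklevel=2)
    return SegmentedFrame(arr, pixel_size=pixel_size, timestamp=timestamp)


def _contact_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    mask = (a > 0) & (b > 0) & (a != b)
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.stack([a[mask], b[mask]], axis=1).astype(np.int64)
    pairs.sort(axis=1)
    return np.unique(pairs, axis=0)


def build_adjacency(frame: SegmentedFrame | np.ndarray, membrane: int = 0) -> dict[int, list[int]]:
    """Region adjacency from 4-connected wall contact.

    With ``membrane=1``, two labels separated by exactly one orthogonal
    background pixel are also adjacent (one-pixel-membrane segmentations).
    """
    labels = frame.labels if isinstance(frame, SegmentedFrame) else np.asarray(frame)
    chunks = [
        _contact_pairs(labels[:, :-1], labels[:, 1:]),
        _contact_pairs(labels[:-1, :], labels[1:, :]),
    ]
    if membrane:
        gap_h = labels[:, 1:-1] == 0
        gap_v = labels[1:-1, :] == 0
        chunks.append(_contact_pairs(np.where(gap_h, labels[:, :-2], 0), labels[:, 2:]))
        chunks.append(_contact_pairs(np.where(gap_v, labels[:-2, :], 0), labels[2:, :]))
    adjacency: dict[int, list[int]] = {int(i): [] for i in np.unique(labels) if i > 0}
    for i, j in np.unique(np.concatenate(chunks), axis=0) if chunks else []:
        adjacency[int(i)].append(int(j))
        adjacency[int(j)].append(int(i))
    return {i: sorted(set(v)) for i, v in adjacency.items()}


def classify_validity(frame: SegmentedFrame | np.ndarray,
                      adjacency: dict[int, list[int]] | None = None) -> pd.DataFrame:
    """Nested validity tiers for every label.

    Returns a DataFrame (id, touches_border, touches_background, tier) where
    tier is one of ``none`` (border/background contact), ``interior``,
    ``neighbour-complete`` or ``second-order-complete``.
    """
    labels = frame.labels if isinstance(frame, SegmentedFrame) else np.asarray(frame)
    if adjacency is None:
        adjacency = build_adjacency(labels)
    border = set()
    for edge in (labels[0], labels[-1], labels[:, 0], labels[:, -1]):
        border.update(int(i) for i in np.unique(edge) if i > 0)
    background = set()
    for a, b in (
        (labels[:, :-1], labels[:, 1:]),
        (labels[:-1, :], labels[1:, :]),
    ):
        m = (a > 0) & (b == 0)
        background.update(int(i) for i in np.unique(a[m]))
        m = (b > 0) & (a == 0)
        background.update(int(i) for i in np.unique(b[m]))
    ids = sorted(adjacency)
    interior = {i for i in ids if i not in border and i not in background}
    nc = {i for i in interior if all(v in interior for v in adjacency[i])}
    soc = {i for i in nc if all(v in nc for v in adjacency[i])}
    tier = ["second-order-complete" if i in soc else
            "neighbour-complete" if i in nc else
            "interior" if i in interior else "none" for i in ids]
    return pd.DataFrame({
        "id": ids,
        "touches_border": [i in border for i in ids],
        "touches_background": [i in background for i in ids],
        "tier": tier,
    })


def geometry(frame: SegmentedFrame | np.ndarray, pixel_size: float | None = None) -> pd.DataFrame:
    """Per-cell area, centroid and ellipse-equivalent axes.

    Areas are pixel counts scaled by ``pixel_size**2``; the major/minor axis
    lengths come from the second central moments of the pixel coordinates.
    Regions whose minor axis degenerates to zero (single pixels, one-pixel
    lines) get anisotropy 1 and a ``degenerate`` flag.
    """
    if isinstance(frame, SegmentedFrame):
        labels = frame.labels
        pixel_size = frame.pixel_size if pixel_size is None else pixel_size
    else:
        labels = np.asarray(frame)
        pixel_size = 1.0 if pixel_size is None else pixel_size
    props = regionprops_table(
        labels, properties=("label", "area", "centroid",
                            "axis_major_length", "axis_minor_length"))
    df = pd.DataFrame(props).rename(columns={
        "label": "id", "centroid-0": "centroid_y", "centroid-1": "centroid_x",
        "axis_major_length": "major", "axis_minor_length": "minor"})
    df["area"] = df["area"] * pixel_size ** 2
    df[["centroid_y", "centroid_x", "major", "minor"]] *= pixel_size
    degenerate = df["minor"] <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        df["anisotropy"] = np.where(degenerate, 1.0, df["major"] / df["minor"])
    df["degenerate"] = degenerate
    return df


def analyse_frame(frame: SegmentedFrame, membrane: int = 0) -> SegmentedFrame:
    """Fill in adjacency and the per-cell record table of a frame, in place."""
    frame.adjacency = build_adjacency(frame, membrane=membrane)
    geo = geometry(frame)
    val = classify_validity(frame, frame.adjacency)
    cells = geo.merge(val, on="id", how="left")
    cells["n"] = [len(frame.adjacency.get(i, [])) for i in cells["id"]]
    order = ["id", "n", "area", "centroid_y", "centroid_x", "major", "minor",
             "anisotropy", "degenerate", "touches_border", "touches_background", "tier"]
    frame.cells = cells[order]
    return frame


HEATMAP_QUANTITIES = ("n", "area", "normalised_area", "anisotropy")

#: colour used for cells below the required validity tier
_GREY = (128, 128, 128)


def export_heatmap(frame: SegmentedFrame, quantity: str, out=None,
                   cmap: str | None = None) -> np.ndarray:
    """Recolour a label image by a per-cell quantity; returns an RGB array.

    Neighbour number uses a diverging brown-white-green map centred on the
    hexagonal value n = 6; other quantities use a sequential map.  Cells
    below the quantity's required validity tier (neighbour-complete for
    ``n`` and ``normalised_area``, any labelled cell otherwise) and the
    background are rendered grey.  If ``out`` is given the image is also
    written there as PNG.
    """
    import matplotlib

    if quantity not in HEATMAP_QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; expected one of {HEATMAP_QUANTITIES}")
    if frame.cells is None:
        analyse_frame(frame)
    cells = frame.cells
    if quantity == "normalised_area":
        areas = dict(zip(cells["id"], cells["area"]))
        values = {}
        for i in frame.valid_ids("neighbour-complete"):
            nbrs = frame.adjacency[i]
            values[i] = areas[i] / float(np.mean([areas[v] for v in nbrs]))
    elif quantity == "n":
        values = {i: k for i, k in zip(cells["id"], cells["n"])
                  if i in set(frame.valid_ids("neighbour-complete"))}
    else:
        values = dict(zip(cells["id"], cells[quantity]))
    max_label = int(frame.labels.max())
    lut = np.tile(np.array(_GREY, dtype=np.uint8), (max_label + 1, 1))
    if values:
        if quantity == "n":
            cm = matplotlib.colormaps[cmap or "BrBG"]
            span = max(2, max(abs(v - 6) for v in values.values()))
            norm = lambda v: 0.5 + (v - 6) / (2 * span)
        else:
            cm = matplotlib.colormaps[cmap or "viridis"]
            vals = np.array(list(values.values()), dtype=float)
            lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
            norm = (lambda v: 0.5) if hi == lo else (lambda v: (v - lo) / (hi - lo))
        for i, v in values.items():
            lut[i] = (np.array(cm(float(norm(v)))[:3]) * 255).astype(np.uint8)
    rgb = lut[frame.labels]
    if out is not None:
        iio.imwrite(Path(out), rgb, extension=".png")
    return rgb
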