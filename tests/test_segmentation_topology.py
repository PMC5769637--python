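"""Tests for label-image topology and geometry extraction."""

import numpy as np
import pandas as pd
import pytest

from pctopo.segmentation_topology import (
    SegmentedFrame,
    analyse_frame,
    build_adjacency,
    classify_validity,
    export_heatmap,
    geometry,
    read_label_image,
)


def frame_of(arr) -> SegmentedFrame:
    return SegmentedFrame(np.asarray(arr))


class TestReadLabelImage:
    def test_tiff_roundtrip_16bit(self, tmp_path):
        import tifffile

        labels = np.array([[0, 1], [2, 65535]], dtype=np.uint16)
        p = tmp_path / "labels.tif"
        tifffile.imwrite(p, labels)
        frame = read_label_image(p)
        np.testing.assert_array_equal(frame.labels, labels)

    def test_png_roundtrip(self, tmp_path):
        import imageio.v3 as iio

        labels = np.arange(9, dtype=np.uint8).reshape(3, 3)
        p = tmp_path / "labels.png"
        iio.imwrite(p, labels)
        frame = read_label_image(p)
        np.testing.assert_array_equal(frame.labels, labels)
        assert len(frame.label_ids) == 8  # 0 is background

    def test_rejects_rgb_and_float(self, tmp_path):
        import tifffile

        p = tmp_path / "rgb.tif"
        tifffile.imwrite(p, np.zeros((4, 4, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="RGB"):
            read_label_image(p)
        p2 = tmp_path / "float.tif"
        tifffile.imwrite(p2, np.zeros((4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="integer"):
            read_label_image(p2)

    def test_empty_image_warns(self, tmp_path):
        import tifffile

        p = tmp_path / "empty.tif"
        tifffile.imwrite(p, np.zeros((4, 4), dtype=np.uint8))
        with pytest.warns(UserWarning, match="no labelled cells"):
            frame = read_label_image(p)
        assert frame.label_ids.size == 0


class TestAdjacency:
    def test_shared_edges(self):
        adj = build_adjacency(np.array([[1, 2], [2, 1]]))
        assert adj == {1: [2], 2: [1]}

    def test_diagonal_contact_is_not_adjacency(self):
        adj = build_adjacency(np.array([[1, 0], [0, 2]]))
        assert adj == {1: [], 2: []}

    def test_membrane_mode_bridges_single_background_pixel(self):
        labels = np.array([[1, 0, 2], [1, 0, 2]])
        assert build_adjacency(labels) == {1: [], 2: []}
        assert build_adjacency(labels, membrane=1) == {1: [2], 2: [1]}

    def test_invariant_under_transpose_and_rotation(self, rng):
        labels = rng.integers(0, 6, size=(30, 30))
        base = build_adjacency(labels)
        assert build_adjacency(labels.T) == base
        assert build_adjacency(np.rot90(labels)) == base

    def test_matches_generator_truth(self, voronoi_fixture):
        sf = voronoi_fixture
        for i in sf.frame.valid_ids("neighbour-complete"):
            assert set(sf.frame.adjacency[i]) == set(sf.truth_adjacency[i])


class TestValidity:
    def test_single_cell_touching_border_excluded(self):
        val = classify_validity(np.ones((5, 5), dtype=int))
        assert val.loc[0, "tier"] == "none"
        assert bool(val.loc[0, "touches_border"])

    def test_three_by_three_mosaic_tiers(self):
        labels = np.repeat(np.repeat(np.arange(1, 10).reshape(3, 3), 4, 0), 4, 1)
        val = classify_validity(labels).set_index("id")
        assert val.loc[5, "tier"] == "interior"  # its neighbours touch the border
        assert all(val.loc[i, "tier"] == "none" for i in (1, 2, 3, 4, 6, 7, 8, 9))

    def test_background_contact_excludes(self):
        labels = np.repeat(np.repeat(np.arange(1, 26).reshape(5, 5), 3, 0), 3, 1)
        labels[7, 7] = 0  # punch a background hole into the centre cell 13
        val = classify_validity(labels).set_index("id")
        assert val.loc[13, "tier"] == "none"
        assert bool(val.loc[13, "touches_background"])

    def test_tiers_nested_on_voronoi(self, voronoi_fixture):
        cells = voronoi_fixture.frame.cells.set_index("id")
        adj = voronoi_fixture.frame.adjacency
        rank = {"none": 0, "interior": 1, "neighbour-complete": 2,
                "second-order-complete": 3}
        for i, row in cells.iterrows():
            r = rank[row["tier"]]
            if r >= 2:
                assert all(rank[cells.loc[v, "tier"]] >= 1 for v in adj[i])
            if r >= 3:
                assert all(rank[cells.loc[v, "tier"]] >= 2 for v in adj[i])


class TestGeometry:
    def test_square_region(self):
        labels = np.zeros((14, 14), dtype=int)
        labels[2:12, 2:12] = 1
        geo = geometry(labels).set_index("id")
        assert geo.loc[1, "area"] == 100
        assert geo.loc[1, "anisotropy"] == pytest.approx(1.0)
        assert geo.loc[1, "centroid_y"] == pytest.approx(6.5)

    def test_rectangle_anisotropy_is_aspect_ratio(self):
        labels = np.zeros((10, 25), dtype=int)
        labels[2:7, 2:22] = 1  # 5 x 20 rectangle
        geo = geometry(labels).set_index("id")
        # second moments of k discrete pixel centres give variance (k^2-1)/12
        assert geo.loc[1, "anisotropy"] == pytest.approx(np.sqrt(399 / 24))
        assert geo.loc[1, "anisotropy"] == pytest.approx(4.0, rel=0.02)

    def test_pixel_size_scaling(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[1:5, 1:5] = 1
        geo = geometry(labels, pixel_size=0.5).set_index("id")
        assert geo.loc[1, "area"] == pytest.approx(16 * 0.25)

    def test_degenerate_single_pixel(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[1, 1] = 1
        geo = geometry(labels).set_index("id")
        assert bool(geo.loc[1, "degenerate"])
        assert geo.loc[1, "anisotropy"] == 1.0

    def test_blob_area_equals_pixel_count(self, rng, voronoi_fixture):
        cells = voronoi_fixture.frame.cells.set_index("id")
        for i in voronoi_fixture.frame.label_ids[:20]:
            assert cells.loc[i, "area"] == (voronoi_fixture.frame.labels == i).sum()

    def test_area_conservation(self, voronoi_fixture):
        labels = voronoi_fixture.frame.labels
        cells = voronoi_fixture.frame.cells
        assert cells["area"].sum() + (labels == 0).sum() == labels.size


class TestHeatmap:
    def test_uniform_mosaic_uniform_colour(self):
        # 4x4 block mosaic on a torus-like interior: use a big frame and
        # check only that same-label pixels share a colour and geometry is
        # unchanged
        labels = np.repeat(np.repeat(np.arange(1, 26).reshape(5, 5), 5, 0), 5, 1)
        frame = analyse_frame(SegmentedFrame(labels))
        rgb = export_heatmap(frame, "n")
        assert rgb.shape == labels.shape + (3,)
        for i in np.unique(labels):
            colours = np.unique(rgb[labels == i].reshape(-1, 3), axis=0)
            assert len(colours) == 1  # recolouring preserves label geometry

    def test_unknown_quantity(self, voronoi_fixture):
        with pytest.raises(ValueError, match="unknown quantity"):
            export_heatmap(voronoi_fixture.frame, "perimeter")

    def test_writes_png(self, tmp_path, voronoi_fixture):
        out = tmp_path / "n.png"
        export_heatmap(voronoi_fixture.frame, "n", out=out)
        assert out.exists()


def test_statistics_invariant_under_transposition(voronoi_fixture):
    sf = voronoi_fixture
    transposed = analyse_frame(SegmentedFrame(sf.frame.labels.T))
    a = sf.frame.cells.sort_values("id")
    b = transposed.cells.sort_values("id")
    assert list(a["n"]) == list(b["n"])
    assert list(a["area"]) == list(b["area"])
    np.testing.assert_allclose(a["anisotropy"], b["anisotropy"])
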