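"""Tests for neighbour-distribution, law-curve and division-matrix statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pctopo.topology_stats import (
    aboav_curve,
    aboav_reference,
    alpha_statistic,
    analytic_division_matrix,
    distribution_from_counts,
    empirical_division_matrix,
    lewis_curve,
    normalised_area_relations,
)


class TestDistribution:
    def test_pure_hexagonal(self):
        d = distribution_from_counts([6] * 10)
        assert d.p(6) == 1 and d.mu1 == 6 and d.mu2 == 0

    def test_hand_arithmetic(self):
        d = distribution_from_counts([5, 5, 6, 6, 6, 7, 7])
        assert d.mu1 == pytest.approx(6.0)
        assert d.mu2 == pytest.approx(4 / 7)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            distribution_from_counts([])
        with pytest.raises(ValueError, match="#2"):
            distribution_from_counts([6, 5, 2])

    @given(hst.lists(hst.integers(3, 15), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_moments_match_population_variance(self, counts):
        d = distribution_from_counts(counts)
        assert d.mu1 == pytest.approx(np.mean(counts))
        assert d.mu2 == pytest.approx(np.var(counts), abs=1e-12)
        assert sum(d.frequencies.values()) == pytest.approx(1.0)


class TestAlpha:
    def test_degenerate_and_direct(self):
        assert alpha_statistic(distribution_from_counts([6, 6])) == 0
        d = distribution_from_counts([4, 6, 6, 8])  # P(6)=1/2, mu2=2
        assert alpha_statistic(d) == pytest.approx(2 * 0.25)

    def test_undefined_without_hexagons(self):
        with pytest.raises(ValueError, match="P\\(6\\)"):
            alpha_statistic(distribution_from_counts([5, 7]))


class TestAnalyticMatrix:
    def test_rows_are_distributions(self):
        for rule in ("equal", "random", "pascal"):
            m = analytic_division_matrix(rule, n_max=12)
            np.testing.assert_allclose(m.probs.sum(axis=1), 1.0)
            assert (m.probs.to_numpy() >= 0).all()

    def test_equal_forced_split(self):
        assert analytic_division_matrix("equal", 8).row(6)[5] == 1.0

    def test_random_uniform(self):
        row = analytic_division_matrix("random", 8).row(6)
        for k in range(3, 8):
            assert row[k] == pytest.approx(0.2)

    def test_pascal_binomial_weights(self):
        # daughters of a 6-sided mother keep 1 + Binomial(2, 1/2) arc cells
        row = analytic_division_matrix("pascal", 8).row(6)
        assert row[4] == pytest.approx(0.25)
        assert row[5] == pytest.approx(0.5)
        assert row[6] == pytest.approx(0.25)
        assert row[3] == 0 and row[7] == 0

    def test_pascal_small_mothers(self):
        m = analytic_division_matrix("pascal", 5)
        assert m.row(3)[3] == m.row(3)[4] == 0.5
        assert m.row(4)[4] == 1.0

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            analytic_division_matrix("fibonacci", 6)


class TestEmpiricalMatrix:
    def test_single_class(self):
        m = empirical_division_matrix([(6, 5, 5), (6, 5, 5)])
        assert m.row(6)[5] == 1.0
        assert m.row_events[6] == 2

    def test_tracked_seven_three_division(self):
        m = empirical_division_matrix([(6, 7, 3)])
        assert m.row(6)[7] == 0.5 and m.row(6)[3] == 0.5

    def test_rows_without_events_are_undefined(self):
        m = empirical_division_matrix([(6, 5, 5)], n_max=8)
        assert m.probs.loc[7].isna().all()
        assert not np.isnan(m.probs.loc[6, 5])

    def test_out_of_range_daughter_flagged_not_dropped(self):
        m = empirical_division_matrix([(3, 6, 3)])
        assert m.row(3)[6] == 0.5
        assert len(m.anomalies) == 1
        assert m.anomalies.iloc[0]["daughter_n"] == 6

    def test_converges_to_analytic(self):
        from pctopo.synthetic_data import rule_event_stream

        for rule in ("equal", "random", "pascal"):
            events = rule_event_stream(rule, {5: 0.3, 6: 0.4, 7: 0.3},
                                       20_000, seed=5)
            emp = empirical_division_matrix(events, n_max=7)
            tv = emp.total_variation(analytic_division_matrix(rule, 7))
            assert (tv[[5, 6, 7]] < 0.02).all()


class TestAboav:
    def test_perfect_hex_lattice(self):
        from pctopo.tissue_graph import make_hex_torus

        g = make_hex_torus(4, 4)
        curve = aboav_curve(g.order)
        assert list(curve.table["n"]) == [6]
        assert curve.table["m_n"].iloc[0] == 6.0

    def test_reference_values(self):
        ref = aboav_reference([4, 6])
        assert ref.set_index("n").loc[4, "m_n"] == pytest.approx(7.0)
        ref_w = aboav_reference([6], form="weaire", a=1, mu2=1.3)
        assert ref_w["m_n"].iloc[0] == pytest.approx(5 + 7.3 / 6)

    def test_small_graph_against_brute_force(self):
        # pentagon ring with two poles: 5-sided poles, 4-sided ring cells
        ring = [f"r{i}" for i in range(5)]
        adj = {"top": list(ring), "bottom": list(ring)}
        for i, r in enumerate(ring):
            adj[r] = ["top", "bottom", ring[(i - 1) % 5], ring[(i + 1) % 5]]
        curve = aboav_curve(adj)
        # brute force: loop over cells per class
        deg = {c: len(v) for c, v in adj.items()}
        for n, expect_cells in ((4, 5), (5, 2)):
            members = [c for c in adj if deg[c] == n]
            oracle = np.mean([np.mean([deg[v] for v in adj[c]]) for c in members])
            row = curve.table.set_index("n").loc[n]
            assert row["cells"] == expect_cells
            assert row["m_n"] == pytest.approx(oracle)

    def test_edge_weighted_mean_degree_identity(self):
        """sum_n P(n) n m_n / sum_n P(n) n equals the mean degree over edge
        endpoints, by direct edge enumeration."""
        from pctopo.tissue_graph import DivisionRule, divide_cell, make_hex_torus

        g = make_hex_torus(4, 4)
        rng = np.random.default_rng(3)
        for _ in range(40):
            divide_cell(g, list(g.order)[int(rng.integers(g.n_cells))],
                        DivisionRule("random"), rng)
        deg = {c: len(v) for c, v in g.order.items()}
        curve = aboav_curve(g.order)
        dist = distribution_from_counts(deg.values())
        num = sum(dist.p(int(n)) * n * m for n, m in
                  zip(curve.table["n"], curve.table["m_n"])
                  for _ in [0])
        den = sum(dist.p(int(n)) * n for n in curve.table["n"])
        direct = np.mean([deg[v] for c in g.order for v in g.order[c]])
        assert num / den == pytest.approx(direct)


class TestLewis:
    def test_uniform_hexagons(self):
        cells = pd.DataFrame({"n": [6] * 5, "area": [1.0] * 5})
        lw = lewis_curve(cells)
        assert lw.table["mean_area"].iloc[0] == 1.0
        assert lw.reference.set_index("n").loc[6, "mean_area"] == pytest.approx(1.0)

    def test_reference_scaling_at_n3(self):
        cells = pd.DataFrame({"n": [3, 6], "area": [2.0, 4.0]})
        lw = lewis_curve(cells)
        a0_over_n = (2 + 4) / 2
        assert lw.reference.set_index("n").loc[3, "mean_area"] == pytest.approx(
            0.25 * a0_over_n)

    def test_groupby_is_order_invariant(self, rng, voronoi_fixture):
        cells = voronoi_fixture.frame.cells
        valid = cells[cells["tier"].isin(["neighbour-complete",
                                          "second-order-complete"])]
        shuffled = valid.sample(frac=1, random_state=1)
        a = lewis_curve(valid[["n", "area"]]).table
        b = lewis_curve(shuffled[["n", "area"]]).table
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))
        # oracle: direct per-class tabulation
        for n, grp in valid.groupby("n"):
            assert a.set_index("n").loc[n, "mean_area"] == pytest.approx(
                grp["area"].mean())


class TestNormalisedAreas:
    def test_three_cell_toy(self):
        adj = {1: [2, 3], 2: [1, 3], 3: [1, 2]}
        areas = {1: 1.0, 2: 2.0, 3: 3.0}
        res = normalised_area_relations(adj, areas)
        got = dict(zip(res.table["id"], res.table["norm_area"]))
        assert got[1] == pytest.approx(1 / 2.5)
        assert got[2] == pytest.approx(2 / 2.0)
        assert got[3] == pytest.approx(3 / 1.5)

    def test_central_cell_excluded_from_neighbour_normalisation(self):
        adj = {1: [2, 3], 2: [1, 3], 3: [1, 2]}
        areas = {1: 1.0, 2: 2.0, 3: 3.0}
        res = normalised_area_relations(adj, areas)
        row = res.table.set_index("id").loc[1]
        # neighbour 2 normalised by its neighbours minus cell 1 -> 2/3;
        # neighbour 3 -> 3/2
        assert row["nbr_mean_norm_area"] == pytest.approx((2 / 3 + 3 / 2) / 2)

    def test_uniform_areas_flagged_degenerate(self):
        adj = {i: [j for j in range(4) if j != i] for i in range(4)}
        areas = {i: 5.0 for i in range(4)}
        res = normalised_area_relations(adj, areas)
        assert (res.table["norm_area"] == 1).all()
        fit = res.fits["norm_area_vs_n"]
        assert fit["degenerate"] and np.isnan(fit["r2"])

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            normalised_area_relations({1: [2], 2: [1]}, {1: 1.0, 2: 2.0})
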