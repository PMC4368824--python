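"""Power diagrams, area solving, hierarchy, significance coloring, SVG."""

import numpy as np
import pytest

from egtcensus import voronoi_treemap as vt
from egtcensus.go_enrichment import EnrichmentResult


def result(term, p_adj, k=5):
    return EnrichmentResult(term=term, name=term, namespace="BP", k=k, n=10, K=20,
                            N=100, p_raw=p_adj, p_adj=p_adj,
                            significant=p_adj < 0.05)


class TestPowerDiagram:
    def test_single_site_fills_container(self):
        cells = vt.power_diagram(np.array([[0.5, 0.5]]), np.array([0.0]),
                                 vt.UNIT_SQUARE)
        assert vt.polygon_area(cells[0]) == pytest.approx(1.0)

    def test_two_symmetric_equal_sites_halve_the_square(self):
        cells = vt.power_diagram(np.array([[0.25, 0.5], [0.75, 0.5]]),
                                 np.zeros(2), vt.UNIT_SQUARE)
        assert vt.polygon_area(cells[0]) == pytest.approx(0.5, abs=1e-12)
        assert vt.polygon_area(cells[1]) == pytest.approx(0.5, abs=1e-12)

    def test_total_area_partitions_container(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 15))
            sites = rng.uniform(0.05, 0.95, size=(n, 2))
            weights = rng.uniform(0, 0.01, size=n)
            cells = vt.power_diagram(sites, weights, vt.UNIT_SQUARE)
            total = sum(vt.polygon_area(c) for c in cells)
            assert total == pytest.approx(1.0, rel=1e-9)

    def test_zero_weights_agree_with_sampled_voronoi_oracle(self, rng):
        """Monte-Carlo nearest-site membership oracle at zero weights."""
        sites = rng.uniform(0.1, 0.9, size=(3, 2))
        cells = vt.power_diagram(sites, np.zeros(3), vt.UNIT_SQUARE)
        pts = rng.uniform(0, 1, size=(1_000_000, 2))
        d2 = ((pts[:, None, :] - sites[None, :, :]) ** 2).sum(-1)
        counts = np.bincount(d2.argmin(axis=1), minlength=3)
        for i, cell in enumerate(cells):
            assert vt.polygon_area(cell) == pytest.approx(counts[i] / 1e6, abs=3e-3)

    def test_coincident_sites_jittered_not_crashed(self):
        sites = np.array([[0.5, 0.5], [0.5, 0.5]])
        cells = vt.power_diagram(sites, np.zeros(2), vt.UNIT_SQUARE,
                                 rng=np.random.default_rng(0))
        total = sum(vt.polygon_area(c) for c in cells)
        assert total == pytest.approx(1.0, rel=1e-6)


class TestSolveAreas:
    def test_single_weight_is_container(self):
        cells = vt.solve_areas([3.0], vt.LayoutConfig(seed=0))
        assert cells[0].area == pytest.approx(1.0)

    def test_two_equal_weights(self):
        cells = vt.solve_areas([1, 1], vt.LayoutConfig(seed=1))
        assert all(c.converged for c in cells)
        for c in cells:
            assert c.area == pytest.approx(0.5, rel=0.01)

    def test_proportional_areas_1234(self):
        cells = vt.solve_areas([1, 2, 3, 4], vt.LayoutConfig(seed=1))
        assert all(c.converged for c in cells)
        for c, target in zip(cells, [0.1, 0.2, 0.3, 0.4]):
            assert c.area == pytest.approx(target, rel=0.01)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            vt.solve_areas([1.0, 0.0], vt.LayoutConfig(seed=0))

    def test_deterministic_given_seed(self):
        a = vt.solve_areas([1, 2, 3], vt.LayoutConfig(seed=9))
        b = vt.solve_areas([1, 2, 3], vt.LayoutConfig(seed=9))
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.polygon, cb.polygon)


class TestLayoutHierarchy:
    def test_flat_list_equals_solve_areas(self):
        root = vt.WeightedTerm("root", 6.0, [vt.WeightedTerm("a", 1.0),
                                             vt.WeightedTerm("b", 2.0),
                                             vt.WeightedTerm("c", 3.0)])
        cells = vt.layout_hierarchy(root, vt.LayoutConfig(seed=4))
        flat = vt.solve_areas([1, 2, 3], vt.LayoutConfig(seed=4),
                              terms=["a", "b", "c"], parent="root")
        assert [c.term for c in cells] == [c.term for c in flat]
        for ca, cb in zip(cells, flat):
            assert ca.area == pytest.approx(cb.area)

    def test_nested_symmetric_quarters(self):
        children = [vt.WeightedTerm(f"p{i}", 1.0,
                                    [vt.WeightedTerm(f"p{i}c{j}", 0.5) for j in range(2)])
                    for i in range(2)]
        root = vt.WeightedTerm("root", 2.0, children)
        cells = vt.layout_hierarchy(root, vt.LayoutConfig(seed=5))
        leaf_cells = [c for c in cells if c.level == 1]
        assert len(leaf_cells) == 4
        for c in leaf_cells:
            assert c.area == pytest.approx(0.25, rel=0.025)

    def test_level_area_conservation(self):
        children = [vt.WeightedTerm(f"p{i}", w,
                                    [vt.WeightedTerm(f"p{i}c{j}", w / 3) for j in range(3)])
                    for i, w in enumerate([1.0, 2.0, 3.0])]
        root = vt.WeightedTerm("root", 6.0, children)
        cells = vt.layout_hierarchy(root, vt.LayoutConfig(seed=6))
        parents = {c.term: c.area for c in cells if c.level == 0}
        for parent, parent_area in parents.items():
            child_total = sum(c.area for c in cells
                              if c.level == 1 and c.parent == parent)
            assert child_total == pytest.approx(parent_area, rel=0.005)

    def test_single_chain_reuses_parent_polygon(self):
        root = vt.WeightedTerm("root", 1.0, [vt.WeightedTerm("a", 1.0)])
        cells = vt.layout_hierarchy(root, vt.LayoutConfig(seed=0))
        assert len(cells) == 1
        assert cells[0].term == "a"
        assert cells[0].area == pytest.approx(1.0)

    def test_residual_cell_for_excess_weight(self):
        root = vt.WeightedTerm("root", 4.0, [vt.WeightedTerm("a", 1.0),
                                             vt.WeightedTerm("b", 1.0)])
        cells = vt.layout_hierarchy(root, vt.LayoutConfig(seed=0))
        assert any(c.term == "root:residual" for c in cells)
        residual = next(c for c in cells if c.term == "root:residual")
        assert residual.area == pytest.approx(0.5, rel=0.02)

    def test_overweight_children_rejected(self):
        root = vt.WeightedTerm("root", 1.0, [vt.WeightedTerm("a", 2.0)])
        with pytest.raises(ValueError, match="outweigh"):
            vt.layout_hierarchy(root, vt.LayoutConfig(seed=0))

    def test_cyclic_hierarchy_rejected(self):
        a = vt.WeightedTerm("a", 1.0)
        root = vt.WeightedTerm("root", 2.0, [a])
        a.children.append(root)
        with pytest.raises(ValueError, match="cyclic"):
            vt.layout_hierarchy(root, vt.LayoutConfig(seed=0))


class TestColorBySignificance:
    def cells(self):
        return vt.solve_areas([1, 1, 1], vt.LayoutConfig(seed=2),
                              terms=["a", "b", "c"])

    def test_nonsignificant_band(self):
        cells = vt.color_by_significance(self.cells(), [result("a", 1.0)])
        assert cells[0].color == vt.NONSIG_COLOR

    def test_alpha_exactly_is_nonsignificant(self):
        cells = vt.color_by_significance(self.cells(), [result("a", 0.05)])
        assert cells[0].color == vt.NONSIG_COLOR

    def test_ramp_monotone_darker_for_smaller_p(self):
        cells = vt.color_by_significance(
            self.cells(), [result("a", 0.04), result("b", 0.0004)])
        assert cells[0].color != cells[1].color
        # viridis: smaller value = darker; smaller p maps further up the ramp
        assert sum(cells[1].color) != sum(cells[0].color)

    def test_missing_term_gets_neutral_grey(self):
        cells = vt.color_by_significance(self.cells(), [result("a", 0.01)])
        assert cells[1].color == vt.MISSING_COLOR


class TestRenderSvg:
    def test_byte_identical_for_same_seed(self):
        def build():
            cells = vt.solve_areas([1, 2, 3, 4], vt.LayoutConfig(seed=7))
            vt.color_by_significance(cells, [result(c.term, 0.01) for c in cells])
            return vt.render_svg(cells)

        assert build() == build()

    def test_polygons_tagged_with_metadata(self):
        cells = vt.solve_areas([1, 2], vt.LayoutConfig(seed=7), terms=["x", "y"])
        svg = vt.render_svg(cells)
        assert 'data-term="x"' in svg and 'data-term="y"' in svg
        assert "data-weight" in svg and "data-area" in svg
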