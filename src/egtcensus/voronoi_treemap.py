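"""Weight-proportional Voronoi treemaps for GO fingerprints.

Cells are computed as an additively weighted (power) Voronoi diagram inside
a convex container, obtained by clipping the container with the power
bisector half-plane of every site pair.  Cell areas are driven to their
target weights by Lloyd centroid moves combined with multiplicative
adaptation of the power weights (the standard centroidal-power-diagram
construction for Voronoi treemaps); hierarchical layouts recurse into each
parent cell.  Cells are colored on a continuous ramp over −log10 of the
adjusted p-value, with a distinct neutral band for non-significant terms
(p_adj ≥ alpha), and written as deterministic SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from matplotlib import colormaps

from .go_enrichment import EnrichmentResult

DEFAULT_ALPHA = 0.05
NONSIG_COLOR = (0.85, 0.85, 0.85)
MISSING_COLOR = (0.7, 0.7, 0.7)
RAMP_NAME = "viridis"
RAMP_MAX_NEGLOG10 = 10.0

UNIT_SQUARE = np.array([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])


@dataclass
class LayoutConfig:
    container: np.ndarray = field(default_factory=lambda: UNIT_SQUARE.copy())
    max_area_error: float = 0.01  # max relative area error per cell
    max_iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        self.container = np.asarray(self.container, dtype=float)
        if not 0.0 < self.max_area_error < 0.2:
            raise ValueError("max_area_error must lie in (0, 0.2)")
        if polygon_area(self.container) <= 0:
            raise ValueError("container must be counter-clockwise and non-degenerate")


@dataclass
class TreemapCell:
    term: str
    polygon: np.ndarray
    weight: float
    area: float
    color: tuple[float, float, float] = MISSING_COLOR
    parent: str | None = None
    level: int = 0
    p_adj: float | None = None
    converged: bool = True


def polygon_area(poly: np.ndarray) -> float:
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    a = polygon_area(poly)
    if a <= 0:
        return poly.mean(axis=0) if len(poly) else np.zeros(2)
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return np.array([cx, cy])


def _clip_halfplane(poly: np.ndarray, normal: np.ndarray, offset: float) -> np.ndarray:
    """Clip a convex polygon to {x : normal·x ≤ offset}.

    Exploits convexity: the kept vertices form one contiguous cyclic arc,
    capped by the two edge intersections.
    """
    if len(poly) == 0:
        return poly
    d = poly @ normal - offset
    inside = d <= 1e-12
    if inside.all():
        return poly
    if not inside.any():
        return poly[:0]
    n = len(poly)
    prev_inside = np.empty_like(inside)
    prev_inside[0] = inside[-1]
    prev_inside[1:] = inside[:-1]
    start = int(np.nonzero(inside & ~prev_inside)[0][0])
    count = int(inside.sum())
    keep = (start + np.arange(count)) % n
    i_in, i_prev = start, (start - 1) % n
    t = d[i_prev] / (d[i_prev] - d[i_in])
    entry = poly[i_prev] + t * (poly[i_in] - poly[i_prev])
    j_last, j_next = int(keep[-1]), (int(keep[-1]) + 1) % n
    t = d[j_last] / (d[j_last] - d[j_next])
    exit_pt = poly[j_last] + t * (poly[j_next] - poly[j_last])
    return np.vstack([entry[None, :], poly[keep], exit_pt[None, :]])


def power_diagram(
    sites: np.ndarray,
    weights: np.ndarray,
    container: np.ndarray,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Power (additively weighted Voronoi) cells inside a convex container.

    Cell i is {x : |x−p_i|² − w_i ≤ |x−p_j|² − w_j ∀j}, computed by
    clipping the container with the bisector half-plane of every pair.
    Empty cells come back as empty vertex arrays; the cells partition the
    container (total area matches to ~1e−9 relative).  Coincident sites
    with equal weights are separated by a seeded 1e−9 jitter.
    """
    sites = np.asarray(sites, dtype=float).copy()
    weights = np.asarray(weights, dtype=float)
    n = len(sites)
    if n == 1:
        return [container.copy()]
    diff2 = np.einsum("ijk,ijk->ij", sites[:, None, :] - sites[None, :, :],
                      sites[:, None, :] - sites[None, :, :])
    coincident = diff2 < 1e-24
    np.fill_diagonal(coincident, False)
    if coincident.any():  # separate coincident equal-weight sites by jitter
        jitter_rng = rng or np.random.default_rng(0)
        for i, j in zip(*np.nonzero(np.triu(coincident))):
            if abs(weights[i] - weights[j]) < 1e-15:
                sites[j] = sites[j] + jitter_rng.normal(scale=1e-9, size=2)
        diff2 = np.einsum("ijk,ijk->ij", sites[:, None, :] - sites[None, :, :],
                          sites[:, None, :] - sites[None, :, :])
    norms = np.einsum("ij,ij->i", sites, sites)
    cells: list[np.ndarray] = []
    for i in range(n):
        order = np.argsort(diff2[i])
        poly = container
        radius = None  # max vertex distance from the site; None = recompute
        for j in order:
            if j == i:
                continue
            d = math.sqrt(diff2[i, j])
            if d > 0:
                # distance from site i to the i/j power bisector; a site whose
                # bisector lies beyond every current vertex cannot cut the cell
                h = 0.5 * (d + (weights[i] - weights[j]) / d)
                if radius is None:
                    radius = math.sqrt(
                        np.max(np.einsum("kj,kj->k", poly - sites[i], poly - sites[i])))
                if h >= radius:
                    continue
            normal = 2.0 * (sites[j] - sites[i])
            offset = norms[j] - norms[i] - weights[j] + weights[i]
            clipped = _clip_halfplane(poly, normal, offset)
            if clipped is not poly:
                poly = clipped
                radius = None
            if len(poly) == 0:
                break
        cells.append(np.asarray(poly, dtype=float))
    return cells


def solve_areas(
    weights: Sequence[float],
    config: LayoutConfig,
    terms: Sequence[str] | None = None,
    parent: str | None = None,
    level: int = 0,
) -> list[TreemapCell]:
    """Drive power-diagram cell areas to the given weight proportions.

    Each iteration moves every site to its cell centroid (Lloyd step) and
    then nudges its power weight by the cell's area deficit — a damped
    gradient step on the concave area-capacity objective of the power
    diagram.  Iteration stops when every cell's relative area error is
    within ``config.max_area_error`` or after ``config.max_iterations``
    (cells are then flagged non-converged).  Deterministic given the seed.
    """
    weights = np.asarray(list(weights), dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    n = len(weights)
    terms = list(terms) if terms is not None else [f"cell{i}" for i in range(n)]
    container = config.container
    total_area = polygon_area(container)
    if n == 1:
        return [TreemapCell(term=terms[0], polygon=container.copy(), weight=float(weights[0]),
                            area=total_area, parent=parent, level=level)]
    targets = weights / weights.sum()
    rng = np.random.default_rng(config.seed)

    lo, hi = container.min(axis=0), container.max(axis=0)
    sites = np.empty((n, 2))
    filled = 0
    while filled < n:  # rejection-sample interior start positions
        cand = rng.uniform(lo, hi, size=(n - filled, 2))
        inside = _points_in_convex(cand, container)
        take = cand[inside]
        sites[filled : filled + len(take)] = take
        filled += len(take)
    pw = np.zeros(n)
    # step size in units of the container scale; backed off on divergence
    tau = 0.8
    prev_err = np.inf

    cells: list[np.ndarray] = []
    converged = False
    for _ in range(config.max_iterations):
        cells = power_diagram(sites, pw, container, rng=rng)
        areas = np.array([polygon_area(c) for c in cells])
        rel_err = np.abs(areas / total_area - targets) / targets
        if np.all(rel_err <= config.max_area_error):
            converged = True
            break
        # Lloyd move
        for i, c in enumerate(cells):
            if len(c) >= 3:
                sites[i] = polygon_centroid(c)
        err = float(rel_err.max())
        if err > prev_err * 1.02:
            tau = max(tau * 0.9, 0.05)
        prev_err = err
        pw = pw + tau * (targets * total_area - areas)
        pw -= pw.mean()

    out = []
    for i, c in enumerate(cells):
        out.append(TreemapCell(term=terms[i], polygon=c, weight=float(weights[i]),
                               area=polygon_area(c), parent=parent, level=level,
                               converged=converged))
    return out


def _points_in_convex(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    inside = np.ones(len(points), dtype=bool)
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        edge = b - a
        normal = np.array([edge[1], -edge[0]])  # outward for CCW polygons
        inside &= (points - a) @ normal <= -1e-9
    return inside


@dataclass
class WeightedTerm:
    """A node of the weighted GO-term hierarchy to lay out."""

    term: str
    weight: float
    children: list["WeightedTerm"] = field(default_factory=list)


def layout_hierarchy(root: WeightedTerm, config: LayoutConfig) -> list[TreemapCell]:
    """Recursive treemap: each level partitions its parent's polygon.

    An internal term whose weight exceeds the sum of its children gets a
    residual cell for the excess.  A chain (single child carrying the full
    weight) reuses the parent polygon unchanged.
    """
    _check_acyclic(root, set())
    cells: list[TreemapCell] = []

    def recurse(node: WeightedTerm, polygon: np.ndarray, level: int, seed: int) -> None:
        if not node.children:
            return
        child_sum = sum(c.weight for c in node.children)
        if child_sum > node.weight + 1e-9:
            raise ValueError(f"children of {node.term} outweigh their parent")
        entries = list(node.children)
        residual = node.weight - child_sum
        if residual > 1e-9 * node.weight:
            entries.append(WeightedTerm(term=f"{node.term}:residual", weight=residual))
        sub_config = LayoutConfig(container=polygon, max_area_error=config.max_area_error,
                                  max_iterations=config.max_iterations, seed=seed)
        level_cells = solve_areas([e.weight for e in entries], sub_config,
                                  terms=[e.term for e in entries], parent=node.term,
                                  level=level)
        cells.extend(level_cells)
        for idx, (e, cell) in enumerate(zip(entries, level_cells)):
            if e.children and len(cell.polygon) >= 3:
                recurse(e, cell.polygon, level + 1, (seed * 31 + idx + 1) % (2**31))

    recurse(root, config.container, 0, config.seed)
    if not cells:  # a leaf-only "hierarchy": the root fills the container
        cells = [TreemapCell(term=root.term, polygon=config.container.copy(),
                             weight=root.weight, area=polygon_area(config.container))]
    return cells


def _check_acyclic(node: WeightedTerm, seen: set[str]) -> None:
    if node.term in seen:
        raise ValueError(f"cyclic term hierarchy at {node.term}")
    seen = seen | {node.term}
    for c in node.children:
        _check_acyclic(c, seen)


def color_by_significance(
    cells: Sequence[TreemapCell],
    results: Sequence[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
) -> list[TreemapCell]:
    """Color cells on a −log10(p_adj) ramp; non-significant cells (p_adj ≥
    alpha, strict < rule) get a distinct neutral band, terms without a
    result neutral grey."""
    p_of: Mapping[str, float] = {r.term: r.p_adj for r in results}
    cmap = colormaps[RAMP_NAME]
    lo = -np.log10(alpha)
    for cell in cells:
        p = p_of.get(cell.term)
        cell.p_adj = p
        if p is None:
            cell.color = MISSING_COLOR
        elif p >= alpha:
            cell.color = NONSIG_COLOR
        else:
            x = (-np.log10(max(p, 1e-300)) - lo) / (RAMP_MAX_NEGLOG10 - lo)
            r, g, b, _ = cmap(float(np.clip(x, 0.0, 1.0)))
            cell.color = (r, g, b)
    return list(cells)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _rgb_hex(color: tuple[float, float, float]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*(int(round(255 * c)) for c in color))


def render_svg(cells: Sequence[TreemapCell], width: int = 600, height: int = 600) -> str:
    """Deterministic SVG: one group per hierarchy level, each polygon tagged
    with its term, weight, area and adjusted p-value."""
    if not cells:
        raise ValueError("nothing to render")
    allpts = np.vstack([c.polygon for c in cells if len(c.polygon)])
    lo, hi = allpts.min(axis=0), allpts.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    scale = min(width / span[0], height / span[1])

    def fmt_point(p: np.ndarray) -> str:
        x = (p[0] - lo[0]) * scale
        y = (hi[1] - p[1]) * scale  # flip y for SVG
        return f"{x:.4f},{y:.4f}"

    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">'
    ]
    for level in sorted({c.level for c in cells}):
        lines.append(f'<g id="level{level}">')
        for c in cells:
            if c.level != level or len(c.polygon) < 3:
                continue
            pts = " ".join(fmt_point(p) for p in c.polygon)
            p_attr = f"{c.p_adj:.6g}" if c.p_adj is not None else "NA"
            lines.append(
                f'<polygon points="{pts}" fill="{_rgb_hex(c.color)}" stroke="#ffffff" '
                f'stroke-width="1" data-term="{c.term}" data-weight="{c.weight:.6g}" '
                f'data-area="{c.area:.6g}" data-p-adj="{p_attr}"/>'
            )
        lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def write_cells_tsv(cells: Sequence[TreemapCell], path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tlevel\tparent\tweight\tarea\tp_adj\tvertices\n")
        for c in cells:
            verts = ";".join(f"{x:.6f},{y:.6f}" for x, y in c.polygon)
            p_attr = f"{c.p_adj:.6g}" if c.p_adj is not None else "NA"
            fh.write(f"{c.term}\t{c.level}\t{c.parent or ''}\t{c.weight:.6g}\t"
                     f"{c.area:.6g}\t{p_attr}\t{verts}\n")
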