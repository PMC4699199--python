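"""Deterministic synthetic networks with hand-computable ground truth.

These fixtures pin down the decomposition and the metrics: the nesting tree
of a ladder is the caterpillar dictated by the rank order of its rung
widths, the recursive-bisection fixture is perfectly nested by
construction, and the tapered path has a closed-form mean topological
length.  Widths are chosen as exact values so float ties cannot occur
unless deliberately introduced.
"""

from __future__ import annotations

from .network import Edge, VeinNetwork, build_network
from .segments import VeinSegment, segments_to_network


def make_ladder(
    n_cells: int,
    shared_widths: list[float] | None = None,
    perimeter_width: float = 3.0,
) -> VeinNetwork:
    """1 x n chain of unit cells (cm).  Interior rung i gets
    ``shared_widths[i]`` (mm); all perimeter edges get ``perimeter_width``.

    Edge ids 0..n-2 are the interior rungs left to right, so width ties
    resolve left-first.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if shared_widths is None:
        shared_widths = [float(i + 1) for i in range(n_cells - 1)]
    if len(shared_widths) != n_cells - 1:
        raise ValueError("need exactly n_cells - 1 shared widths")
    if shared_widths and not all(w < perimeter_width for w in shared_widths):
        raise ValueError("shared widths must be thinner than the perimeter")

    nodes = []
    for i in range(n_cells + 1):
        nodes.append((2 * i, float(i), 0.0))
        nodes.append((2 * i + 1, float(i), 1.0))
    edges: list[tuple[int, int, int, float, float | None]] = []
    eid = 0
    for i in range(1, n_cells):  # interior rungs first: ids 0..n-2
        edges.append((eid, 2 * i, 2 * i + 1, shared_widths[i - 1], None))
        eid += 1
    edges.append((eid, 0, 1, perimeter_width, None)); eid += 1  # left end
    edges.append((eid, 2 * n_cells, 2 * n_cells + 1, perimeter_width, None)); eid += 1  # right end
    for i in range(n_cells):  # top and bottom rails
        edges.append((eid, 2 * i, 2 * i + 2, perimeter_width, None)); eid += 1
        edges.append((eid, 2 * i + 1, 2 * i + 3, perimeter_width, None)); eid += 1
    return build_network(nodes, edges)


def make_caterpillar(n_cells: int = 4, perimeter_width: float = 10.0) -> VeinNetwork:
    """Ladder whose rung widths increase left to right: its nesting tree is
    the caterpillar with nesting ratios 1, 1/2, ..., 1/(n-1)."""
    return make_ladder(n_cells, [float(i + 1) for i in range(n_cells - 1)], perimeter_width)


def make_hierarchical(depth: int, width_decay: float = 0.5, side_cm: float = 1.0) -> VeinNetwork:
    """Recursive midline bisection of a square: generation-g veins have width
    ``width_decay**g`` mm, giving 2**depth areoles and a perfectly balanced
    nesting tree (unweighted nesting number 1)."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0 < width_decay < 1):
        raise ValueError("width_decay must lie in (0, 1)")
    s = side_cm
    segments = [
        VeinSegment(0, 0, s, 0, 1.0),
        VeinSegment(s, 0, s, s, 1.0),
        VeinSegment(s, s, 0, s, 1.0),
        VeinSegment(0, s, 0, 0, 1.0),
    ]
    rects = [(0.0, 0.0, s, s)]
    for g in range(1, depth + 1):
        w = width_decay**g
        new_rects = []
        for (x0, y0, x1, y1) in rects:
            if (x1 - x0) >= (y1 - y0):  # split the longer axis
                xm = (x0 + x1) / 2
                segments.append(VeinSegment(xm, y0, xm, y1, w))
                new_rects += [(x0, y0, xm, y1), (xm, y0, x1, y1)]
            else:
                ym = (y0 + y1) / 2
                segments.append(VeinSegment(x0, ym, x1, ym, w))
                new_rects += [(x0, y0, x1, ym), (x0, ym, x1, y1)]
        rects = new_rects
    return segments_to_network(segments)


def make_grid(n_rows: int, n_cols: int, cell_cm: float = 1.0, width: float = 1.0) -> VeinNetwork:
    """n_rows x n_cols grid of square cells with uniform widths; combine with
    :func:`with_widths` for randomized-width instances."""
    nodes = []
    for i in range(n_rows + 1):
        for j in range(n_cols + 1):
            nodes.append((i * (n_cols + 1) + j, j * cell_cm, i * cell_cm))
    edges: list[tuple[int, int, int, float, float | None]] = []
    eid = 0
    for i in range(n_rows + 1):
        for j in range(n_cols + 1):
            n = i * (n_cols + 1) + j
            if j < n_cols:
                edges.append((eid, n, n + 1, width, None)); eid += 1
            if i < n_rows:
                edges.append((eid, n, n + n_cols + 1, width, None)); eid += 1
    return build_network(nodes, edges)


def make_tapered_path(n_edges: int, top_width: float | None = None) -> VeinNetwork:
    """Straight path whose widths decrease strictly along it (n, n-1, ..., 1);
    its mean topological length is (n - 1) / 2."""
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    nodes = [(i, float(i), 0.0) for i in range(n_edges + 1)]
    w0 = float(n_edges) if top_width is None else top_width
    edges = [(i, i, i + 1, w0 - i, None) for i in range(n_edges)]
    return build_network(nodes, edges)


def with_widths(net: VeinNetwork, widths: dict[int, float]) -> VeinNetwork:
    """Copy of the network with edge widths replaced (same ids/geometry)."""
    edges = {
        eid: Edge(e.node_a, e.node_b, float(widths.get(eid, e.width)), e.length)
        for eid, e in net.edges.items()
    }
    return VeinNetwork(dict(net.nodes), edges)
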