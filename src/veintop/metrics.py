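"""Topological and geometric venation phenotype metrics.

The eight-entry "venation fingerprint" of a network combines five geometric
quantities — vein density sigma (mm/mm²), mean inter-vein distance a (mm),
mean areole area A (mm²), areole density rho_A (mm⁻²), length-weighted mean
vein diameter d (mm) — with three topological ones: the mean topological
length L_top of the strictly width-decreasing greedy walk, and the
unweighted / degree-weighted nesting numbers i_u, i_w averaged over the
nesting-tree internal nodes whose subtree degree does not exceed a
threshold (256 for whole leaves, 128 for fragments, to remove organ-size
effects).

Topological entries depend only on the rank order of vein widths; geometric
entries scale with the lamina (under uniform scaling by k: sigma -> sigma/k,
a -> k a, A -> k² A, rho_A -> rho_A/k², d unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .decomposition import NestingTree, build_nesting_tree
from .network import (
    CM_TO_MM,
    Areole,
    EmptyNetworkError,
    VeinNetwork,
    extract_facets,
    outer_boundary_polygon,
    prune_to_cycles,
)

FULL_LEAF_MAX_DEGREE = 256
FRAGMENT_MAX_DEGREE = 128


class UndefinedMetricError(ValueError):
    """No internal tree node passes the degree filter: the metric is undefined."""


@dataclass(frozen=True)
class Fingerprint:
    sigma: float  # vein density, mm / mm^2
    a: float  # mean inter-vein distance, mm
    A: float  # mean areole area, mm^2
    rho_A: float  # areole density, mm^-2
    d: float  # length-weighted mean vein diameter, mm
    L_top: float  # mean topological length (dimensionless)
    i_u: float  # unweighted nesting number
    i_w: float  # degree-weighted nesting number

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRIC_COLUMNS = [f.name for f in fields(Fingerprint)]
GEOMETRY_COLUMNS = ["sigma", "a", "A", "rho_A", "d"]
TOPOLOGY_COLUMNS = ["L_top", "i_u", "i_w"]


# ---------------------------------------------------------------------------
# nesting-tree statistics
# ---------------------------------------------------------------------------

def nesting_ratios(tree: NestingTree, max_degree: int = FULL_LEAF_MAX_DEGREE) -> list[float]:
    """q_j = s_j / r_j for every internal node with subtree degree d_j <= max_degree."""
    if max_degree < 2:
        raise ValueError("max_degree must be >= 2")
    return [n.q for n in tree.internal_nodes if n.d <= max_degree]


def nesting_number(
    tree: NestingTree,
    mode: str = "unweighted",
    max_degree: int = FULL_LEAF_MAX_DEGREE,
) -> float:
    """Weighted mean of nesting ratios over degree-filtered internal nodes.

    ``unweighted`` gives every node equal weight; ``degree_weighted`` uses
    weights proportional to d_j - 1, emphasizing merges near the root.
    """
    nodes = [n for n in tree.internal_nodes if n.d <= max_degree]
    if not nodes:
        raise UndefinedMetricError(
            f"no internal nodes with degree <= {max_degree}; nesting number undefined"
        )
    q = np.array([n.q for n in nodes])
    if mode == "unweighted":
        return float(q.mean())
    if mode == "degree_weighted":
        w = np.array([n.d - 1 for n in nodes], dtype=float)
        return float((w * q).sum() / w.sum())
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# topological (tapering) lengths
# ---------------------------------------------------------------------------

def topological_lengths(net: VeinNetwork) -> dict[int, int]:
    """Greedy strictly width-decreasing walk length L_e from every edge.

    From the current edge, step to the adjacent edge (sharing an endpoint)
    of maximal width among those strictly thinner; ties break on the smaller
    edge id; stop when no strictly thinner neighbor exists.  Strict decrease
    makes the walk finite without visited-set bookkeeping.
    """
    incident: dict[int, list[int]] = {n: [] for n in net.nodes}
    for eid, e in net.edges.items():
        incident[e.node_a].append(eid)
        incident[e.node_b].append(eid)

    def next_edge(eid: int) -> int | None:
        e = net.edges[eid]
        w = e.width
        best: tuple[float, int] | None = None
        for n in (e.node_a, e.node_b):
            for other in incident[n]:
                if other == eid:
                    continue
                ow = net.edges[other].width
                if ow < w and (best is None or (-ow, other) < best):
                    best = (-ow, other)
        return None if best is None else best[1]

    out: dict[int, int] = {}
    for eid in net.edges:
        steps = 0
        cur = eid
        while True:
            nxt = next_edge(cur)
            if nxt is None:
                break
            cur = nxt
            steps += 1
        out[eid] = steps
    return out


def mean_topological_length(net: VeinNetwork) -> float:
    if net.n_edges == 0:
        raise EmptyNetworkError("mean topological length of an empty network")
    lengths = topological_lengths(net)
    return float(np.mean(list(lengths.values())))


# ---------------------------------------------------------------------------
# geometric metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometricMetrics:
    sigma: float
    a: float
    A: float
    rho_A: float
    d: float


def _mean_intervein_distance_mm(net: VeinNetwork, spacing_mm: float | None) -> float:
    """Mean distance from uniform sample points inside the blade polygon to
    the nearest vein centerline, via an STRtree over the edge segments."""
    outer = np.asarray(outer_boundary_polygon(net)) * CM_TO_MM
    poly = Polygon(outer)
    if not poly.is_valid:
        poly = poly.buffer(0)
    minx, miny, maxx, maxy = poly.bounds
    diameter = max(maxx - minx, maxy - miny)
    if spacing_mm is None:
        spacing_mm = min(0.1, diameter / 500.0)
    xs = np.arange(minx + spacing_mm / 2, maxx, spacing_mm)
    ys = np.arange(miny + spacing_mm / 2, maxy, spacing_mm)
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(gx.ravel(), gy.ravel())
    inside = shapely.contains(poly, pts)
    pts = pts[inside]
    if pts.size == 0:
        raise EmptyNetworkError("no interior sample points; blade polygon degenerate")
    segs = []
    for eid in sorted(net.edges):
        e = net.edges[eid]
        (xa, ya), (xb, yb) = net.nodes[e.node_a], net.nodes[e.node_b]
        segs.append(LineString([(xa * CM_TO_MM, ya * CM_TO_MM), (xb * CM_TO_MM, yb * CM_TO_MM)]))
    tree = shapely.STRtree(segs)
    qi, ti = tree.query_nearest(pts)
    seg_arr = np.array(segs, dtype=object)
    dists = shapely.distance(pts[qi], seg_arr[ti])
    # query_nearest may return several equally-near segments per point
    import pandas as pd

    return float(pd.Series(dists).groupby(qi).min().mean())


def geometric_metrics(
    net: VeinNetwork,
    facets: list[Areole] | None = None,
    grid_spacing_mm: float | None = None,
) -> GeometricMetrics:
    """sigma, a, A, rho_A, d of a pruned connected network (units mm-based).

    Leaf area is the area of the outer boundary polygon (robust for lobed
    outlines, unlike a convex hull).
    """
    if facets is None:
        facets = extract_facets(net)
    if not facets:
        raise EmptyNetworkError("geometric metrics require at least one facet")
    leaf_area_mm2 = abs(Polygon(np.asarray(outer_boundary_polygon(net)) * CM_TO_MM).area)
    total_len = net.total_vein_length_mm()
    areas_mm2 = np.array([f.area for f in facets]) * CM_TO_MM**2
    lengths = np.array([net.edges[eid].length for eid in sorted(net.edges)])
    widths = np.array([net.edges[eid].width for eid in sorted(net.edges)])
    return GeometricMetrics(
        sigma=total_len / leaf_area_mm2,
        a=_mean_intervein_distance_mm(net, grid_spacing_mm),
        A=float(areas_mm2.mean()),
        rho_A=len(facets) / leaf_area_mm2,
        d=float((widths * lengths).sum() / lengths.sum()),
    )


# ---------------------------------------------------------------------------
# the fingerprint
# ---------------------------------------------------------------------------

def fingerprint(
    net: VeinNetwork,
    max_degree: int = FULL_LEAF_MAX_DEGREE,
    grid_spacing_mm: float | None = None,
    pair_weight: str = "min",
) -> Fingerprint:
    """Assemble the 8-metric fingerprint of a network.

    The input is pruned to its cycle-supported subgraph first (a no-op if
    already pruned); at least two facets are required so the nesting tree
    has an internal node.
    """
    pruned = prune_to_cycles(net)
    facets = extract_facets(pruned)
    if len(facets) < 2:
        raise EmptyNetworkError("fingerprint requires >= 2 facets")
    tree = build_nesting_tree(pruned, facets, pair_weight=pair_weight)
    geo = geometric_metrics(pruned, facets, grid_spacing_mm)
    return Fingerprint(
        sigma=geo.sigma,
        a=geo.a,
        A=geo.A,
        rho_A=geo.rho_A,
        d=geo.d,
        L_top=mean_topological_length(pruned),
        i_u=nesting_number(tree, "unweighted", max_degree),
        i_w=nesting_number(tree, "degree_weighted", max_degree),
    )
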