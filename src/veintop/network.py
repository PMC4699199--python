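"""Planar weighted vein networks: domain types, validation, I/O, pruning, faces.

A :class:`VeinNetwork` is a planar graph embedded in the plane by its node
coordinates (cm); edges are straight segments carrying a vein width (mm) and
a centerline length (mm, defaulting to the Euclidean distance between the
endpoints).  Faces of the embedding other than the unbounded outer face are
the *areoles* — the smallest closed regions bounded by veins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LineString

logger = logging.getLogger(__name__)

CM_TO_MM = 10.0


class NetworkValidationError(ValueError):
    """Input violates a VeinNetwork invariant (widths, loops, attributes)."""


class EmbeddingError(NetworkValidationError):
    """Straight-segment edges cross: coordinates do not define a planar embedding."""


class EmptyNetworkError(ValueError):
    """The operation requires a network with at least one cycle/facet."""


@dataclass(frozen=True)
class Edge:
    node_a: int
    node_b: int
    width: float  # mm
    length: float  # mm


@dataclass(frozen=True)
class Areole:
    """An internal face of a pruned network.

    ``boundary`` is the ordered cyclic list of edge ids of the face walk;
    ``area`` is the shoelace area of the boundary polygon in cm².
    """

    facet_id: int
    boundary: tuple[int, ...]
    area: float  # cm^2
    boundary_nodes: tuple[int, ...] = field(compare=False, default=())


@dataclass
class VeinNetwork:
    """Planar embedded weighted graph: node coords in cm, edge widths in mm."""

    nodes: dict[int, tuple[float, float]]
    edges: dict[int, Edge]

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_length_cm(self, eid: int) -> float:
        e = self.edges[eid]
        (xa, ya), (xb, yb) = self.nodes[e.node_a], self.nodes[e.node_b]
        return math.hypot(xb - xa, yb - ya)

    def total_vein_length_mm(self) -> float:
        return sum(e.length for e in self.edges.values())

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        for nid, (x, y) in self.nodes.items():
            g.add_node(nid, x=x, y=y)
        for eid, e in self.edges.items():
            g.add_edge(e.node_a, e.node_b, eid=eid, width=e.width, length=e.length)
        return g

    # -- validation --------------------------------------------------------
    def validate(self, check_crossings: bool = False) -> None:
        for eid, e in self.edges.items():
            if e.node_a == e.node_b:
                raise NetworkValidationError(f"edge {eid} is a self-loop")
            if not (e.width > 0):
                raise NetworkValidationError(f"edge {eid} has non-positive width {e.width}")
            if not (e.length > 0):
                raise NetworkValidationError(f"edge {eid} has non-positive length {e.length}")
            for n in (e.node_a, e.node_b):
                if n not in self.nodes:
                    raise NetworkValidationError(f"edge {eid} references unknown node {n}")
        # straight-segment edges: a parallel pair is geometrically coincident,
        # which breaks the embedding — reject it.
        seen: set[tuple[int, int]] = set()
        for eid, e in self.edges.items():
            key = (min(e.node_a, e.node_b), max(e.node_a, e.node_b))
            if key in seen:
                raise EmbeddingError(f"parallel edge {eid} between nodes {key}")
            seen.add(key)
        if check_crossings:
            self._check_crossings()

    def _check_crossings(self) -> None:
        if self.n_edges < 2:
            return
        segs = []
        eids = list(self.edges)
        for eid in eids:
            e = self.edges[eid]
            segs.append(LineString([self.nodes[e.node_a], self.nodes[e.node_b]]))
        tree = shapely.STRtree(segs)
        for pred in ("crosses", "overlaps"):
            i, j = tree.query(np.array(segs, dtype=object), predicate=pred)
            bad = [(eids[a], eids[b]) for a, b in zip(i, j) if a < b]
            if bad:
                raise EmbeddingError(f"edges {pred.rstrip('es')} each other: {bad[:5]}")


def build_network(
    node_rows: list[tuple[int, float, float]],
    edge_rows: list[tuple[int, int, int, float, float | None]],
    check_crossings: bool = False,
) -> VeinNetwork:
    """Assemble a VeinNetwork from raw rows; missing lengths default to the
    Euclidean endpoint distance converted from cm to mm."""
    nodes = {int(nid): (float(x), float(y)) for nid, x, y in node_rows}
    edges: dict[int, Edge] = {}
    for eid, a, b, width, length in edge_rows:
        a, b = int(a), int(b)
        if length is None or (isinstance(length, float) and math.isnan(length)):
            (xa, ya), (xb, yb) = nodes[a], nodes[b]
            length = math.hypot(xb - xa, yb - ya) * CM_TO_MM
        edges[int(eid)] = Edge(a, b, float(width), float(length))
    net = VeinNetwork(nodes, edges)
    if check_crossings:
        net._check_crossings()
    return net


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_network(path: str, format: str | None = None, check_crossings: bool = True) -> VeinNetwork:
    """Read a network from GraphML or TSV.

    GraphML carries node attrs ``x``, ``y`` (cm) and edge attrs ``width`` (mm)
    and optional ``length`` (mm).  The TSV form is a pair of files: an edge
    list ``node_a<TAB>node_b<TAB>width[<TAB>length]`` at *path* plus a
    companion node table ``node_id<TAB>x<TAB>y`` at ``<path minus .tsv>.nodes.tsv``.
    """
    fmt = format or ("tsv" if str(path).endswith(".tsv") else "graphml")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        node_rows, edge_rows = [], []
        relabel = {n: i for i, n in enumerate(g.nodes)}
        for n, d in g.nodes(data=True):
            if "x" not in d or "y" not in d:
                raise NetworkValidationError(f"node {n} missing x/y attribute")
            node_rows.append((relabel[n], float(d["x"]), float(d["y"])))
        for i, (u, v, d) in enumerate(g.edges(data=True)):
            if "width" not in d:
                raise NetworkValidationError(f"edge {(u, v)} missing width attribute")
            eid = int(d.get("eid", i))
            length = float(d["length"]) if "length" in d else None
            edge_rows.append((eid, relabel[u], relabel[v], float(d["width"]), length))
    elif fmt == "tsv":
        import pandas as pd

        nodes_path = str(path)[: -len(".tsv")] + ".nodes.tsv" if str(path).endswith(".tsv") else str(path) + ".nodes.tsv"
        edf = pd.read_csv(path, sep="\t")
        ndf = pd.read_csv(nodes_path, sep="\t")
        for col in ("node_a", "node_b", "width"):
            if col not in edf.columns:
                raise NetworkValidationError(f"TSV edge list missing column {col!r}")
        for col in ("node_id", "x", "y"):
            if col not in ndf.columns:
                raise NetworkValidationError(f"TSV node table missing column {col!r}")
        node_rows = [(int(r.node_id), float(r.x), float(r.y)) for r in ndf.itertuples()]
        edge_rows = []
        for i, r in enumerate(edf.itertuples()):
            length = float(r.length) if "length" in edf.columns else None
            edge_rows.append((i, int(r.node_a), int(r.node_b), float(r.width), length))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return build_network(node_rows, edge_rows, check_crossings=check_crossings)


def write_network(net: VeinNetwork, path: str, format: str | None = None) -> None:
    """Write a network; round-trips with :func:`read_network`."""
    fmt = format or ("tsv" if str(path).endswith(".tsv") else "graphml")
    if fmt == "graphml":
        g = nx.Graph()
        for nid in sorted(net.nodes):
            x, y = net.nodes[nid]
            g.add_node(nid, x=x, y=y)
        for eid in sorted(net.edges):
            e = net.edges[eid]
            g.add_edge(e.node_a, e.node_b, eid=eid, width=e.width, length=e.length)
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        import pandas as pd

        nodes_path = str(path)[: -len(".tsv")] + ".nodes.tsv" if str(path).endswith(".tsv") else str(path) + ".nodes.tsv"
        edf = pd.DataFrame(
            [
                {"node_a": e.node_a, "node_b": e.node_b, "width": e.width, "length": e.length}
                for _, e in sorted(net.edges.items())
            ]
        )
        ndf = pd.DataFrame(
            [{"node_id": nid, "x": x, "y": y} for nid, (x, y) in sorted(net.nodes.items())]
        )
        edf.to_csv(path, sep="\t", index=False)
        ndf.to_csv(nodes_path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Pruning to the cycle-supported subgraph
# ---------------------------------------------------------------------------

def prune_to_cycles(net: VeinNetwork) -> VeinNetwork:
    """Keep exactly the edges that lie on at least one cycle.

    An edge lies on a cycle iff it is not a bridge, so a single bridge
    removal plus dropping isolated nodes reaches the fixed point of the
    iterative degree-1/bridge peeling.  If several loopy components remain,
    the one with the most faces (E - V + 1) is kept with a warning.
    """
    g = net.to_nx()
    bridges = set(nx.bridges(g))
    g.remove_edges_from(bridges)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    if g.number_of_edges() == 0:
        raise EmptyNetworkError("no cycles remain after pruning (input was a forest)")
    comps = [g.subgraph(c) for c in nx.connected_components(g)]
    if len(comps) > 1:
        comps.sort(key=lambda c: (c.number_of_edges() - c.number_of_nodes() + 1, c.number_of_edges()), reverse=True)
        logger.warning(
            "pruned network has %d loopy components; keeping the one with most faces",
            len(comps),
        )
    keep = comps[0]
    nodes = {n: net.nodes[n] for n in keep.nodes}
    edges = {d["eid"]: net.edges[d["eid"]] for _, _, d in keep.edges(data=True)}
    return VeinNetwork(nodes, edges)


# ---------------------------------------------------------------------------
# Face (areole) extraction
# ---------------------------------------------------------------------------

def _face_walks(net: VeinNetwork) -> list[list[tuple[int, int, int]]]:
    """Trace all faces of the straight-line embedding.

    Half-edges (u, v, eid); at each node the incident edges are sorted by
    angle and the successor of an incoming half-edge is the next one in
    clockwise rotation, which traces each face exactly once.
    """
    # rotation system: outgoing half-edges sorted counterclockwise by angle
    rotation: dict[int, list[tuple[int, int]]] = {}
    for nid in net.nodes:
        rotation[nid] = []
    for eid, e in net.edges.items():
        rotation[e.node_a].append((e.node_b, eid))
        rotation[e.node_b].append((e.node_a, eid))
    index: dict[tuple[int, int, int], int] = {}
    for nid, out in rotation.items():
        x0, y0 = net.nodes[nid]
        out.sort(key=lambda t: math.atan2(net.nodes[t[0]][1] - y0, net.nodes[t[0]][0] - x0))
        for i, (nbr, eid) in enumerate(out):
            index[(nid, nbr, eid)] = i

    visited: set[tuple[int, int, int]] = set()
    faces = []
    for eid, e in sorted(net.edges.items()):
        for start in ((e.node_a, e.node_b, eid), (e.node_b, e.node_a, eid)):
            if start in visited:
                continue
            walk = []
            h = start
            while h not in visited:
                visited.add(h)
                walk.append(h)
                u, v, he = h
                out = rotation[v]
                i = index[(v, u, he)]
                # next clockwise outgoing half-edge at v after the reversal
                nbr, neid = out[(i - 1) % len(out)]
                h = (v, nbr, neid)
            faces.append(walk)
    return faces


def _signed_area(net: VeinNetwork, walk: list[tuple[int, int, int]]) -> float:
    pts = [net.nodes[u] for u, _, _ in walk]
    s = 0.0
    for (x1, y1), (x2, y2) in zip(pts, pts[1:] + pts[:1]):
        s += x1 * y2 - x2 * y1
    return 0.5 * s


def extract_facets(net: VeinNetwork) -> list[Areole]:
    """All internal faces of a pruned, connected network as Areole records.

    The outer face (negative signed area under the traversal orientation,
    ties broken by the largest absolute area) is excluded.  For a connected
    planar graph the count satisfies F_internal = E - V + 1.
    """
    g = net.to_nx()
    if g.number_of_edges() == 0:
        raise EmptyNetworkError("cannot extract facets of an empty network")
    if not nx.is_connected(g):
        raise NetworkValidationError("facet extraction requires a connected network")
    if set(nx.bridges(g)):
        raise NetworkValidationError("facet extraction requires a pruned (bridgeless) network")

    walks = _face_walks(net)
    areas = [_signed_area(net, w) for w in walks]
    # outer face: negative orientation, largest magnitude
    outer = min(range(len(walks)), key=lambda i: (0 if areas[i] < 0 else 1, -abs(areas[i])))
    expected = net.n_edges - net.n_nodes + 1
    facets = []
    fid = 0
    for i, (walk, area) in enumerate(zip(walks, areas)):
        if i == outer:
            continue
        facets.append(
            Areole(
                facet_id=fid,
                boundary=tuple(h[2] for h in walk),
                area=abs(area),
                boundary_nodes=tuple(h[0] for h in walk),
            )
        )
        fid += 1
    if len(facets) != expected:
        raise EmbeddingError(
            f"face traversal found {len(facets)} internal faces, Euler's formula "
            f"requires {expected}; coordinates are not a valid planar embedding"
        )
    return facets


def outer_boundary_polygon(net: VeinNetwork) -> list[tuple[float, float]]:
    """Vertex list (cm) of the outer face walk, for leaf-area computation."""
    walks = _face_walks(net)
    areas = [_signed_area(net, w) for w in walks]
    outer = min(range(len(walks)), key=lambda i: (0 if areas[i] < 0 else 1, -abs(areas[i])))
    return [net.nodes[u] for u, _, _ in walks[outer]]


def edge_facet_map(net: VeinNetwork, facets: list[Areole]) -> dict[int, list[int]]:
    """Map edge_id -> facet ids bordering it (outer face omitted, so perimeter
    edges map to a single facet)."""
    m: dict[int, list[int]] = {eid: [] for eid in net.edges}
    for f in facets:
        for eid in f.boundary:
            m[eid].append(f.facet_id)
    return m
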