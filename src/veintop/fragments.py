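"""In-silico fragmentation of a network into fixed-size square tiles.

Each tile of the grid (anchored at the bounding-box lower-left, 1.2 cm by
default — the herbarium-fragment scale) receives the geometric clip of the
network: edges are cut at the tile border and the cut points become new
boundary nodes.  Loops opened by the cut are removed by re-pruning, so a
fragment's areoles are always whole.  Tiles with too few areoles to carry
meaningful nesting statistics are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, box

from .metrics import FRAGMENT_MAX_DEGREE, Fingerprint, fingerprint
from .network import EmptyNetworkError, VeinNetwork, build_network, extract_facets, prune_to_cycles

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fragment:
    tile_id: str
    x_range: tuple[float, float]  # cm
    y_range: tuple[float, float]  # cm
    network: VeinNetwork


@dataclass
class FragmentSet:
    tiles: list[Fragment]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.tiles)

    def fingerprints(self, max_degree: int = FRAGMENT_MAX_DEGREE, **kw) -> dict[str, Fingerprint]:
        return {f.tile_id: fingerprint(f.network, max_degree=max_degree, **kw) for f in self.tiles}


def _clip_to_tile(net: VeinNetwork, x0: float, y0: float, x1: float, y1: float) -> VeinNetwork | None:
    tile = box(x0, y0, x1, y1)
    node_key_to_id: dict[tuple[float, float], int] = {}
    node_rows: list[tuple[int, float, float]] = []

    def node_for(x: float, y: float) -> int:
        key = (round(x, 9), round(y, 9))
        if key not in node_key_to_id:
            nid = len(node_key_to_id)
            node_key_to_id[key] = nid
            node_rows.append((nid, x, y))
        return node_key_to_id[key]

    edge_rows = []
    eid_out = 0
    for eid in sorted(net.edges):
        e = net.edges[eid]
        pa, pb = net.nodes[e.node_a], net.nodes[e.node_b]
        seg = LineString([pa, pb])
        inter = seg.intersection(tile)
        if inter.is_empty or inter.geom_type != "LineString" or inter.length < 1e-9:
            continue  # outside, or a float-epsilon sliver along the border
        (cx0, cy0), (cx1, cy1) = inter.coords[0], inter.coords[-1]
        na, nb = node_for(cx0, cy0), node_for(cx1, cy1)
        if na == nb:
            continue
        frac = inter.length / seg.length
        edge_rows.append((eid_out, na, nb, e.width, e.length * frac))
        eid_out += 1
    if not edge_rows:
        return None
    return build_network(node_rows, edge_rows)


def fragment_network(
    net: VeinNetwork,
    tile_cm: float = 1.2,
    min_areoles: int = 10,
    offset_seed: int | None = None,
    provenance: str = "",
) -> FragmentSet:
    """Cut the network into tile_cm x tile_cm fragments and re-prune each.

    Tiles retaining fewer than ``min_areoles`` facets are dropped.  With
    ``offset_seed`` set, the grid origin is jittered uniformly within one
    tile (for robustness experiments); by default it sits at the bounding
    box lower-left corner.
    """
    xs = [x for x, _ in net.nodes.values()]
    ys = [y for _, y in net.nodes.values()]
    minx, maxx, miny, maxy = min(xs), max(xs), min(ys), max(ys)
    if (maxx - minx) < tile_cm and (maxy - miny) < tile_cm:
        # the whole network fits inside a single tile
        tiles_origin = (minx, miny)
        nx_t, ny_t = 1, 1
    else:
        ox, oy = minx, miny
        if offset_seed is not None:
            rng = np.random.default_rng(offset_seed)
            ox -= rng.random() * tile_cm
            oy -= rng.random() * tile_cm
        tiles_origin = (ox, oy)
        nx_t = max(1, math.ceil((maxx - tiles_origin[0]) / tile_cm - 1e-12))
        ny_t = max(1, math.ceil((maxy - tiles_origin[1]) / tile_cm - 1e-12))

    fragments: list[Fragment] = []
    for i in range(nx_t):
        for j in range(ny_t):
            x0 = tiles_origin[0] + i * tile_cm
            y0 = tiles_origin[1] + j * tile_cm
            clipped = _clip_to_tile(net, x0, y0, x0 + tile_cm, y0 + tile_cm)
            if clipped is None:
                continue
            try:
                pruned = prune_to_cycles(clipped)
                n_facets = len(extract_facets(pruned))
            except EmptyNetworkError:
                continue
            if n_facets < min_areoles:
                continue
            fragments.append(
                Fragment(
                    tile_id=f"{provenance}t{i}_{j}" if provenance else f"t{i}_{j}",
                    x_range=(x0, x0 + tile_cm),
                    y_range=(y0, y0 + tile_cm),
                    network=pruned,
                )
            )
    if not fragments:
        logger.warning("no tile retained >= %d areoles; empty fragment set", min_areoles)
    return FragmentSet(tiles=fragments, provenance=provenance)
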