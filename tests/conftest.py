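"""Shared fixtures: small hand-checkable networks, random loopy networks,
and an independent brute-force facet-merging oracle for the decomposition."""

from __future__ import annotations

import numpy as np
import pytest

from veintop.fixtures import make_grid, with_widths
from veintop.network import VeinNetwork, build_network, extract_facets, prune_to_cycles


@pytest.fixture
def unit_square() -> VeinNetwork:
    nodes = [(0, 0.0, 0.0), (1, 1.0, 0.0), (2, 1.0, 1.0), (3, 0.0, 1.0)]
    edges = [(0, 0, 1, 0.1, None), (1, 1, 2, 0.1, None), (2, 2, 3, 0.1, None), (3, 3, 0, 0.1, None)]
    return build_network(nodes, edges)


def random_loopy_network(rng: np.random.Generator, max_facets: int = 6) -> VeinNetwork:
    """Random grid-based network with <= max_facets faces and distinct random
    widths; occasionally an interior edge is dropped to create a non-grid
    face structure."""
    shapes = [(1, 2), (1, 3), (1, 4), (1, 5), (1, 6), (2, 2), (2, 3)]
    shapes = [s for s in shapes if s[0] * s[1] <= max_facets]
    r, c = shapes[rng.integers(len(shapes))]
    net = make_grid(r, c)
    eids = sorted(net.edges)
    if rng.random() < 0.4 and r * c > 2:
        # drop one random edge and re-prune: merged faces, dangling bits removed
        drop = eids[rng.integers(len(eids))]
        edges = {e: net.edges[e] for e in eids if e != drop}
        net = prune_to_cycles(VeinNetwork(dict(net.nodes), edges))
        eids = sorted(net.edges)
    widths = rng.permutation(len(eids)) + 1.0
    return with_widths(net, dict(zip(eids, widths)))


def oracle_nesting_clades(net: VeinNetwork) -> set[frozenset[int]]:
    """Literal facet-merging simulation, independent of the package's
    union-find/heapless implementation: every round, rescan all edges for the
    thinnest one whose two sides carry different facet labels, merge the two
    label groups, and record the merged clade."""
    facets = extract_facets(net)
    sides: dict[int, list[int]] = {}
    for f in facets:
        for eid in f.boundary:
            sides.setdefault(eid, []).append(f.facet_id)
    label = {f.facet_id: f.facet_id for f in facets}
    members = {f.facet_id: {f.facet_id} for f in facets}
    clades: set[frozenset[int]] = set()
    while len(members) > 1:
        best = None
        for eid in sorted(net.edges):
            fs = sides.get(eid, [])
            if len(fs) != 2:
                continue
            la, lb = label[fs[0]], label[fs[1]]
            if la == lb:
                continue
            key = (net.edges[eid].width, eid)
            if best is None or key < best[0]:
                best = (key, la, lb)
        if best is None:
            break
        _, la, lb = best
        merged = members[la] | members[lb]
        clades.add(frozenset(merged))
        for fid in members[lb]:
            label[fid] = la
        members[la] = merged
        del members[lb]
    return clades


def tree_clades(tree) -> set[frozenset[int]]:
    return tree.clades()
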