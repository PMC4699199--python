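"""Hierarchical loop decomposition of a pruned network into a nesting tree.

Each areole starts as a leaf.  Repeatedly, the pair of current facets whose
shared boundary is thinnest is merged: the globally thinnest edge separating
two distinct facets selects the pair, the whole shared boundary between the
pair is removed, and a new internal tree node becomes the parent of the two
facets' representatives.  Iteration ends when a single facet — the whole
blade — remains; it is the root.  Internal node j records the leaf counts
r_j >= s_j of its two subtrees, the nesting ratio q_j = s_j / r_j, and the
subtree degree d_j = r_j + s_j.

The tree depends only on the *rank order* of edge widths and on the face
adjacency structure: monotone width transforms and junction-preserving
geometric deformations leave it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import Areole, EmptyNetworkError, VeinNetwork, extract_facets


@dataclass
class TreeNode:
    node_id: int
    facet_id: int | None = None  # set for leaves
    children: tuple[int, int] | None = None  # set for internal nodes
    n_leaves: int = 1
    r: int | None = None
    s: int | None = None
    q: float | None = None
    d: int | None = None
    merge_width: float | None = None


@dataclass
class NestingTree:
    """Strictly binary tree over areoles; internal nodes carry (r, s, q, d)."""

    nodes: dict[int, TreeNode]
    root: int | None
    merge_order: list[int] = field(default_factory=list)  # internal node ids, in merge order

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes.values() if n.children is None)

    @property
    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.children is not None]

    def leaf_facets(self, node_id: int) -> frozenset[int]:
        """Facet ids under a node — the clade it represents."""
        node = self.nodes[node_id]
        if node.children is None:
            return frozenset({node.facet_id})
        a, b = node.children
        return self.leaf_facets(a) | self.leaf_facets(b)

    def clades(self) -> set[frozenset[int]]:
        """Facet-id sets of all internal nodes; two strictly binary trees over
        the same leaves are equal iff their clade sets are equal."""
        out: set[frozenset[int]] = set()
        for n in self.internal_nodes:
            out.add(self.leaf_facets(n.node_id))
        return out


def _pair_key(edges: list[tuple[float, int]], pair_weight: str) -> tuple[float, int]:
    """Selection key of a facet pair from its separating edges (width, edge_id)."""
    if pair_weight == "min":
        return min(edges)
    widths = [w for w, _ in edges]
    tie = min(e for _, e in edges)
    if pair_weight == "mean":
        return (sum(widths) / len(widths), tie)
    if pair_weight == "max":
        return (max(widths), tie)
    raise ValueError(f"unknown pair_weight {pair_weight!r}")


def build_nesting_tree(
    net: VeinNetwork,
    facets: list[Areole] | None = None,
    pair_weight: str = "min",
) -> NestingTree:
    """Decompose a pruned connected network into its nesting tree.

    ``pair_weight`` controls how a multi-edge shared boundary is scored when
    selecting the next merge (min is the default: the single thinnest
    separating edge picks the pair).  Ties break on the smaller edge id, so
    the result is deterministic without randomness.
    """
    if facets is None:
        facets = extract_facets(net)
    if not facets:
        raise EmptyNetworkError("cannot decompose a network with zero facets")

    # union-find over facet ids
    parent = {f.facet_id: f.facet_id for f in facets}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # edges separating two internal facets, grouped by facet pair
    borders: dict[int, list[int]] = {}
    for f in facets:
        for eid in f.boundary:
            borders.setdefault(eid, []).append(f.facet_id)
    pair_edges: dict[frozenset[int], list[tuple[float, int]]] = {}
    for eid, fs in borders.items():
        if len(fs) == 2 and fs[0] != fs[1]:
            pair_edges.setdefault(frozenset(fs), []).append((net.edges[eid].width, eid))

    tree_nodes: dict[int, TreeNode] = {}
    rep: dict[int, int] = {}  # facet root -> tree node id
    for f in facets:
        tree_nodes[f.facet_id] = TreeNode(node_id=f.facet_id, facet_id=f.facet_id)
        rep[f.facet_id] = f.facet_id
    next_id = max(tree_nodes) + 1 if tree_nodes else 0
    merge_order: list[int] = []

    while len(pair_edges) > 0:
        pair, key = None, None
        for p, eds in pair_edges.items():
            k = _pair_key(eds, pair_weight)
            if key is None or k < key:
                pair, key = p, k
        fa, fb = sorted(pair)
        ra, rb = find(fa), find(fb)
        assert ra != rb
        ta, tb = tree_nodes[rep[ra]], tree_nodes[rep[rb]]
        r, s = max(ta.n_leaves, tb.n_leaves), min(ta.n_leaves, tb.n_leaves)
        node = TreeNode(
            node_id=next_id,
            children=(rep[ra], rep[rb]) if ta.n_leaves >= tb.n_leaves else (rep[rb], rep[ra]),
            n_leaves=r + s,
            r=r,
            s=s,
            q=s / r,
            d=r + s,
            merge_width=key[0],
        )
        tree_nodes[next_id] = node
        merge_order.append(next_id)
        parent[rb] = ra
        root = find(ra)
        rep[root] = next_id
        next_id += 1
        # relabel pairs under the merged facet; drop now-internal boundaries
        new_pairs: dict[frozenset[int], list[tuple[float, int]]] = {}
        for p, eds in pair_edges.items():
            canon = frozenset(find(x) for x in p)
            if len(canon) == 1:
                continue  # edges now interior to one facet: separate nothing
            new_pairs.setdefault(canon, []).extend(eds)
        pair_edges = new_pairs

    roots = {find(f.facet_id) for f in facets}
    if len(roots) != 1:
        # facets can only all merge if the dual graph is connected; a pruned
        # connected planar network guarantees that
        raise EmptyNetworkError(f"decomposition left {len(roots)} unmerged facet groups")
    root_node = rep[roots.pop()]
    return NestingTree(nodes=tree_nodes, root=root_node, merge_order=merge_order)


def write_newick(tree: NestingTree, path: str) -> None:
    """Serialize the nesting tree as Newick with ``q=<val>|d=<val>`` internal
    labels; child order is deterministic (larger subtree first, ties by the
    smallest facet id underneath)."""

    def render(node_id: int) -> str:
        node = tree.nodes[node_id]
        if node.children is None:
            return f"F{node.facet_id}"
        a, b = node.children
        ka = (-tree.nodes[a].n_leaves, min(tree.leaf_facets(a)))
        kb = (-tree.nodes[b].n_leaves, min(tree.leaf_facets(b)))
        if kb < ka:
            a, b = b, a
        return f"({render(a)},{render(b)})q={node.q:g}|d={node.d}"

    text = (render(tree.root) + ";\n") if tree.root is not None else ";\n"
    with open(path, "w") as fh:
        fh.write(text)
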