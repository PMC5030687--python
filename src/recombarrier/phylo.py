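"""Trees: neighbor joining, Fitch parsimony, parsimony search, bootstrap.

Trees are carried as :class:`dendropy.Tree` objects throughout the package.
The inference kernels (neighbor joining with negative-length redistribution,
the vectorised Fitch small-parsimony scorer, stepwise-addition + NNI search)
are implemented here on a lightweight adjacency representation and converted
to dendropy at the boundary.

Parsimony uses unordered (Fitch) states: the cost of any state change is 1,
which is the natural model for gene presence/absence/multicopy characters
and for SNP columns alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CharacterMatrix",
    "neighbor_joining",
    "fitch_length",
    "fitch_lengths",
    "parsimony_tree",
    "bootstrap_support",
    "collapse_low_support",
    "read_newick",
    "write_newick",
    "patristic_distances",
    "path_edges",
]


# ---------------------------------------------------------------------------
# Character matrices


@dataclass
class CharacterMatrix:
    """Taxa x characters matrix of unordered discrete states.

    States are small non-negative integers (for gene content:
    0 = absent, 1 = single-copy, 2 = multicopy).
    """

    taxa: list[str]
    data: np.ndarray
    characters: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxa")
        if self.data.size and self.data.min() < 0:
            raise ValueError("states must be non-negative integers")
        if self.characters is None:
            self.characters = [f"c{i}" for i in range(self.data.shape[1])]

    @property
    def n_characters(self) -> int:
        return self.data.shape[1]

    def masks(self) -> np.ndarray:
        """Per-taxon bitmask vectors over characters (uint64)."""
        if self.data.size and self.data.max() > 62:
            raise ValueError("more than 63 distinct states not supported")
        return (np.uint64(1) << self.data.astype(np.uint64)).astype(np.uint64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.taxa, columns=self.characters)

    @classmethod
    def from_tsv(cls, path) -> "CharacterMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), list(df.columns))


# ---------------------------------------------------------------------------
# Adjacency representation and conversion


class _Unrooted:
    """Unrooted tree: leaves 0..n-1 fixed, internal nodes allocated above."""

    def __init__(self, n_leaves: int):
        self.n_leaves = n_leaves
        self.adj: dict[int, set[int]] = {}
        self.next_node = n_leaves

    def add_edge(self, u: int, v: int) -> None:
        self.adj.setdefault(u, set()).add(v)
        self.adj.setdefault(v, set()).add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)

    def new_internal(self) -> int:
        node = self.next_node
        self.next_node += 1
        return node

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v)) for u in self.adj for v in self.adj[u] if u < v
        )

    def postorder(self, root_edge: tuple[int, int]) -> list[tuple[int, int]]:
        """(node, parent) pairs, children before parents, rooted on an edge.

        A virtual root of degree 2 sits on ``root_edge``; the traversal
        yields every real node with its parent (-1 for the two subroots).
        """
        a, b = root_edge
        order: list[tuple[int, int]] = []
        stack = [(a, b), (b, a)]
        seen = set()
        while stack:
            node, parent = stack.pop()
            if (node, parent) in seen:  # pragma: no cover - defensive
                continue
            seen.add((node, parent))
            order.append((node, parent))
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        order.reverse()
        return order


def _score_topology(tree: _Unrooted, leaf_masks: np.ndarray) -> int:
    """Total Fitch length over all characters for one unrooted topology.

    ``leaf_masks`` is (n_leaves, n_chars) uint64 of state bitmasks.
    """
    n_chars = leaf_masks.shape[1]
    root_edge = tree.edges()[0]
    sets: dict[int, np.ndarray] = {}
    changes = np.zeros(n_chars, dtype=np.int64)
    for node, parent in tree.postorder(root_edge):
        children = [c for c in tree.adj[node] if c != parent]
        if not children:
            sets[node] = leaf_masks[node]
            continue
        acc = sets[children[0]]
        for c in children[1:]:
            inter = acc & sets[c]
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | sets[c], inter)
        sets[node] = acc
    a, b = root_edge
    changes += (sets[a] & sets[b]) == 0
    return int(changes.sum())


def _to_dendropy(
    tree: _Unrooted,
    taxa: Sequence[str],
    taxon_namespace: dendropy.TaxonNamespace | None = None,
    edge_length: float = 1.0,
) -> dendropy.Tree:
    ns = taxon_namespace or dendropy.TaxonNamespace(list(taxa))
    dtree = dendropy.Tree(taxon_namespace=ns)
    root_edge = tree.edges()[0]
    a, b = root_edge
    nodes: dict[int, dendropy.Node] = {}

    def make(node: int) -> dendropy.Node:
        dn = dendropy.Node()
        if node < tree.n_leaves:
            dn.taxon = ns.get_taxon(taxa[node])
        dn.edge.length = edge_length
        nodes[node] = dn
        return dn

    order = tree.postorder(root_edge)
    for node, parent in order:
        make(node)
    for node, parent in reversed(order):  # parents before children
        if (node, parent) in ((a, b), (b, a)):
            dtree.seed_node.add_child(nodes[node])
        else:
            nodes[parent].add_child(nodes[node])
    dtree.seed_node.edge.length = None
    dtree.is_rooted = False
    return dtree


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(d) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a :class:`~.variants.DistanceMatrix`.

    Exactly recovers additive trees. Negative branch-length estimates are
    clamped to zero with the deficit moved onto the sibling branch, so the
    joined pair's path length is conserved.
    """
    names = list(d.names)
    n = len(names)
    if n < 2:
        raise ValueError("need >=2 taxa")
    dist = np.array(d.values, dtype=float)
    if not np.isfinite(dist).all():
        raise ValueError("undefined (NaN/inf) distances")
    ns = dendropy.TaxonNamespace(names)
    nodes: list[dendropy.Node] = []
    for name in names:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(name)
        nodes.append(node)
    if n == 2:
        tree = dendropy.Tree(taxon_namespace=ns)
        half = dist[0, 1] / 2
        for node in nodes:
            node.edge.length = half
            tree.seed_node.add_child(node)
        tree.is_rooted = False
        return tree

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = dist[i, j]
        li = 0.5 * dij + (totals[i_loc] - totals[j_loc]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, conserving li + lj onto the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_idx = dist.shape[0]
        new_row = 0.5 * (dist[i] + dist[j] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[new_idx, : new_idx] = new_row
        dist[: new_idx, new_idx] = new_row
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    lengths = [max(x, 0.0) for x in (li, lj, lk)]
    tree = dendropy.Tree(taxon_namespace=ns)
    for idx, length in zip((i, j, k), lengths):
        nodes[idx].edge.length = length
        tree.seed_node.add_child(nodes[idx])
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Fitch parsimony


def _leaf_adjacency(tree: dendropy.Tree, taxa: list[str]) -> _Unrooted:
    """Convert a dendropy tree into the internal adjacency representation,
    suppressing the root if it has degree 2."""
    index = {name: i for i, name in enumerate(taxa)}
    ut = _Unrooted(len(taxa))
    ids: dict[int, int] = {}

    def node_id(dn: dendropy.Node) -> int:
        key = id(dn)
        if key not in ids:
            if dn.taxon is not None:
                ids[key] = index[dn.taxon.label]
            else:
                ids[key] = ut.new_internal()
        return ids[key]

    for dn in tree.preorder_node_iter():
        for child in dn.child_nodes():
            ut.add_edge(node_id(dn), node_id(child))
    root = node_id(tree.seed_node)
    if len(ut.adj[root]) == 2 and root >= len(taxa):
        a, b = sorted(ut.adj[root])
        ut.remove_edge(root, a)
        ut.remove_edge(root, b)
        ut.add_edge(a, b)
        del ut.adj[root]
    return ut


def fitch_lengths(tree: dendropy.Tree, matrix: CharacterMatrix) -> np.ndarray:
    """Per-character minimal change counts (Fitch) on a fixed tree."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [t for t in matrix.taxa if t not in leaves]
    if missing:
        raise KeyError(f"taxa missing from tree: {missing}")
    if set(leaves) != set(matrix.taxa):
        raise KeyError("tree has leaves without character states")
    ut = _leaf_adjacency(tree, matrix.taxa)
    masks = matrix.masks()
    n_chars = masks.shape[1]
    root_edge = ut.edges()[0]
    sets: dict[int, np.ndarray] = {}
    changes = np.zeros(n_chars, dtype=np.int64)
    for node, parent in ut.postorder(root_edge):
        children = [c for c in ut.adj[node] if c != parent]
        if not children:
            sets[node] = masks[node]
            continue
        acc = sets[children[0]]
        for c in children[1:]:
            inter = acc & sets[c]
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | sets[c], inter)
        sets[node] = acc
    a, b = root_edge
    changes += (sets[a] & sets[b]) == 0
    return changes


def fitch_length(tree: dendropy.Tree, character: Mapping[str, int]) -> int:
    """Minimal number of unordered state changes for one character."""
    taxa = sorted(character)
    states = sorted(set(character.values()))
    recode = {s: i for i, s in enumerate(states)}
    data = np.array([[recode[character[t]]] for t in taxa])
    return int(fitch_lengths(tree, CharacterMatrix(taxa, data))[0])


# ---------------------------------------------------------------------------
# Parsimony tree search: stepwise addition + NNI


def parsimony_tree(matrix: CharacterMatrix, addition_order: list[int] | None = None
                   ) -> dendropy.Tree:
    """Heuristic maximum-parsimony tree for unordered characters.

    Taxa are added stepwise (input order by default) at the placement
    minimising total Fitch length, then nearest-neighbor-interchange hill
    climbing runs to a local optimum. Ties go to the first candidate in a
    fixed edge ordering, so the result is deterministic for a given input.
    """
    n = len(matrix.taxa)
    if n < 4:
        raise ValueError("need >=4 taxa for a meaningful parsimony search")
    per_char_states = (matrix.data.max(axis=0) != matrix.data.min(axis=0))
    if not per_char_states.any():
        raise ValueError("all characters constant: tree is unresolved (star)")
    masks = matrix.masks()
    order = addition_order if addition_order is not None else list(range(n))

    ut = _Unrooted(n)
    center = ut.new_internal()
    for leaf in order[:3]:
        ut.add_edge(leaf, center)

    for leaf in order[3:]:
        best = None
        for u, v in ut.edges():
            mid = ut.new_internal()
            ut.remove_edge(u, v)
            ut.add_edge(u, mid)
            ut.add_edge(mid, v)
            ut.add_edge(leaf, mid)
            score = _score_topology(ut, masks)
            if best is None or score < best[0]:
                best = (score, (u, v))
            ut.remove_edge(leaf, mid)
            ut.remove_edge(u, mid)
            ut.remove_edge(mid, v)
            del ut.adj[mid], ut.adj[leaf]
            ut.next_node -= 1
            ut.add_edge(u, v)
        u, v = best[1]
        mid = ut.new_internal()
        ut.remove_edge(u, v)
        ut.add_edge(u, mid)
        ut.add_edge(mid, v)
        ut.add_edge(leaf, mid)

    # NNI hill climbing
    current = _score_topology(ut, masks)
    improved = True
    while improved:
        improved = False
        for u, v in ut.edges():
            if u < n or v < n:
                continue  # external edge
            u_nb = sorted(x for x in ut.adj[u] if x != v)
            v_nb = sorted(x for x in ut.adj[v] if x != u)
            a = u_nb[0]
            for c in v_nb:
                ut.remove_edge(u, a)
                ut.remove_edge(v, c)
                ut.add_edge(u, c)
                ut.add_edge(v, a)
                score = _score_topology(ut, masks)
                if score < current:
                    current = score
                    improved = True
                else:
                    ut.remove_edge(u, c)
                    ut.remove_edge(v, a)
                    ut.add_edge(u, a)
                    ut.add_edge(v, c)
            if improved:
                break
    tree = _to_dendropy(ut, matrix.taxa)
    tree.parsimony_length = current
    return tree


def total_fitch_length(tree: dendropy.Tree, matrix: CharacterMatrix) -> int:
    return int(fitch_lengths(tree, matrix).sum())


# ---------------------------------------------------------------------------
# Bootstrap support


def _bipartitions(tree: dendropy.Tree, taxa: list[str]) -> dict[frozenset, dendropy.Node]:
    """Non-trivial splits of an unrooted tree keyed by the side not
    containing the first taxon (canonical orientation)."""
    all_taxa = frozenset(taxa)
    anchor = taxa[0]
    splits: dict[frozenset, dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = all_taxa - side
        if 1 < len(side) < len(taxa) - 1:
            splits.setdefault(side, node)
    return splits


def bootstrap_support(
    matrix: CharacterMatrix,
    builder: Callable[[CharacterMatrix], dendropy.Tree] = parsimony_tree,
    B: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """Point-estimate tree with bootstrap support on internal branches.

    Characters are resampled with replacement B times; support for each
    internal bipartition of the point tree is the percentage of replicate
    trees containing that bipartition, stored as the internal node label.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    point = builder(matrix)
    taxa = list(matrix.taxa)
    splits = _bipartitions(point, taxa)
    counts = {s: 0 for s in splits}
    n_chars = matrix.n_characters
    for _ in range(B):
        cols = rng.integers(0, n_chars, size=n_chars)
        rep = CharacterMatrix(
            taxa, matrix.data[:, cols], [matrix.characters[c] for c in cols]
        )
        rep_splits = _bipartitions(builder(rep), taxa)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for split, node in splits.items():
        node.label = str(round(100.0 * counts[split] / B))
    return point


def collapse_low_support(tree: dendropy.Tree, threshold: float = 50.0) -> dendropy.Tree:
    """Collapse internal branches whose support label is below *threshold*."""
    clone = tree.clone(depth=1)
    to_collapse = []
    for node in clone.postorder_internal_node_iter():
        if node.parent_node is None or node.label is None:
            continue
        if float(node.label) < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return clone


# ---------------------------------------------------------------------------
# Newick I/O and tree utilities


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def patristic_distances(tree: dendropy.Tree):
    """(names, matrix) of leaf-to-leaf path lengths."""
    pdm = tree.phylogenetic_distance_matrix()
    names = sorted(t.label for t in tree.taxon_namespace)
    mat = np.zeros((len(names), len(names)))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[a], taxa[names[j]])
    return names, mat


def path_edges(tree: dendropy.Tree, a: str, b: str) -> set[int]:
    """Edge identity set on the leaf-to-leaf path (for edge-disjointness)."""
    nodes = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if a not in nodes or b not in nodes:
        raise KeyError(f"leaf not in tree: {a if a not in nodes else b}")

    def ancestors(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent_node
        return out

    pa, pb = ancestors(nodes[a]), ancestors(nodes[b])
    sa = {id(n) for n in pa}
    mrca = next(n for n in pb if id(n) in sa)
    edges = set()
    for start in (nodes[a], nodes[b]):
        n = start
        while id(n) != id(mrca):
            edges.add(id(n.edge))
            n = n.parent_node
    return edges
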