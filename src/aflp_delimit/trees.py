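"""Unrooted-tree utilities for parsimony analysis.

Trees are held as adjacency maps over integer node ids; leaves are
0..n-1 and map positionally onto a taxon-label list. Tree length is the
Fitch count of unordered state changes (computed by the classic two-set
recursion on binary trees, and by unit-cost Sankoff dynamic programming on
multifurcating ones — the two agree on binary trees). Character columns are
encoded as per-leaf bitmasks over a padded 4-letter state universe; missing
observations carry the full mask and therefore never force a change.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "UnrootedTree",
    "tree_from_newick",
    "enumerate_topologies",
    "tree_length",
    "branch_and_bound_search",
    "heuristic_search",
    "nni_neighbors",
    "strict_consensus",
    "tree_from_splits",
    "collapse_zero_length_edges",
    "random_addition_tree",
]

_BIG = np.int32(1 << 20)
FULL_MASK = np.uint8(0b1111)


@dataclass
class UnrootedTree:
    """Unrooted (possibly multifurcating) tree over a fixed taxon list."""

    taxa: list[str]
    adj: dict[int, list[int]]

    @property
    def n(self) -> int:
        return len(self.taxa)

    def copy(self) -> "UnrootedTree":
        return UnrootedTree(list(self.taxa), {u: list(vs) for u, vs in self.adj.items()})

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, vs in self.adj.items() for v in vs if u < v]

    def internal_edges(self) -> list[tuple[int, int]]:
        n = self.n
        return [(u, v) for u, v in self.edges() if u >= n and v >= n]

    def postorder(self, root: int | None = None) -> list[tuple[int, int]]:
        """(node, parent) pairs, children before parents; parent of root is -1."""
        if root is None:
            root = self.adj[0][0] if self.adj[0] else 0
        order: list[tuple[int, int]] = []
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        order.reverse()
        return order

    def splits(self, nontrivial_only: bool = True) -> set[frozenset]:
        """Splits as frozensets of taxon labels, canonical side = the side not
        containing the lexicographically smallest label."""
        ref = min(self.taxa)
        out: set[frozenset] = set()
        below: dict[int, set[int]] = {}
        root = self.adj[0][0] if self.adj[0] else 0
        for node, parent in self.postorder(root):
            leaves = {node} if node < self.n else set()
            for nb in self.adj[node]:
                if nb != parent:
                    leaves |= below[nb]
            below[node] = leaves
            if parent != -1:
                side = {self.taxa[i] for i in leaves}
                if ref in side:
                    side = set(self.taxa) - side
                if nontrivial_only and not 1 < len(side) < self.n - 1:
                    continue
                if 0 < len(side) < self.n:
                    out.add(frozenset(side))
        return out

    def to_newick(
        self,
        lengths: dict[frozenset, float] | None = None,
        support: dict[frozenset, float] | None = None,
    ) -> str:
        """Newick string rooted at an internal node adjacent to the first leaf.

        ``lengths`` and ``support`` are optional maps from canonical split
        (as returned by :meth:`splits`) to branch length / support percent;
        supports are written as comments after the subtending branch.
        """
        ref = min(self.taxa)
        all_taxa = set(self.taxa)

        def annot(leaves_below: set[int], leaf_edge: bool) -> str:
            side = {self.taxa[i] for i in leaves_below}
            key = frozenset(all_taxa - side if ref in side else side)
            s = ""
            if lengths is not None:
                s += f":{lengths.get(key, 0.0):.6g}"
            if support is not None and not leaf_edge and key in support:
                s += f"[{support[key]:.0f}]"
            return s

        below: dict[int, set[int]] = {}
        root = self.adj[0][0] if self.adj[0] else 0

        def render(node: int, parent: int) -> str:
            if node < self.n:
                below[node] = {node}
                return self.taxa[node] + annot({node}, True)
            parts = [render(nb, node) for nb in self.adj[node] if nb != parent]
            leaves = set().union(*(below[nb] for nb in self.adj[node] if nb != parent))
            below[node] = leaves
            s = "(" + ",".join(parts) + ")"
            if parent != -1:
                s += annot(leaves, len(leaves) <= 1)
            return s

        parts = [render(nb, root) for nb in self.adj[root]]
        return "(" + ",".join(parts) + ");"


def tree_from_newick(newick: str, taxa: list[str] | None = None) -> UnrootedTree:
    """Parse a newick string (via dendropy) into an UnrootedTree.

    ``taxa`` fixes the leaf-id order; by default labels are sorted.
    """
    dt = dendropy.Tree.get(data=newick, schema="newick")
    labels = [lf.taxon.label for lf in dt.leaf_node_iter()]
    if taxa is None:
        taxa = sorted(labels)
    if set(labels) != set(taxa):
        raise ValueError("newick taxa do not match the expected taxon set")
    index = {lab: i for i, lab in enumerate(taxa)}
    adj: dict[int, list[int]] = {i: [] for i in range(len(taxa))}
    next_id = len(taxa)
    node_id: dict = {}

    def get_id(nd) -> int:
        nonlocal next_id
        if nd in node_id:
            return node_id[nd]
        if nd.is_leaf():
            node_id[nd] = index[nd.taxon.label]
        else:
            node_id[nd] = next_id
            adj[next_id] = []
            next_id += 1
        return node_id[nd]

    for nd in dt.preorder_node_iter():
        for ch in nd.child_nodes():
            u, v = get_id(nd), get_id(ch)
            adj[u].append(v)
            adj[v].append(u)
    tree = UnrootedTree(taxa, adj)
    _suppress_degree_two(tree)
    return tree


def _suppress_degree_two(tree: UnrootedTree) -> None:
    """Remove internal nodes of degree 2 (artifacts of rooted parses)."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.adj):
            if node >= tree.n and len(tree.adj[node]) == 2:
                a, b = tree.adj[node]
                tree.adj[a] = [x if x != node else b for x in tree.adj[a]]
                tree.adj[b] = [x if x != node else a for x in tree.adj[b]]
                del tree.adj[node]
                changed = True


# ---------------------------------------------------------------------------
# tree length
# ---------------------------------------------------------------------------


def _fitch_binary(tree: UnrootedTree, masks: np.ndarray, weights: np.ndarray) -> int:
    """Fitch count on a binary (or partially built) tree.

    masks: (n_leaves, n_cols) uint8 per-leaf state sets; weights: per-column
    multiplicities (bootstrap resampling reuses columns).
    """
    n_cols = masks.shape[1]
    node_set: dict[int, np.ndarray] = {}
    changes = np.zeros(n_cols, dtype=np.int64)
    for node, parent in tree.postorder():
        if node < tree.n:
            node_set[node] = masks[node]
            continue
        children = [nb for nb in tree.adj[node] if nb != parent]
        acc = node_set[children[0]]
        for ch in children[1:]:
            inter = acc & node_set[ch]
            union = acc | node_set[ch]
            empty = inter == 0
            changes += empty * 1
            acc = np.where(empty, union, inter)
        node_set[node] = acc
    return int((changes * weights).sum())


def _sankoff(tree: UnrootedTree, masks: np.ndarray, weights: np.ndarray) -> int:
    """Unit-cost Sankoff DP; exact on multifurcating trees."""
    n_cols = masks.shape[1]
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    leaf_cost = {
        i: np.where((masks[i][:, None] & bits[None, :]) != 0, 0, _BIG).astype(np.int32)
        for i in range(tree.n)
    }
    cost: dict[int, np.ndarray] = {}
    root = tree.adj[0][0] if tree.adj[0] else 0
    for node, parent in tree.postorder(root):
        if node < tree.n:
            cost[node] = leaf_cost[node]
            continue
        acc = np.zeros((n_cols, 4), dtype=np.int32)
        for ch in (nb for nb in tree.adj[node] if nb != parent):
            c = cost[ch]
            m = c.min(axis=1)
            acc = acc + np.minimum(c, m[:, None] + 1)
        cost[node] = acc
    # close the root edge to leaf `root`'s parentless position: root is an
    # internal node adjacent to leaf 0; include leaf 0 via postorder already.
    total = cost[root].min(axis=1)
    return int((total * weights).sum())


def _is_binary(tree: UnrootedTree) -> bool:
    return all(
        (len(vs) == 1) if u < tree.n else (len(vs) == 3) for u, vs in tree.adj.items()
    )


def tree_length(
    tree: UnrootedTree, masks: np.ndarray, weights: np.ndarray | None = None
) -> int:
    """Parsimony length: minimal total unordered state changes over all columns."""
    if weights is None:
        weights = np.ones(masks.shape[1], dtype=np.int64)
    if masks.shape[1] == 0:
        return 0
    if _is_binary(tree):
        return _fitch_binary(tree, masks, weights)
    return _sankoff(tree, masks, weights)


# ---------------------------------------------------------------------------
# topology enumeration / stepwise addition
# ---------------------------------------------------------------------------


def _three_taxon_tree(taxa: list[str]) -> UnrootedTree:
    n = len(taxa)
    center = n
    adj = {i: [] for i in range(n)}
    adj[center] = [0, 1, 2]
    for leaf in (0, 1, 2):
        adj[leaf] = [center]
    return UnrootedTree(list(taxa), adj)


def _insert_leaf(tree: UnrootedTree, leaf: int, edge: tuple[int, int], new_internal: int):
    u, v = edge
    tree.adj[u] = [x if x != v else new_internal for x in tree.adj[u]]
    tree.adj[v] = [x if x != u else new_internal for x in tree.adj[v]]
    tree.adj[new_internal] = [u, v, leaf]
    tree.adj[leaf] = [new_internal]


def _remove_leaf(tree: UnrootedTree, leaf: int, edge: tuple[int, int], internal: int):
    u, v = edge
    tree.adj[u] = [x if x != internal else v for x in tree.adj[u]]
    tree.adj[v] = [x if x != internal else u for x in tree.adj[v]]
    del tree.adj[internal]
    del tree.adj[leaf]


def enumerate_topologies(taxa: list[str]):
    """Yield every unrooted binary topology on the taxa ((2n-5)!! of them)."""
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    tree = _three_taxon_tree(taxa)

    def recurse(k: int):
        if k == n:
            yield tree.copy()
            return
        for edge in tree.edges():
            new_internal = n + k - 2
            _insert_leaf(tree, k, edge, new_internal)
            yield from recurse(k + 1)
            _remove_leaf(tree, k, edge, new_internal)

    yield from recurse(3)


def random_addition_tree(
    taxa: list[str], masks: np.ndarray, rng: random.Random
) -> UnrootedTree:
    """Greedy stepwise addition in a random taxon order (ties: first edge)."""
    n = len(taxa)
    order = list(range(n))
    rng.shuffle(order)
    # build over permuted taxa then relabel back
    perm_taxa = [taxa[i] for i in order]
    perm_masks = masks[order]
    tree = _three_taxon_tree(perm_taxa)
    for k in range(3, n):
        best_len = None
        best_edge = None
        for edge in tree.edges():
            new_internal = n + k - 2
            _insert_leaf(tree, k, edge, new_internal)
            ln = tree_length(tree, perm_masks)
            _remove_leaf(tree, k, edge, new_internal)
            if best_len is None or ln < best_len:
                best_len = ln
                best_edge = edge
        _insert_leaf(tree, k, best_edge, n + k - 2)
    # relabel leaf ids back to canonical taxon order
    mapping = {k: order[k] for k in range(n)}
    adj = {
        mapping.get(u, u): [mapping.get(v, v) for v in vs] for u, vs in tree.adj.items()
    }
    return UnrootedTree(list(taxa), adj)


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------


def branch_and_bound_search(
    taxa: list[str], masks: np.ndarray, weights: np.ndarray | None = None
) -> tuple[list[UnrootedTree], int]:
    """All minimum-length topologies, by stepwise-addition branch and bound.

    The parsimony length of a partial (induced) tree never exceeds that of
    any completion, so partial trees longer than the incumbent are pruned.
    Feasible to ~12 taxa.
    """
    n = len(taxa)
    if n < 4:
        t = _three_taxon_tree(taxa) if n == 3 else None
        if t is None:
            raise ValueError("need at least 3 taxa")
        return [t], tree_length(t, masks, weights)
    if weights is None:
        weights = np.ones(masks.shape[1], dtype=np.int64)

    # initial upper bound from one greedy addition
    seed_tree = random_addition_tree(taxa, masks, random.Random(0))
    best_len = tree_length(seed_tree, masks, weights)
    best_trees: list[UnrootedTree] = []
    tree = _three_taxon_tree(taxa)

    def recurse(k: int):
        nonlocal best_len, best_trees
        if k == n:
            ln = tree_length(tree, masks, weights)
            if ln < best_len:
                best_len = ln
                best_trees = [tree.copy()]
            elif ln == best_len:
                best_trees.append(tree.copy())
            return
        for edge in tree.edges():
            new_internal = n + k - 2
            _insert_leaf(tree, k, edge, new_internal)
            if tree_length(tree, masks, weights) <= best_len:
                recurse(k + 1)
            _remove_leaf(tree, k, edge, new_internal)

    recurse(3)
    if not best_trees:  # incumbent from the greedy tree was never matched
        best_trees = [seed_tree]
    return _dedupe(best_trees), best_len


def nni_neighbors(tree: UnrootedTree):
    """Yield the nearest-neighbor-interchange neighborhood of a binary tree."""
    for u, v in tree.internal_edges():
        u_others = [x for x in tree.adj[u] if x != v]
        v_others = [x for x in tree.adj[v] if x != u]
        for swap_v in v_others:
            t = tree.copy()
            b = u_others[1]
            t.adj[u] = [x if x != b else swap_v for x in t.adj[u]]
            t.adj[v] = [x if x != swap_v else b for x in t.adj[v]]
            t.adj[b] = [x if x != u else v for x in t.adj[b]]
            t.adj[swap_v] = [x if x != v else u for x in t.adj[swap_v]]
            yield t


def heuristic_search(
    taxa: list[str],
    masks: np.ndarray,
    weights: np.ndarray | None = None,
    n_starts: int = 10,
    seed: int = 0,
    max_saved: int = 1000,
) -> tuple[list[UnrootedTree], int]:
    """Random-addition starts followed by NNI hill climbing.

    Keeps every distinct topology attaining the best length found (up to
    ``max_saved``). Not guaranteed optimal; use the branch-and-bound search
    when exactness matters and the taxon count allows.
    """
    if weights is None:
        weights = np.ones(masks.shape[1], dtype=np.int64)
    rng = random.Random(seed)
    best_len: int | None = None
    best: list[UnrootedTree] = []

    def consider(t: UnrootedTree, ln: int):
        nonlocal best_len, best
        if best_len is None or ln < best_len:
            best_len = ln
            best = [t]
        elif ln == best_len and len(best) < max_saved:
            key = frozenset(t.splits())
            if all(frozenset(b.splits()) != key for b in best):
                best.append(t)

    for _ in range(max(1, n_starts)):
        t = random_addition_tree(taxa, masks, rng)
        ln = tree_length(t, masks, weights)
        improved = True
        while improved:
            improved = False
            for nb in nni_neighbors(t):
                lnb = tree_length(nb, masks, weights)
                if lnb < ln:
                    t, ln = nb, lnb
                    improved = True
                    break
        consider(t, ln)
        # sweep the plateau around the local optimum for equally good trees
        for nb in nni_neighbors(t):
            lnb = tree_length(nb, masks, weights)
            if lnb == ln:
                consider(nb, lnb)
    return _dedupe(best), int(best_len)


def _dedupe(trees: list[UnrootedTree]) -> list[UnrootedTree]:
    seen: set[frozenset] = set()
    out = []
    for t in trees:
        key = frozenset(t.splits())
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# consensus / collapsing
# ---------------------------------------------------------------------------


def tree_from_splits(taxa: list[str], splits: set[frozenset]) -> UnrootedTree:
    """Build the (possibly multifurcating) tree displaying a compatible split set.

    Splits are given as canonical sides (not containing min(taxa)); they form
    a laminar family, so each becomes an internal node nested under the
    smallest split properly containing it.
    """
    n = len(taxa)
    index = {lab: i for i, lab in enumerate(taxa)}
    clusters = sorted(splits, key=len)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    root = n
    adj[root] = []
    node_of: dict[frozenset, int] = {}
    next_id = n + 1
    # parent = smallest strictly-containing cluster, else root
    for cl in clusters:
        node_of[cl] = next_id
        adj[next_id] = []
        next_id += 1
    full = frozenset(taxa)

    def parent_node(cl: frozenset) -> int:
        best = None
        for other in clusters:
            if other != cl and cl < other:
                if best is None or len(other) < len(best):
                    best = other
        return node_of[best] if best is not None else root

    for cl in clusters:
        p = parent_node(cl)
        u = node_of[cl]
        adj[p].append(u)
        adj[u].append(p)
    for lab in taxa:
        leaf = index[lab]
        containing = [cl for cl in clusters if lab in cl]
        if containing:
            smallest = min(containing, key=len)
            p = node_of[smallest]
        else:
            p = root
        adj[p].append(leaf)
        adj[leaf].append(p)
    tree = UnrootedTree(list(taxa), adj)
    _suppress_degree_two(tree)
    return tree


def strict_consensus(trees: list[UnrootedTree]) -> UnrootedTree:
    """Tree containing exactly the nontrivial splits shared by all inputs."""
    if not trees:
        raise ValueError("strict consensus of an empty tree set")
    common = set.intersection(*(t.splits() for t in trees))
    return tree_from_splits(list(trees[0].taxa), common)


def collapse_zero_length_edges(tree: UnrootedTree, masks: np.ndarray) -> UnrootedTree:
    """Collapse internal edges whose minimum parsimony length is zero.

    An edge can carry zero changes in some optimal reconstruction exactly
    when contracting it leaves the tree length unchanged (checked with the
    multifurcation-exact Sankoff length).
    """
    base = tree_length(tree, masks)
    keep: set[frozenset] = set()
    ref = min(tree.taxa)
    for u, v in tree.internal_edges():
        t = tree.copy()
        # contract u-v: merge v into u
        for x in t.adj[v]:
            if x != u:
                t.adj[x] = [u if y == v else y for y in t.adj[x]]
                t.adj[u].append(x)
        t.adj[u] = [x for x in t.adj[u] if x != v]
        del t.adj[v]
        if tree_length(t, masks) > base:
            # edge is required: keep the corresponding split
            side = _edge_side(tree, u, v)
            label_side = {tree.taxa[i] for i in side}
            if ref in label_side:
                label_side = set(tree.taxa) - label_side
            keep.add(frozenset(label_side))
    return tree_from_splits(list(tree.taxa), keep)


def _edge_side(tree: UnrootedTree, u: int, v: int) -> set[int]:
    """Leaf ids on v's side of edge (u, v)."""
    side: set[int] = set()
    stack = [(v, u)]
    while stack:
        node, parent = stack.pop()
        if node < tree.n:
            side.add(node)
        for nb in tree.adj[node]:
            if nb != parent:
                stack.append((nb, node))
    return side
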