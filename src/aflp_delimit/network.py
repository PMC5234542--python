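"""p-distances and NeighborNet split networks for three-state AFLP profiles.

The genotype-cluster analysis rests on three pieces:

* **p-distances** between profiles: the proportion of pairwise-comparable
  bins (both calls determinate) at which one profile is scored present and
  the other absent.

* **NeighborNet**: the agglomerative method of Bryant & Moulton that
  produces a circular ordering of the taxa. Pairs of clusters are selected
  by a neighbor-joining-style criterion on cluster-averaged distances, the
  selected nodes are linked into chains, and whenever a node acquires two
  neighbors the three nodes involved are replaced by two using linear
  distance-reduction formulas. Expanding the reduction history yields the
  circular order. On additive (tree) metrics the resulting split system is
  exactly the tree's split set; on circularly decomposable metrics the
  generating splits are recovered.

* **Split weights**: over all n(n-1)/2 interval splits of the circular
  ordering, non-negative least squares fits split weights so that the
  induced split metric approximates the observed distances. Splits with
  (numerically) zero weight are pruned.

Cluster delineation — eyeballed from the network figure in practice — is
made explicit here as single-linkage agglomeration on the same distance
matrix, cut at a requested number of groups or at a distance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .scoring import AMBIGUOUS, CallMatrix

__all__ = [
    "DistanceMatrix",
    "SplitSystem",
    "GroupAssignment",
    "p_distance_matrix",
    "neighbor_net_ordering",
    "fit_split_weights",
    "neighbor_net",
    "extract_groups",
]


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with pairwise-complete character counts."""

    labels: list[str]
    d: np.ndarray                 # (n, n), in [0, 1] for p-distances
    comparable_count: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix must have zero diagonal")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab.ljust(12) + " ".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(labels, np.array(rows))

    def to_nexus(self, path) -> None:
        """NEXUS TAXA + DISTANCES blocks (square, labelled)."""
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"    DIMENSIONS NTAX={self.n};\n    TAXLABELS\n")
            for lab in self.labels:
                fh.write(f"        '{lab}'\n")
            fh.write("    ;\nEND;\n\nBEGIN DISTANCES;\n")
            fh.write("    FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n    MATRIX\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(f"        '{lab}' " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("    ;\nEND;\n")


@dataclass
class SplitSystem:
    """A circular taxon ordering plus weighted splits, all intervals of it.

    Each split is stored as (frozenset of labels on one side, weight >= 0);
    the stored side is the one not containing the first taxon of the
    circular order. ``fit`` is the percent of squared distance explained by
    the fitted split metric.
    """

    circular_order: list[str]
    splits: list[tuple[frozenset, float]]
    fit: float

    def nontrivial(self) -> list[tuple[frozenset, float]]:
        n = len(self.circular_order)
        return [(s, w) for s, w in self.splits if 1 < len(s) < n - 1]

    def weight_of(self, side) -> float:
        """Weight of the split with the given side (either orientation); 0 if absent."""
        side = frozenset(side)
        comp = frozenset(self.circular_order) - side
        for s, w in self.splits:
            if s == side or s == comp:
                return w
        return 0.0

    def to_nexus(self, path) -> None:
        """SplitsTree-compatible NEXUS: TAXA block, then a SPLITS block with a
        CYCLE statement and one line per split (weight + taxon index set)."""
        taxa = self.circular_order
        index = {t: i + 1 for i, t in enumerate(sorted(taxa))}
        labels = sorted(taxa)
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN Taxa;\n")
            fh.write(f"DIMENSIONS ntax={len(taxa)};\nTAXLABELS\n")
            for i, lab in enumerate(labels, 1):
                fh.write(f"[{i}] '{lab}'\n")
            fh.write(";\nEND; [Taxa]\n\nBEGIN Splits;\n")
            fh.write(f"DIMENSIONS ntax={len(taxa)} nsplits={len(self.splits)};\n")
            fh.write("FORMAT labels=no weights=yes confidences=no intervals=no;\n")
            cycle = " ".join(str(index[t]) for t in taxa)
            fh.write(f"CYCLE {cycle};\nMATRIX\n")
            for k, (side, w) in enumerate(self.splits, 1):
                ids = sorted(index[t] for t in side)
                fh.write(f"[{k}, size={len(ids)}]\t{w:.10g}\t"
                         + " ".join(str(i) for i in ids) + ",\n")
            fh.write(";\nEND; [Splits]\n")


@dataclass
class GroupAssignment:
    """Taxon -> group id mapping with the delineation parameters used."""

    assignment: dict[str, int]
    method: dict = field(default_factory=dict)

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for taxon, g in self.assignment.items():
            out.setdefault(g, []).append(taxon)
        return out


def p_distance_matrix(calls: CallMatrix) -> DistanceMatrix:
    """Pairwise p-distances over comparable (both-determinate) bins.

    d(i, j) = #(one 0, other 1) / #(both non-?). A pair with zero comparable
    bins has no defined distance and is an error naming the pair.
    """
    if calls.n_samples < 2 or calls.n_bins < 1:
        raise ValueError("need at least 2 samples and 1 bin for p-distances")
    S = calls.states
    known = (S != AMBIGUOUS).astype(np.int32)
    # pairwise-complete counts via matrix products on indicator matrices
    comparable = known @ known.T
    ones = ((S == 1) & (known > 0)).astype(np.int32)
    zeros = ((S == 0) & (known > 0)).astype(np.int32)
    mism = ones @ zeros.T + zeros @ ones.T
    n = calls.n_samples
    if (comparable[~np.eye(n, dtype=bool)] == 0).any():
        i, j = np.argwhere((comparable == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"no comparable bins between {calls.samples[i]!r} and {calls.samples[j]!r}"
        )
    d = mism / comparable
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(calls.samples), d, comparable)


# ---------------------------------------------------------------------------
# NeighborNet circular ordering (agglomeration with linear reductions)
# ---------------------------------------------------------------------------


def neighbor_net_ordering(dm: DistanceMatrix) -> list[str]:
    """Circular taxon ordering by NeighborNet agglomeration.

    Active nodes are kept in chains of one or two (clusters). Each round:

    1. pick the cluster pair (A, B) minimizing
       Q(A,B) = (m-2) D(A,B) - sum_C D(A,C) - sum_C D(B,C)
       on cluster-averaged distances D, m = number of clusters;
    2. pick nodes x in A, y in B minimizing the same criterion with A and B
       broken into singleton clusters;
    3. link x and y; when a node would acquire two neighbors, replace the
       three chained nodes (a, b, c) by two new nodes u, v with
       d(u,z) = 2/3 d(a,z) + 1/3 d(b,z), d(v,z) = 2/3 d(c,z) + 1/3 d(b,z),
       d(u,v) = (d(a,b) + d(a,c) + d(b,c)) / 3,
       recording the reduction for later expansion.

    When three or fewer nodes remain they are closed into a cycle and the
    reduction history is expanded, yielding the circular order. Ties are
    broken by the lexicographically smallest original taxon label subsumed
    by a node, which makes orderings reproducible.
    """
    n = dm.n
    if n <= 3:
        return list(dm.labels)
    _validate_square(dm.d)

    # growing distance store; node ids are ints, new nodes get fresh ids
    dist: dict[int, dict[int, float]] = {
        i: {j: float(dm.d[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    nbr: dict[int, int | None] = {i: None for i in range(n)}
    # lexicographic tie-break key: smallest original label under each node
    key: dict[int, str] = {i: dm.labels[i] for i in range(n)}
    active: set[int] = set(range(n))
    reductions: list[tuple[int, int, int, int, int]] = []  # (u, v, a, b, c)
    next_id = n

    def d_of(x: int, y: int) -> float:
        return dist[x][y]

    def reduce3(a: int, b: int, c: int) -> tuple[int, int]:
        """Replace the chain a-b-c by the linked pair u-v."""
        nonlocal next_id
        u, v = next_id, next_id + 1
        next_id += 2
        others = [z for z in active if z not in (a, b, c)]
        dist[u] = {}
        dist[v] = {}
        for z in others:
            du = (2.0 * d_of(a, z) + d_of(b, z)) / 3.0
            dv = (2.0 * d_of(c, z) + d_of(b, z)) / 3.0
            dist[u][z] = du
            dist[z][u] = du
            dist[v][z] = dv
            dist[z][v] = dv
        duv = (d_of(a, b) + d_of(a, c) + d_of(b, c)) / 3.0
        dist[u][v] = duv
        dist[v][u] = duv
        for x in (a, b, c):
            active.discard(x)
            for z in others:
                dist[z].pop(x, None)
            dist.pop(x, None)
        active.update((u, v))
        nbr[u] = v
        nbr[v] = u
        nbr.pop(a, None)
        nbr.pop(b, None)
        nbr.pop(c, None)
        key[u] = key[v] = min(key[a], key[b], key[c])  # used only for tie-breaks
        reductions.append((u, v, a, b, c))
        return u, v

    while len(active) > 3:
        # clusters: chains of one or two active nodes, in deterministic order
        clusters: list[tuple[int, ...]] = []
        seen: set[int] = set()
        for i in sorted(active, key=lambda x: (key[x], x)):
            if i in seen:
                continue
            j = nbr[i]
            if j is not None:
                clusters.append((i, j))
                seen.update((i, j))
            else:
                clusters.append((i,))
                seen.add(i)
        m = len(clusters)
        if m < 2:
            break

        Dc = np.zeros((m, m))
        for p in range(m):
            for q in range(p + 1, m):
                acc = sum(d_of(x, y) for x in clusters[p] for y in clusters[q])
                Dc[p, q] = Dc[q, p] = acc / (len(clusters[p]) * len(clusters[q]))
        R = Dc.sum(axis=1)
        best = None
        best_pq = None
        for p in range(m):
            for q in range(p + 1, m):
                Qpq = (m - 2) * Dc[p, q] - R[p] - R[q]
                if best is None or Qpq < best - 1e-14:
                    best = Qpq
                    best_pq = (p, q)
        A = clusters[best_pq[0]]
        B = clusters[best_pq[1]]

        # second selection: members of A and B as singletons, others intact
        others = [clusters[r] for r in range(m) if r not in best_pq]
        mh = len(others) + len(A) + len(B)
        loose = list(A) + list(B)

        def r_node(x: int) -> float:
            s = sum(
                sum(d_of(x, y) for y in C) / len(C) for C in others
            )
            s += sum(d_of(x, z) for z in loose if z != x)
            return s

        rx = {x: r_node(x) for x in loose}
        best = None
        best_xy = None
        for x in A:
            for y in B:
                Qxy = (mh - 2) * d_of(x, y) - rx[x] - rx[y]
                if best is None or Qxy < best - 1e-14:
                    best = Qxy
                    best_xy = (x, y)
        x, y = best_xy

        if nbr[x] is None and nbr[y] is None:
            nbr[x] = y
            nbr[y] = x
        elif nbr[x] is not None and nbr[y] is None:
            reduce3(nbr[x], x, y)
        elif nbr[x] is None and nbr[y] is not None:
            reduce3(nbr[y], y, x)
        else:
            z = nbr[y]
            nbr[z] = None
            u, v = reduce3(nbr[x], x, y)
            reduce3(u, v, z)

    # close remaining nodes into a cycle (any cyclic order of <= 3 nodes works)
    cycle = sorted(active, key=lambda x: (key[x], x))

    # expand the reduction history, last reduction first; each (u, v) is an
    # adjacent pair in the current cycle and is replaced by (a, b, c) with a
    # on u's side and c on v's side
    for u, v, a, b, c in reversed(reductions):
        i = cycle.index(u)
        cycle = cycle[i:] + cycle[:i]  # rotate u to the front
        if cycle[1] == v:
            cycle = [a, b, c] + cycle[2:]
        elif cycle[-1] == v:
            cycle = [a] + cycle[1:-1] + [c, b]
        else:
            raise RuntimeError("internal error: reduced pair not adjacent in cycle")

    return [dm.labels[i] for i in cycle]


def _validate_square(d: np.ndarray) -> None:
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")


# ---------------------------------------------------------------------------
# Split-weight estimation (constrained least squares on interval splits)
# ---------------------------------------------------------------------------


def _interval_splits(n: int) -> list[tuple[int, int]]:
    """All n(n-1)/2 intervals [i, j] (positions 1..n-1) of a circular order;
    the interval side never contains position 0, so each split appears once."""
    return [(i, j) for i in range(1, n) for j in range(i, n)]


def fit_split_weights(
    dm: DistanceMatrix,
    order: list[str],
    weight_epsilon: float = 1e-9,
) -> SplitSystem:
    """Non-negative least squares split weights for a circular ordering.

    Builds the split-metric incidence A over all interval splits of the
    ordering (A[(p,q), S] = 1 when S separates p and q) and solves
    min ||A w - d|| s.t. w >= 0 with an active-set NNLS solver. Splits with
    weight below ``weight_epsilon`` (numerical zeros) are dropped. The fit
    statistic is the percent of squared distance explained.
    """
    if set(order) != set(dm.labels):
        raise ValueError("circular order must be a permutation of the taxa")
    n = dm.n
    pos = {lab: k for k, lab in enumerate(order)}
    perm = [dm.labels.index(lab) for lab in order]
    D = dm.d[np.ix_(perm, perm)]
    dvec = squareform(D, checks=False)  # pairs (p, q), p < q, in position space
    pairs = [(p, q) for p in range(n - 1) for q in range(p + 1, n)]
    splits = _interval_splits(n)
    A = np.zeros((len(pairs), len(splits)))
    for s_idx, (i, j) in enumerate(splits):
        inside = np.zeros(n, dtype=bool)
        inside[i : j + 1] = True
        for p_idx, (p, q) in enumerate(pairs):
            if inside[p] != inside[q]:
                A[p_idx, s_idx] = 1.0
    w, rnorm = nnls(A, dvec)
    ss_tot = float(dvec @ dvec)
    fit = 100.0 * (1.0 - (rnorm**2) / ss_tot) if ss_tot > 0 else 100.0
    out: list[tuple[frozenset, float]] = []
    for (i, j), wk in zip(splits, w):
        if wk >= weight_epsilon:
            side = frozenset(order[i : j + 1])
            out.append((side, float(wk)))
    return SplitSystem(circular_order=list(order), splits=out, fit=fit)


def neighbor_net(dm: DistanceMatrix, weight_epsilon: float = 1e-9) -> SplitSystem:
    """Convenience: NeighborNet ordering followed by split-weight fitting."""
    order = neighbor_net_ordering(dm)
    return fit_split_weights(dm, order, weight_epsilon=weight_epsilon)


# ---------------------------------------------------------------------------
# Cluster delineation
# ---------------------------------------------------------------------------


def extract_groups(
    dm: DistanceMatrix,
    k: int | None = None,
    threshold: float | None = None,
) -> GroupAssignment:
    """Single-linkage agglomeration on the distance matrix, cut at ``k`` groups
    or at a distance ``threshold``. Single linkage respects the neighborhood
    structure of the split network. Group ids are renumbered 1..k in order of
    first appearance along the (label-sorted) taxon list.
    """
    if (k is None) == (threshold is None):
        raise ValueError("specify exactly one of k or threshold")
    n = dm.n
    if k is not None and not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if threshold is not None and not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    # deterministic tie-breaking: feed taxa in label order
    order = sorted(range(n), key=lambda i: dm.labels[i])
    D = dm.d[np.ix_(order, order)]
    Z = linkage(squareform(D, checks=False), method="single")
    if k is not None:
        raw = fcluster(Z, t=k, criterion="maxclust")
        meta = {"linkage": "single", "k": k}
    else:
        raw = fcluster(Z, t=threshold, criterion="distance")
        meta = {"linkage": "single", "threshold": threshold}
    renum: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for idx, i in enumerate(order):
        g = int(raw[idx])
        if g not in renum:
            renum[g] = len(renum) + 1
        assignment[dm.labels[i]] = renum[g]
    return GroupAssignment(assignment=assignment, method=meta)
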