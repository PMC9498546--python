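"""Distance phylogenetics: pairwise differences, neighbor joining, bootstrap
support, reference-anchored group assignment, species-overlap duplication
counting.

Distances follow the "number of differences" convention: the count of aligned
columns at which two sequences differ, with positions that are gapped in
either member of the pair removed (pairwise deletion; complete deletion is
available as a mode).  Tie-breaking is lexicographic on taxon ids throughout,
so every function is deterministic for a fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .seqio import ReferenceAnchorSet

GAP_CHARS = frozenset("-.")


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxa ids")
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_positions(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subsample_columns(self, cols: np.ndarray) -> "Alignment":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Alignment(list(self.ids), rows)


def read_alignment_fasta(path) -> Alignment:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(ids, rows)


def write_alignment_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for tid, row in zip(aln.ids, aln.rows):
            fh.write(f">{tid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def pairwise_distances(
    aln: Alignment, method: str = "count_differences", deletion: str = "pairwise"
) -> DistanceMatrix:
    """Count-of-differences distances with pairwise (default) or complete
    gap deletion.  A pair with zero comparable columns is an error."""
    if method != "count_differences":
        raise ValueError(f"unknown method {method!r}")
    if deletion not in {"pairwise", "complete"}:
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = len(aln.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    arr = np.array([list(r) for r in aln.rows])
    is_gap = np.isin(arr, list(GAP_CHARS))
    if deletion == "complete":
        keep = ~is_gap.any(axis=0)
        arr = arr[:, keep]
        is_gap = is_gap[:, keep]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(is_gap[i] | is_gap[j])
            if not ok.any():
                raise ValueError(
                    f"no comparable columns for pair ({aln.ids[i]}, {aln.ids[j]})"
                )
            diff = int(np.sum((arr[i] != arr[j]) & ok))
            d[i, j] = d[j, i] = diff
    return DistanceMatrix(list(aln.ids), d)


# ---------------------------------------------------------------------------
# Unrooted tree container

@dataclass
class PhyloTree:
    """Unrooted tree: integer nodes, adjacency with branch lengths, leaf labels.

    ``supports`` maps canonical bipartitions (see :func:`canonical_split`) to
    bootstrap proportions.  ``negative_length_log`` records NJ branch-length
    clamps as (node_pair, raw_value).
    """

    adjacency: dict[int, dict[int, float]]
    labels: dict[int, str]  # leaf node -> taxon id
    supports: dict[frozenset, float] = field(default_factory=dict)
    negative_length_log: list = field(default_factory=list)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.labels.values())

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u in self.adjacency:
            for v in self.adjacency[u]:
                if u < v:
                    out.append((u, v))
        return sorted(out)

    def side_leaves(self, u: int, v: int) -> frozenset:
        """Leaf labels on the v side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        labels = set()
        while stack:
            node = stack.pop()
            if node in self.labels:
                labels.add(self.labels[node])
            for nxt in self.adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return frozenset(labels)

    def bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial bipartitions (internal edges only)."""
        all_leaves = frozenset(self.labels.values())
        out = set()
        for u, v in self.edges():
            side = self.side_leaves(u, v)
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(canonical_split(side, all_leaves))
        return out

    def total_branch_length(self) -> float:
        return sum(self.adjacency[u][v] for u, v in self.edges())

    def to_newick(self, decimals: int = 6) -> str:
        """Rooted rendering of the unrooted tree at the neighbor of the
        lexicographically smallest leaf; supports become internal labels."""
        if len(self.labels) == 1:
            (node,) = self.labels
            return f"{self.labels[node]};"
        all_leaves = frozenset(self.labels.values())
        first_leaf = min(self.labels, key=lambda n: self.labels[n])
        root = next(iter(self.adjacency[first_leaf])) if self.adjacency[first_leaf] else first_leaf

        def subtree_min_label(node: int, parent: int) -> str:
            if node in self.labels:
                return self.labels[node]
            return min(
                subtree_min_label(c, node)
                for c in self.adjacency[node]
                if c != parent
            )

        def render(node: int, parent: int) -> str:
            length = self.adjacency[node][parent]
            blen = f":{length:.{decimals}g}"
            if node in self.labels:
                return f"{self.labels[node]}{blen}"
            children = sorted(
                (c for c in self.adjacency[node] if c != parent),
                key=lambda c: subtree_min_label(c, node),
            )
            inner = ",".join(render(c, node) for c in children)
            side = self.side_leaves(parent, node)
            split = canonical_split(side, all_leaves)
            label = ""
            if split in self.supports:
                label = f"{self.supports[split]:.{decimals}g}"
            return f"({inner}){label}{blen}"

        children = sorted(
            self.adjacency[root], key=lambda c: subtree_min_label(c, root)
        )
        inner = ",".join(render(c, root) for c in children)
        return f"({inner});"


def canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Orientation-free key for a bipartition: the side NOT containing the
    alphabetically first leaf."""
    ref = min(all_leaves)
    return frozenset(all_leaves - side) if ref in side else frozenset(side)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic NJ (Saitou & Nei Q-criterion), deterministic.

    Ties in Q are broken by the lexicographically smallest pair of cluster
    keys, where a cluster's key is its alphabetically first leaf.  Negative
    branch lengths are clamped to zero; raw values are kept in
    ``negative_length_log``.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    order = np.argsort(np.array(dm.ids, dtype=object))
    ids = [dm.ids[i] for i in order]
    D = dm.d[np.ix_(order, order)].astype(float)
    D = 0.5 * (D + D.T)  # exact symmetry so tie scanning sees both triangles

    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    labels = {i: ids[i] for i in range(n)}
    keys = list(ids)  # tie-break key per active cluster
    nodes = list(range(n))  # tree-node id per active cluster
    next_node = n
    neg_log: list = []

    def connect(a: int, b: int, length: float) -> None:
        raw = length
        if length < 0:
            neg_log.append(((a, b), raw))
            length = 0.0
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i, j in np.argwhere(Q == qmin):
            if i > j:
                i, j = j, i
            cand = tuple(sorted((keys[i], keys[j])))
            if best is None or cand < best[0]:
                best = (cand, int(i), int(j))
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        u = next_node
        next_node += 1
        connect(nodes[i], u, li)
        connect(nodes[j], u, lj)
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.empty((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        newD[-1, -1] = 0.0
        D = newD
        new_key = min(keys[i], keys[j])
        keys = [keys[k] for k in keep] + [new_key]
        nodes = [nodes[k] for k in keep] + [u]

    # final three clusters join at one internal node (three-point formulas)
    a, b, c = 0, 1, 2
    u = next_node
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    connect(nodes[a], u, la)
    connect(nodes[b], u, lb)
    connect(nodes[c], u, lc)

    return PhyloTree(adjacency, labels, negative_length_log=neg_log)


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_support(
    aln: Alignment,
    replicates: int,
    seed: int,
    deletion: str = "pairwise",
) -> PhyloTree:
    """NJ tree on the full alignment with bipartition bootstrap supports.

    Columns are resampled with replacement per replicate; each replicate's
    RNG stream is derived from (seed, replicate index), so supports are
    reproducible and independent of execution order.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    full = neighbor_joining(pairwise_distances(aln, deletion=deletion))
    target = full.bipartitions()
    hits = {split: 0 for split in target}
    n_pos = aln.n_positions
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, n_pos, size=n_pos)
        rep_aln = aln.subsample_columns(cols)
        try:
            rep_tree = neighbor_joining(pairwise_distances(rep_aln, deletion=deletion))
        except ValueError:
            continue  # a replicate can lose all comparable columns for a pair
        rep_splits = rep_tree.bipartitions()
        for split in target:
            if split in rep_splits:
                hits[split] += 1
    full.supports = {split: hits[split] / replicates for split in target}
    return full


# ---------------------------------------------------------------------------
# Group assignment

@dataclass(frozen=True)
class GroupCall:
    gene_id: str
    group: str  # one of A..P or "unassigned"
    support: float | None = None


def assign_groups(
    tree: PhyloTree, anchors: ReferenceAnchorSet | dict
) -> list[GroupCall]:
    """Assign each query leaf the group of its smallest anchored clade.

    Candidate clades are the leaf sets on either side of every edge.  For a
    query, the smallest side containing it and at least one anchor decides:
    if that side's anchors all share one group the query gets that group (with
    the edge's bootstrap support when available); a mixed anchor set yields
    "unassigned".  The rule depends only on tree shape, so it is invariant to
    leaf input order and re-rooting.
    """
    group_of = anchors.group_of if isinstance(anchors, ReferenceAnchorSet) else dict(anchors)
    leaves = set(tree.labels.values())
    anchor_ids = set(group_of) & leaves
    if not anchor_ids:
        raise ValueError("tree contains no anchor leaves")
    all_leaves = frozenset(leaves)

    sides = []
    for u, v in tree.edges():
        for side in (tree.side_leaves(u, v), tree.side_leaves(v, u)):
            if side and side != all_leaves:
                sides.append(side)
    sides.sort(key=lambda s: (len(s), tuple(sorted(s))))

    calls = []
    for leaf in sorted(leaves - anchor_ids):
        call = GroupCall(leaf, "unassigned")
        for side in sides:
            if leaf not in side:
                continue
            groups = {group_of[a] for a in side & anchor_ids}
            if not groups:
                continue
            if len(groups) == 1:
                split = canonical_split(side, all_leaves)
                call = GroupCall(leaf, groups.pop(), tree.supports.get(split))
            break
        calls.append(call)
    return calls


def write_groups_tsv(calls: list[GroupCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgroup\tsupport\n")
        for c in sorted(calls, key=lambda c: c.gene_id):
            sup = "" if c.support is None else f"{c.support:.4g}"
            fh.write(f"{c.gene_id}\t{c.group}\t{sup}\n")


# ---------------------------------------------------------------------------
# Species-overlap duplication counting

def count_duplications(
    tree: PhyloTree, species_of: dict[str, str]
) -> tuple[tuple[int, int], int, list[frozenset]]:
    """Minimum-duplication rooting by species overlap.

    Every edge is evaluated as a root placement; an internal node (including
    the root) is a duplication when its two child subtrees share at least one
    species.  Returns (root edge, duplication count, duplication-node clades
    as leaf-label sets), with ties broken by deterministic edge order.
    """
    # species set and internal duplication count of each directed subtree
    sp: dict[tuple[int, int], frozenset] = {}
    dups: dict[tuple[int, int], int] = {}

    def walk(node: int, parent: int) -> None:
        key = (parent, node)
        if key in sp:
            return
        if node in tree.labels:
            sp[key] = frozenset({species_of[tree.labels[node]]})
            dups[key] = 0
            return
        children = [c for c in tree.adjacency[node] if c != parent]
        for c in children:
            walk(c, node)
        child_sets = [sp[(node, c)] for c in children]
        total = sum(dups[(node, c)] for c in children)
        # binary interior: duplication if the two child subtrees overlap
        overlap = frozenset()
        if len(child_sets) == 2:
            overlap = child_sets[0] & child_sets[1]
        if overlap:
            total += 1
        sp[key] = frozenset().union(*child_sets)
        dups[key] = total

    def edge_sort_key(e):
        u, v = e
        side = tree.side_leaves(u, v)
        return (len(side), tuple(sorted(side)))

    best = None
    for u, v in sorted(tree.edges(), key=edge_sort_key):
        walk(u, v)
        walk(v, u)
        count = dups[(v, u)] + dups[(u, v)]
        if sp[(v, u)] & sp[(u, v)]:
            count += 1  # the root itself is a branching point
        if best is None or count < best[1]:
            best = ((u, v), count)
    root_edge, count = best

    # collect duplication clades under the best rooting
    u, v = root_edge
    clades: list[frozenset] = []

    def collect(node: int, parent: int) -> None:
        if node in tree.labels:
            return
        children = [c for c in tree.adjacency[node] if c != parent]
        if len(children) == 2:
            a, b = children
            if sp[(node, a)] & sp[(node, b)]:
                clades.append(tree.side_leaves(parent, node))
        for c in children:
            collect(c, node)

    if sp[(v, u)] & sp[(u, v)]:
        clades.append(frozenset(tree.labels.values()))
    collect(u, v)
    collect(v, u)
    clades.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return root_edge, count, clades
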