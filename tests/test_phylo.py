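import itertools

import numpy as np
import pytest

from ugtfam import phylo
from ugtfam.simulate import ScenarioConfig, generate_family_tree

# ---------------------------------------------------------------------------
# independent oracles


def random_topology_edges(taxa, rng):
    """Random unrooted binary topology as an edge list (independent builder)."""
    edges = [(-1, taxa[0]), (-1, taxa[1]), (-1, taxa[2])]
    next_internal = -2
    for t in taxa[3:]:
        i = int(rng.integers(len(edges)))
        u, v = edges.pop(i)
        w = next_internal
        next_internal -= 1
        edges += [(u, w), (w, v), (w, t)]
    return edges


def all_topologies(taxa):
    """Exhaustive enumeration of unrooted binary topologies (edge lists)."""
    if len(taxa) < 4:
        yield [(-1, taxa[0]), (-1, taxa[1]), (-1, taxa[2])]
        return

    def grow(edges, remaining, next_internal):
        if not remaining:
            yield edges
            return
        t, rest = remaining[0], remaining[1:]
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            new_edges = edges[:i] + edges[i + 1:] + [(u, w), (w, v), (w, t)]
            yield from grow(new_edges, rest, next_internal - 1)

    base = [(-1, taxa[0]), (-1, taxa[1]), (-1, taxa[2])]
    yield from grow(base, taxa[3:], -2)


def edges_to_adjacency(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def edge_bipartitions(edges, taxa):
    """Non-trivial bipartitions of an edge-list topology, canonicalized."""
    adj = edges_to_adjacency(edges)
    allset = frozenset(taxa)
    out = set()
    for u, v in edges:
        seen = {u}
        stack = [v]
        side = set()
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            if not isinstance(n, int) or n >= 0:
                if n in taxa:
                    side.add(n)
            for nb in adj[n]:
                if nb not in seen:
                    stack.append(nb)
        side = frozenset(s for s in side)
        if 1 < len(side) < len(taxa) - 1:
            out.add(phylo.canonical_split(side, allset))
    return out


def path_distances(edges, lengths, taxa):
    """Leaf-to-leaf path-sum distances for an edge list with branch lengths."""
    adj = {}
    for (u, v), L in zip(edges, lengths):
        adj.setdefault(u, []).append((v, L))
        adj.setdefault(v, []).append((u, L))
    n = len(taxa)
    d = np.zeros((n, n))
    index = {t: i for i, t in enumerate(taxa)}
    for t in taxa:
        dist = {t: 0.0}
        stack = [t]
        while stack:
            x = stack.pop()
            for y, L in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + L
                    stack.append(y)
        for s in taxa:
            d[index[t], index[s]] = dist[s]
    return d


def least_squares_residual(edges, taxa, dm):
    """Ordinary least-squares fit of branch lengths to a topology; returns
    the residual sum of squares."""
    adj = edges_to_adjacency(edges)
    edge_index = {frozenset(e): i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(taxa, 2))
    A = np.zeros((len(pairs), len(edges)))
    idx = {t: i for i, t in enumerate(dm.ids)}
    b = np.array([dm.d[idx[a], idx[c]] for a, c in pairs])
    # one traversal per source leaf, recording the edge set along each path
    path_edges = {}
    for a in taxa:
        parent = {a: None}
        stack = [a]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in parent:
                    parent[y] = x
                    stack.append(y)
        for c in taxa:
            if c == a:
                continue
            rows = []
            node = c
            while parent[node] is not None:
                rows.append(edge_index[frozenset((node, parent[node]))])
                node = parent[node]
            path_edges[(a, c)] = rows
    for r, (a, c) in enumerate(pairs):
        A[r, path_edges[(a, c)]] = 1.0
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    r = A @ x - b
    return float(r @ r)


# ---------------------------------------------------------------------------


class TestDistances:
    def test_identical_rows_zero(self):
        aln = phylo.Alignment(["a", "b"], ["AAAA", "AAAA"])
        assert phylo.pairwise_distances(aln).d[0, 1] == 0

    def test_single_difference(self):
        aln = phylo.Alignment(["a", "b"], ["AAAA", "AAAT"])
        assert phylo.pairwise_distances(aln).d[0, 1] == 1

    def test_pairwise_deletion_skips_gapped_columns(self):
        # comparable columns are 1,3,4 (1-based); only column 4 differs
        aln = phylo.Alignment(["a", "b"], ["A-CD", "ABCE"])
        assert phylo.pairwise_distances(aln).d[0, 1] == 1

    def test_complete_deletion_mode(self):
        aln = phylo.Alignment(["a", "b", "c"], ["A-CD", "ABCE", "ABCD"])
        dm = phylo.pairwise_distances(aln, deletion="complete")
        # the gapped column is removed for every pair
        assert dm.d[1, 2] == 1  # E vs D only

    def test_all_gap_pair_is_error(self):
        aln = phylo.Alignment(["a", "b"], ["A-", "-B"])
        with pytest.raises(ValueError, match="no comparable columns"):
            phylo.pairwise_distances(aln)


class TestNeighborJoining:
    def test_three_taxon_three_point_solution(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        t = phylo.neighbor_joining(phylo.DistanceMatrix(list("ABC"), d))
        lens = sorted(t.adjacency[u][v] for u, v in t.edges())
        assert lens == pytest.approx([1.0, 2.0, 3.0])

    def test_five_taxon_additive_recovery(self):
        rng = np.random.default_rng(12)
        taxa = list("ABCDE")
        edges = random_topology_edges(taxa, rng)
        lengths = rng.uniform(0.5, 2.0, len(edges))
        d = path_distances(edges, lengths, taxa)
        t = phylo.neighbor_joining(phylo.DistanceMatrix(taxa, d))
        assert t.bipartitions() == edge_bipartitions(edges, taxa)
        assert t.total_branch_length() == pytest.approx(lengths.sum(), abs=1e-9)

    def test_matches_reference_nj_implementation(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(77)
        taxa = [f"t{i}" for i in range(7)]
        edges = random_topology_edges(taxa, rng)
        d = path_distances(edges, rng.uniform(0.2, 3.0, len(edges)), taxa)
        d = 0.5 * (d + d.T)  # exact symmetry for both implementations
        ours = phylo.neighbor_joining(phylo.DistanceMatrix(taxa, d))
        sk_tree = sk_nj(SkDM(d, taxa))
        sk_splits = set()
        allset = frozenset(taxa)
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(taxa) - 1:
                sk_splits.add(phylo.canonical_split(side, allset))
        assert ours.bipartitions() == sk_splits

    def test_degenerate_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = phylo.DistanceMatrix(list("ABCD"), d)
        t1 = phylo.neighbor_joining(dm).to_newick()
        t2 = phylo.neighbor_joining(dm).to_newick()
        assert t1 == t2

    def test_fewer_than_three_taxa_error(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(
                phylo.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
            )

    def test_negative_branch_lengths_clamped_and_logged(self):
        d = np.array(
            [[0, 1, 10, 9], [1, 0, 9, 10], [10, 9, 0, 1], [9, 10, 1, 0]], dtype=float
        )
        t = phylo.neighbor_joining(phylo.DistanceMatrix(list("ABCD"), d))
        assert all(t.adjacency[u][v] >= 0 for u, v in t.edges())


class TestBootstrap:
    def _two_clade_alignment(self):
        a = "A" * 30 + "C" * 30
        b = "C" * 30 + "A" * 30
        return phylo.Alignment(
            ["x1", "x2", "y1", "y2"], [a, a, b, b]
        )

    def test_saturated_signal_gives_full_support(self):
        t = phylo.bootstrap_support(self._two_clade_alignment(), 20, seed=1)
        assert set(t.supports.values()) == {1.0}

    def test_single_replicate_supports_binary(self):
        rng = np.random.default_rng(6)
        rows = ["".join("ACDE"[i] for i in rng.integers(0, 4, 40)) for _ in range(5)]
        aln = phylo.Alignment([f"t{i}" for i in range(5)], rows)
        t = phylo.bootstrap_support(aln, 1, seed=3)
        assert set(t.supports.values()) <= {0.0, 1.0}

    def test_same_seed_reproducible(self):
        aln = self._two_clade_alignment()
        t1 = phylo.bootstrap_support(aln, 10, seed=9)
        t2 = phylo.bootstrap_support(aln, 10, seed=9)
        assert t1.supports == t2.supports
        assert all(0 <= s <= 1 for s in t1.supports.values())


class TestAssignGroups:
    def _tree_from_alignment(self, rows_by_id):
        ids = list(rows_by_id)
        aln = phylo.Alignment(ids, [rows_by_id[i] for i in ids])
        return phylo.neighbor_joining(phylo.pairwise_distances(aln))

    def test_query_sister_to_single_anchor(self):
        t = self._tree_from_alignment(
            {
                "q1": "AAAAAAAAAC",
                "anchE": "AAAAAAAAAA",
                "anchD": "CCCCCCCCCC",
                "anchA": "GGGGGGGGGG",
            }
        )
        calls = {c.gene_id: c.group for c in phylo.assign_groups(t, {"anchE": "E", "anchD": "D", "anchA": "A"})}
        assert calls["q1"] == "E"

    def test_query_in_mixed_anchor_clade_unassigned(self):
        # the two anchors form a cherry; q joins outside it, so q's smallest
        # anchored clade holds anchors of two different groups
        t = self._tree_from_alignment(
            {
                "q1": "AAGGAAAAAAAAAAAAAAAA",
                "anchD": "AAAAAAAAAAAAAAAAAAAA",
                "anchE": "AAATAAAAAAAAAAAAAAAA",
                "out1": "GGGGGGGGGGGGGGGGGGGG",
                "out2": "GGGGGGGGGGGGGGGGGGGT",
            }
        )
        calls = {c.gene_id: c.group for c in phylo.assign_groups(t, {"anchD": "D", "anchE": "E"})}
        assert calls["q1"] == "unassigned"

    def test_invariant_to_leaf_input_order(self):
        cfg = ScenarioConfig(n_groups=4, n_queries=8, alignment_length=120)
        aln, anchors, truth = generate_family_tree(cfg, seed=5)
        t1 = phylo.neighbor_joining(phylo.pairwise_distances(aln))
        order = np.random.default_rng(1).permutation(len(aln.ids))
        shuffled = phylo.Alignment(
            [aln.ids[i] for i in order], [aln.rows[i] for i in order]
        )
        t2 = phylo.neighbor_joining(phylo.pairwise_distances(shuffled))
        c1 = sorted((c.gene_id, c.group) for c in phylo.assign_groups(t1, anchors))
        c2 = sorted((c.gene_id, c.group) for c in phylo.assign_groups(t2, anchors))
        assert c1 == c2

    def test_planted_groups_fully_recovered(self):
        cfg = ScenarioConfig(n_groups=8, n_queries=20, alignment_length=200)
        aln, anchors, truth = generate_family_tree(cfg, seed=2)
        t = phylo.neighbor_joining(phylo.pairwise_distances(aln))
        calls = phylo.assign_groups(t, anchors)
        for c in calls:
            assert c.group == truth["group_of"][c.gene_id]

    def test_tree_without_anchors_is_error(self):
        t = self._tree_from_alignment(
            {"a": "AAAA", "b": "AACC", "c": "CCCC"}
        )
        with pytest.raises(ValueError, match="no anchor"):
            phylo.assign_groups(t, {"zz": "A"})


def naive_duplication_count(tree, species_of):
    """Brute force: for every rooting, recursively count overlap nodes."""
    best = None
    for u, v in tree.edges():

        def species_and_dups(node, parent):
            if node in tree.labels:
                return {species_of[tree.labels[node]]}, 0
            kids = [c for c in tree.adjacency[node] if c != parent]
            sets, total = [], 0
            for k in kids:
                s, d = species_and_dups(k, node)
                sets.append(s)
                total += d
            if len(sets) == 2 and sets[0] & sets[1]:
                total += 1
            return set().union(*sets), total

        su, du = species_and_dups(u, v)
        sv, dv = species_and_dups(v, u)
        count = du + dv + (1 if su & sv else 0)
        if best is None or count < best:
            best = count
    return best


class TestCountDuplications:
    def test_unique_species_zero_duplications(self):
        aln = phylo.Alignment(
            ["a", "b", "c", "d"], ["AAAA", "AACC", "CCAA", "CCCC"]
        )
        t = phylo.neighbor_joining(phylo.pairwise_distances(aln))
        _, count, clades = phylo.count_duplications(
            t, {"a": "s1", "b": "s2", "c": "s3", "d": "s4"}
        )
        assert count == 0 and clades == []

    def test_forced_overlap_single_duplication(self):
        aln = phylo.Alignment(["A1", "A2", "B"], ["AAAA", "AAAC", "GGGG"])
        t = phylo.neighbor_joining(phylo.pairwise_distances(aln))
        _, count, clades = phylo.count_duplications(
            t, {"A1": "spA", "A2": "spA", "B": "spB"}
        )
        assert count == 1

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(19)
        for trial in range(20):
            n = int(rng.integers(5, 11))
            taxa = [f"t{i}" for i in range(n)]
            edges = random_topology_edges(taxa, rng)
            d = path_distances(edges, rng.uniform(0.5, 2.0, len(edges)), taxa)
            t = phylo.neighbor_joining(phylo.DistanceMatrix(taxa, d))
            species = {x: f"s{rng.integers(0, 4)}" for x in taxa}
            _, count, _ = phylo.count_duplications(t, species)
            assert count == naive_duplication_count(t, species)


class TestNewick:
    def test_output_parses_and_preserves_leaves(self):
        import dendropy

        aln = phylo.Alignment(
            ["a", "b", "c", "d", "e"],
            ["AAAA", "AACC", "CCAA", "CCCC", "GGGG"],
        )
        t = phylo.bootstrap_support(aln, 5, seed=4)
        nwk = t.to_newick()
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == list("abcde")
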