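import itertools
import warnings

import numpy as np
import pytest

from ugtfam import duplication as dup
from ugtfam.seqio import GeneLocus
from ugtfam.simulate import ScenarioConfig, generate_duplicates


def oracle_clusters(loci, window, min_size):
    """O(n^2) transitive closure: connect any two same-chromosome loci whose
    start gap is < window, then take components of size >= min_size."""
    parent = {l.gene_id: l.gene_id for l in loci}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in itertools.combinations(loci, 2):
        if a.chrom == b.chrom and abs(a.start - b.start) < window:
            parent[find(a.gene_id)] = find(b.gene_id)
    comps = {}
    for l in loci:
        comps.setdefault(find(l.gene_id), []).append(l)
    out = []
    for members in comps.values():
        if len(members) >= min_size:
            members.sort(key=lambda l: (l.start, l.gene_id))
            out.append((members[0].chrom, tuple(m.gene_id for m in members)))
    return sorted(out)


class TestDetectClusters:
    def test_single_gene_no_cluster(self):
        assert dup.detect_clusters([GeneLocus("g", "c", 0, 100)]) == []

    def test_two_within_window_third_outside(self):
        loci = [
            GeneLocus("g1", "c", 0, 1000),
            GeneLocus("g2", "c", 150_000, 151_000),
            GeneLocus("g3", "c", 400_000, 401_000),
        ]
        (cluster,) = dup.detect_clusters(loci, window=200_000)
        assert cluster.member_ids == ["g1", "g2"]

    def test_chain_of_fifteen(self):
        loci = [
            GeneLocus(f"g{i:02d}", "c", i * 100_000, i * 100_000 + 1000)
            for i in range(15)
        ]
        (cluster,) = dup.detect_clusters(loci)
        assert len(cluster.member_ids) == 15

    def test_window_boundary_is_strict(self):
        loci = [GeneLocus("a", "c", 0, 10), GeneLocus("b", "c", 200_000, 200_010)]
        assert dup.detect_clusters(loci, window=200_000) == []

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(55)
        for trial in range(100):
            n = int(rng.integers(2, 40))
            loci = [
                GeneLocus(
                    f"g{i}",
                    f"chr{rng.integers(1, 4)}",
                    int(rng.integers(0, 2_000_000)),
                    int(rng.integers(0, 2_000_000)) + 2_000_001,
                )
                for i in range(n)
            ]
            got = sorted(
                (c.chrom, tuple(c.member_ids)) for c in dup.detect_clusters(loci)
            )
            assert got == oracle_clusters(loci, 200_000, 2)


class TestClassifyPair:
    clusters = [dup.GeneCluster("c1", ["a", "b", "x"], (0, 300_000))]

    def test_adjacent_in_cluster_tandem(self):
        a = GeneLocus("a", "c1", 0, 1000)
        b = GeneLocus("b", "c1", 50_000, 51_000)
        assert dup.classify_pair(a, b, self.clusters) == "tandem"

    def test_different_chromosomes_segmental(self):
        a = GeneLocus("a", "c1", 0, 1000)
        b = GeneLocus("z", "c2", 0, 1000)
        assert dup.classify_pair(a, b, self.clusters) == "segmental"

    def test_same_chromosome_far_apart_segmental(self):
        a = GeneLocus("a", "c1", 0, 1000)
        z = GeneLocus("z", "c1", 5_000_000, 5_001_000)
        assert dup.classify_pair(a, z, self.clusters) == "segmental"

    def test_non_adjacent_in_cluster_segmental(self):
        a = GeneLocus("a", "c1", 0, 1000)
        x = GeneLocus("x", "c1", 100_000, 101_000)
        assert dup.classify_pair(a, x, self.clusters) == "segmental"

    def test_intervening_gene_list_blocks_tandem(self):
        a = GeneLocus("a", "c1", 0, 1000)
        b = GeneLocus("b", "c1", 50_000, 51_000)
        other = [GeneLocus("nf", "c1", 10_000, 11_000)]
        assert dup.classify_pair(a, b, self.clusters, other) == "segmental"
        far = [GeneLocus("nf", "c1", 400_000, 401_000)]
        assert dup.classify_pair(a, b, self.clusters, far) == "tandem"


class TestNeiGojobori:
    def test_identical_sequences_zero(self):
        r = dup.nei_gojobori_ks("GCTGGT", "GCTGGT")
        assert (r.ka, r.ks) == (0.0, 0.0)

    def test_synonymous_only_change_in_context(self):
        # TTT->TTC is Phe->Phe: one synonymous difference. In a longer
        # identical context p_s stays below the Jukes-Cantor ceiling, so
        # ks > 0 while ka = 0 (hand check: TTT and TTC each contribute 1/3
        # synonymous site; GCT contributes 1).
        ctx = "GCT" * 99
        r = dup.nei_gojobori_ks(ctx + "TTT", ctx + "TTC")
        assert r.ka == 0.0
        assert r.ks > 0
        assert r.sd == 1.0
        assert r.s_sites == pytest.approx(99 + 1 / 3)

    def test_bare_synonymous_codon_pair_saturates(self):
        # a lone codon with one synonymous difference has p_s = 3 >= 3/4
        r = dup.nei_gojobori_ks("TTT", "TTC")
        assert r.ks is None and r.saturated

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(["GCT", "GGA", "ACC", "TTC", "CAT"], 60))
        b = list(a)
        for i in rng.choice(len(b), 25, replace=False):
            old = b[i]
            b[i] = "ACGT"[int(rng.integers(4))]
            codon = "".join(b[3 * (i // 3): 3 * (i // 3) + 3])
            if dup.translate_codon(codon) == "*":
                b[i] = old  # keep both sequences stop-free
        b = "".join(b)
        ra = dup.nei_gojobori_ks(a, b)
        rb = dup.nei_gojobori_ks(b, a)
        assert ra == rb

    def test_gapped_codons_dropped(self):
        r = dup.nei_gojobori_ks("GCT---GGT", "GCTGGAGGT")
        assert r.n_codons == 2
        assert (r.ka, r.ks) == (0.0, 0.0)

    def test_length_mismatch_and_frame_errors(self):
        with pytest.raises(ValueError):
            dup.nei_gojobori_ks("GCT", "GCTGCT")
        with pytest.raises(ValueError):
            dup.nei_gojobori_ks("GCTG", "GCTA")

    def test_agrees_with_reference_implementation(self):
        warnings.filterwarnings("ignore")
        from Bio.Align import Alignment as BioAlignment
        from Bio.Align import analysis

        rng = np.random.default_rng(29)
        cfg = ScenarioConfig(n_codons=200, pairs_per_target=1, ks_targets=(0.3, 0.8))
        data = generate_duplicates(cfg, seed=6)
        for row in data["pairs"]:
            a, b = data["cds"][row["gene_a"]], data["cds"][row["gene_b"]]
            dn, ds = analysis.calculate_dn_ds(BioAlignment([a, b]), method="NG86")
            r = dup.nei_gojobori_ks(a, b)
            assert r.ka == pytest.approx(dn, abs=1e-9)
            assert r.ks == pytest.approx(ds, abs=1e-9)


class TestClockDating:
    def test_zero_ks_zero_age(self):
        assert dup.date_duplication(0.0) == 0.0

    def test_hand_arithmetic(self):
        # 0.182 / (2 * 9.1e-9) = 1e7 years = 10 Mya
        assert dup.date_duplication(0.182) == pytest.approx(10.0)

    def test_linear_in_ks(self):
        t1 = dup.date_duplication(0.25)
        t2 = dup.date_duplication(0.5)
        assert t2 == pytest.approx(2 * t1)

    def test_undefined_ks_propagates(self):
        assert dup.date_duplication(None) is None

    def test_invalid_clock_rejected(self):
        with pytest.raises(ValueError):
            dup.ClockParams(0.0)


class TestBuildPair:
    def test_identical_pair_flagged_recent(self):
        p = dup.build_pair("a", "b", "GCTGGT", "GCTGGT", "tandem")
        assert "recent" in p.flags and p.time_mya == 0.0

    def test_ks_round_trip_within_estimator_error(self):
        cfg = ScenarioConfig(n_codons=300, pairs_per_target=3)
        data = generate_duplicates(cfg, seed=8)
        for row in data["pairs"]:
            p = dup.build_pair(
                row["gene_a"],
                row["gene_b"],
                data["cds"][row["gene_a"]],
                data["cds"][row["gene_b"]],
                "segmental",
            )
            expected_age = row["ks_target"] / (2 * 9.1e-9) / 1e6
            assert p.ka == 0.0
            assert p.time_mya == pytest.approx(expected_age, rel=0.2)


class TestPairTable:
    def test_empty_input(self):
        assert dup.pair_table([]).empty

    def test_single_group_count(self):
        pairs = [
            dup.DuplicationPair("a1", "a2", "segmental", 0.0, 0.2, 11.0),
            dup.DuplicationPair("a3", "a4", "segmental", 0.0, 0.4, 22.0),
            dup.DuplicationPair("a5", "a6", "tandem", 0.0, 0.1, 5.5),
        ]
        groups = {g: "E" for p in pairs for g in (p.gene_a, p.gene_b)}
        table = dup.pair_table(pairs, groups)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["group"] == "E" and row["n_pairs"] == 3
        assert row["n_tandem"] == 1 and row["n_segmental"] == 2
        assert (row["t_min_mya"], row["t_max_mya"]) == (5.5, 22.0)

    def test_group_ranges_bracket_planted_ages(self):
        cfg = ScenarioConfig(pairs_per_target=2)
        data = generate_duplicates(cfg, seed=4)
        pairs = [
            dup.build_pair(
                r["gene_a"], r["gene_b"], data["cds"][r["gene_a"]],
                data["cds"][r["gene_b"]], r["true_dup_type"],
            )
            for r in data["pairs"]
        ]
        table = dup.pair_table(pairs)
        ages = [r["expected_age_mya"] for r in data["pairs"]]
        assert table.iloc[0]["t_min_mya"] <= min(ages) * 1.2
        assert table.iloc[0]["t_max_mya"] >= max(ages) * 0.8

    def test_mean_ks_by_block(self):
        pairs = [
            dup.DuplicationPair("a", "b", "segmental", 0.0, 0.2, 11.0),
            dup.DuplicationPair("c", "d", "segmental", 0.0, 0.4, 22.0),
        ]
        blocks = {("a", "b"): "blk1", ("c", "d"): "blk1"}
        assert dup.mean_ks_by_block(pairs, blocks) == {"blk1": pytest.approx(0.3)}


from hypothesis import given, settings
from hypothesis import strategies as st


class TestClusterProperties:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        starts=st.lists(st.integers(0, 1_500_000), min_size=1, max_size=25),
        window=st.integers(1, 500_000),
    )
    def test_single_linkage_equals_transitive_closure(self, starts, window):
        loci = [
            GeneLocus(f"g{i}", "chr1", s, s + 1000) for i, s in enumerate(starts)
        ]
        got = sorted((c.chrom, tuple(c.member_ids)) for c in dup.detect_clusters(loci, window))
        assert got == oracle_clusters(loci, window, 2)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(0.0, 0.74))
    def test_dating_monotone_in_ks(self, p):
        ks = dup.jukes_cantor(p)
        assert dup.date_duplication(ks + 0.01) > dup.date_duplication(ks)

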