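"""Windows, the in-package aligner, single linkage and dereplication."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seclocus.io_formats import GeneOrder, ProteinRecord, SimilarityEdge
from seclocus.neighborhoods import (
    Cluster,
    ClusteringParams,
    all_pairs_similarity,
    cluster_size_histogram,
    conservation_report,
    dereplicate,
    extract_windows,
    pairwise_identity_coverage,
    single_linkage,
)
from seclocus.synthetic_data import generate_marker_set


def linear_order(n, replicon="c1", genome="g", circular=False):
    records = [
        ProteinRecord(f"{genome}|g{i:04d}", genome, replicon_id=replicon,
                      index_on_replicon=i, length=1)
        for i in range(n)
    ]
    return GeneOrder(records=records, circular={replicon: circular})


class TestExtractWindows:
    def test_focal_at_origin_truncates_upstream(self):
        order = linear_order(15)
        (window,) = extract_windows(order, ["g|g0000"])
        assert len(window.neighbors) == 10
        assert all(off > 0 for _pid, off in window.neighbors)

    def test_mid_replicon_full_window(self):
        order = linear_order(30)
        (window,) = extract_windows(order, ["g|g0015"])
        offsets = sorted(off for _pid, off in window.neighbors)
        assert offsets == [o for o in range(-10, 11) if o != 0]

    def test_circular_wraparound_deduplicates(self):
        order = linear_order(12, circular=True)
        (window,) = extract_windows(order, ["g|g0000"])
        # 11 other genes, each at most once
        ids = [pid for pid, _off in window.neighbors]
        assert len(ids) == len(set(ids)) == 11

    def test_offset_equals_rank_distance(self):
        order = linear_order(25)
        (window,) = extract_windows(order, ["g|g0007"])
        for pid, off in window.neighbors:
            rank = int(pid.split("g")[-1])
            assert rank - 7 == off
            assert abs(off) <= 10

    def test_absent_focal_protein_is_an_error(self):
        order = linear_order(5)
        with pytest.raises(KeyError, match="nope"):
            extract_windows(order, ["nope"])

    def test_each_focal_occurrence_gets_a_window(self):
        order = linear_order(30)
        windows = extract_windows(order, ["g|g0002", "g|g0020"])
        assert [w.focal_protein_id for w in windows] == ["g|g0002", "g|g0020"]


class TestPairwiseAlignment:
    def test_identical_sequences(self):
        edge = pairwise_identity_coverage("a", "MKTAYIAKQRQISFVK", "b", "MKTAYIAKQRQISFVK")
        assert edge.percent_identity == pytest.approx(100.0)
        assert edge.coverage_a == pytest.approx(1.0)
        assert edge.coverage_b == pytest.approx(1.0)

    def test_disjoint_alphabets_give_zero_edge(self):
        edge = pairwise_identity_coverage("a", "KKKKKKKKKK", "b", "DDDDDDDDDD")
        assert edge.percent_identity == 0.0
        assert edge.coverage_a == 0.0

    def test_non_amino_acid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            pairwise_identity_coverage("a", "MKT1", "b", "MKT")

    def test_score_matches_naive_affine_dp(self):
        """The aligner's optimum equals an independent Gotoh DP oracle."""
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")

        def gotoh_local_score(s, t, open_=-11.0, extend=-1.0):
            n, m = len(s), len(t)
            NEG = -1e9
            M = np.full((n + 1, m + 1), 0.0)
            X = np.full((n + 1, m + 1), NEG)  # gap in t
            Y = np.full((n + 1, m + 1), NEG)  # gap in s
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    sub = blosum[s[i - 1], t[j - 1]]
                    M[i, j] = max(0.0, sub + max(M[i - 1, j - 1], X[i - 1, j - 1],
                                                 Y[i - 1, j - 1]))
                    X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend)
                    Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend)
                    best = max(best, M[i, j])
            return best

        rng = np.random.default_rng(3)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        from seclocus.neighborhoods import _aligner

        for _ in range(20):
            s = "".join(rng.choice(aa, size=rng.integers(10, 40)))
            t = "".join(rng.choice(aa, size=rng.integers(10, 40)))
            expected = gotoh_local_score(s, t)
            alignments = _aligner().align(s, t)
            score = alignments.score if len(alignments) else 0.0
            assert score == pytest.approx(max(expected, 0.0))

    def test_identity_recomputed_from_alignment_columns(self):
        # one substitution in an otherwise identical pair
        s = "MKTAYIAKQRQISFVKSHFSRQ"
        t = "MKTAYIAKQRWISFVKSHFSRQ"
        edge = pairwise_identity_coverage("a", s, "b", t)
        assert edge.percent_identity == pytest.approx(100 * 21 / 22)
        assert edge.coverage_a == pytest.approx(1.0)


class TestSingleLinkage:
    PARAMS = ClusteringParams(25.0, 0.60, "both")

    def test_transitive_chain_forms_one_cluster(self):
        edges = [
            SimilarityEdge("A", "B", 40, 0.9, 0.9),
            SimilarityEdge("B", "C", 40, 0.9, 0.9),
            SimilarityEdge("A", "C", 10, 0.9, 0.9),  # below threshold
        ]
        clusters = single_linkage(["A", "B", "C"], edges, self.PARAMS)
        assert clusters[0].members == ("A", "B", "C")

    def test_thresholds_inclusive_at_boundary(self):
        edge = SimilarityEdge("A", "B", 25.0, 0.60, 0.60)
        clusters = single_linkage(["A", "B"], [edge], self.PARAMS)
        assert clusters[0].size == 2

    def test_either_coverage_rule(self):
        edge = SimilarityEdge("A", "B", 40.0, 0.9, 0.3)
        both = single_linkage(["A", "B"], [edge], ClusteringParams(25, 0.6, "both"))
        either = single_linkage(["A", "B"], [edge], ClusteringParams(25, 0.6, "either"))
        assert both[0].size == 1
        assert either[0].size == 2

    def test_singletons_included(self):
        clusters = single_linkage(["A", "B"], [], self.PARAMS)
        assert [c.size for c in clusters] == [1, 1]

    def test_endpoint_outside_node_set_rejected(self):
        with pytest.raises(ValueError):
            single_linkage(["A"], [SimilarityEdge("A", "Z", 90, 1, 1)], self.PARAMS)

    def test_matches_bruteforce_components(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(2, 30))
            nodes = [f"n{i:02d}" for i in range(n)]
            edges = []
            adj = np.eye(n, dtype=bool)
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.08:
                    ident = float(rng.uniform(0, 100))
                    cov = float(rng.uniform(0, 1))
                    edges.append(SimilarityEdge(nodes[i], nodes[j], ident, cov, cov))
                    if ident >= 25.0 and cov >= 0.60:
                        adj[i, j] = adj[j, i] = True
            # brute force: boolean transitive closure
            reach = adj.copy()
            for _ in range(n):
                reach = reach | (reach @ reach)
            expected = {
                frozenset(nodes[j] for j in range(n) if reach[i, j]) for i in range(n)
            }
            got = {
                frozenset(c.members)
                for c in single_linkage(nodes, edges, self.PARAMS)
            }
            assert got == expected

    @given(st.permutations(range(5)))
    def test_invariant_to_input_order(self, perm):
        nodes = ["A", "B", "C", "D", "E"]
        edges = [
            SimilarityEdge("A", "B", 40, 0.9, 0.9),
            SimilarityEdge("C", "D", 40, 0.9, 0.9),
            SimilarityEdge("B", "E", 40, 0.9, 0.9),
        ]
        base = single_linkage(nodes, edges, self.PARAMS)
        shuffled = single_linkage([nodes[i] for i in perm], edges[::-1], self.PARAMS)
        assert base == shuffled

    def test_raising_thresholds_refines_clusters(self):
        rng = np.random.default_rng(23)
        nodes = [f"n{i}" for i in range(20)]
        edges = [
            SimilarityEdge(a, b, float(rng.uniform(0, 100)),
                           float(rng.uniform(0, 1)), float(rng.uniform(0, 1)))
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.3
        ]
        loose = single_linkage(nodes, edges, ClusteringParams(25, 0.3))
        strict = single_linkage(nodes, edges, ClusteringParams(60, 0.8))
        loose_sets = [set(c.members) for c in loose]
        for cluster in strict:
            assert any(set(cluster.members) <= s for s in loose_sets)


class TestConservationReport:
    def test_planted_locus_families_rank_top3(
        self, small_pangenome, small_similarity, small_bundle_dir
    ):
        from seclocus.io_formats import read_gene_order

        bundle, truth = small_pangenome
        order = read_gene_order(small_bundle_dir / "genes.gff")
        windows = extract_windows(order, truth.secondary_ids)
        members = sorted(set().union(*(w.member_ids for w in windows)))
        clusters = single_linkage(members, small_similarity, ClusteringParams())
        genome_of = {m: m.split("|")[0] for m in members}
        report = conservation_report(clusters, windows, genome_of)
        member_of = {c.cluster_id: c.members for c in clusters}
        top_families = {
            truth.intended_cluster[member_of[cid][0]]
            for cid in report.head(3)["cluster_id"]
        }
        assert top_families == {"cluster1", "cluster2", "cluster3"}

    def test_single_offset_cluster_distribution(self):
        from seclocus.neighborhoods import NeighborhoodWindow

        windows = [
            NeighborhoodWindow("f1", "g1", "r1", (("a", 1),)),
            NeighborhoodWindow("f2", "g2", "r2", (("b", 1),)),
        ]
        clusters = [Cluster("C1", ("a", "b"))]
        report = conservation_report(clusters, windows, {"a": "g1", "b": "g2"})
        assert report.loc[0, "offsets"] == "1,1"
        assert report.loc[0, "n_windows"] == 2
        assert report.loc[0, "n_genomes"] == 2

    def test_empty_window_set_gives_empty_report(self):
        report = conservation_report([], [])
        assert report.empty

    def test_size_histogram_counts_clusters_by_size(self):
        clusters = [Cluster("C1", ("a", "b", "c")), Cluster("C2", ("d", "e")),
                    Cluster("C3", ("f",)), Cluster("C4", ("g",))]
        hist = cluster_size_histogram(clusters)
        assert dict(zip(hist["cluster_size"], hist["n_clusters"])) == {1: 2, 2: 1, 3: 1}


class TestDereplicate:
    def test_identical_markers_collapse_to_one(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        records = [
            ProteinRecord("g1|m", "g1", sequence=seq),
            ProteinRecord("g2|m", "g2", sequence=seq),
        ]
        assert dereplicate(records) == ["g1"]

    def test_dissimilar_markers_all_retained(self):
        rng = np.random.default_rng(9)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        records = [
            ProteinRecord(f"g{i}|m", f"g{i}",
                          sequence="".join(rng.choice(aa, size=80)))
            for i in range(4)
        ]
        assert len(dereplicate(records)) == 4

    def test_planted_clone_groups_yield_one_representative_each(self):
        records, group_of = generate_marker_set(n_genomes=15, n_groups=5, seed=2)
        representatives = dereplicate(records)
        assert len(representatives) == 5
        assert {group_of[g] for g in representatives} == set(range(5))

    def test_representative_is_longest_then_lexicographic(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        records = [
            ProteinRecord("g2|m", "g2", sequence=seq),
            ProteinRecord("g1|m", "g1", sequence=seq + "AAAA"),
        ]
        assert dereplicate(records) == ["g1"]
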