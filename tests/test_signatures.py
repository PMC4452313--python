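import pytest
from hypothesis import given
from hypothesis import strategies as st

from seclocus.io_formats import DomainHit
from seclocus.signatures import (
    DomainArchitecture,
    Signature,
    architectures_from_hits,
    classify_copies,
    detect_rearrangement,
    find_homologs,
    infer_signature,
    merge_intervals,
)


def arch(pid, *domains):
    """Build an architecture from (name, start, end[, bit]) tuples."""
    hits = []
    for d in domains:
        name, start, end = d[:3]
        bit = d[3] if len(d) > 3 else 50.0
        hits.append(DomainHit(pid, name, start, end, 1e-10, bit, True))
    return DomainArchitecture(pid, tuple(hits))


SECA_REFS = [
    arch(f"ref{i}|secA",
         ("SecA_DEAD", 1, 390, 500.0),
         ("SecA_PP_bind", 395, 470, 90.0),
         ("SecA_SW", 480, 629, 160.0))
    for i in range(4)
]


class TestMergeIntervals:
    def test_overlapping_and_touching_merge(self):
        assert merge_intervals([(1, 10), (5, 20), (21, 30), (40, 45)]) == [
            (1, 30), (40, 45)
        ]


class TestInferSignature:
    def test_single_shared_domain(self):
        refs = [arch("a", ("D", 1, 50)), arch("b", ("D", 5, 60))]
        sig = infer_signature("X", refs)
        assert sig.required_domains == frozenset({"D"})

    def test_longest_universal_domain_wins(self):
        sig = infer_signature("SecA", SECA_REFS)
        assert sig.required_domains == frozenset({"SecA_DEAD"})

    def test_equal_lengths_and_bits_break_lexicographically(self):
        refs = [
            arch("a", ("B", 1, 100, 50.0), ("A", 200, 299, 50.0)),
            arch("b", ("A", 1, 100, 50.0), ("B", 200, 299, 50.0)),
        ]
        sig = infer_signature("X", refs)
        assert sig.required_domains == frozenset({"A"})

    def test_bit_score_breaks_length_ties(self):
        refs = [
            arch("a", ("A", 1, 100, 10.0), ("B", 200, 299, 90.0)),
            arch("b", ("A", 1, 100, 10.0), ("B", 200, 299, 90.0)),
        ]
        assert infer_signature("X", refs).required_domains == frozenset({"B"})

    def test_empty_intersection_returns_covering_set(self):
        refs = [arch("a", ("P", 1, 50)), arch("b", ("Q", 1, 50)),
                arch("c", ("P", 1, 50))]
        sig = infer_signature("X", refs)
        assert sig.required_domains == frozenset({"P", "Q"})

    def test_no_small_cover_is_an_error(self):
        refs = [arch(c, (c.upper(), 1, 10)) for c in "abcd"]
        with pytest.raises(ValueError, match="no signature"):
            infer_signature("X", refs, max_cover_size=3)

    @given(st.permutations(range(4)))
    def test_permutation_invariance(self, perm):
        refs = [SECA_REFS[i] for i in perm]
        assert infer_signature("SecA", refs) == infer_signature("SecA", SECA_REFS)

    def test_self_consistency_references_are_homologs(self):
        sig = infer_signature("SecA", SECA_REFS)
        hits = [h for a in SECA_REFS for h in a.ordered_domains]
        genome_of = {a.protein_id: a.protein_id.split("|")[0] for a in SECA_REFS}
        homologs = find_homologs(sig, hits, genome_of)
        found = {pid for pids in homologs.values() for pid in pids}
        assert found == {a.protein_id for a in SECA_REFS}


class TestFindHomologs:
    def test_duplicate_signature_domain_counts_once(self):
        hits = [
            DomainHit("p1", "D", 1, 50, 1e-5, 40, True),
            DomainHit("p1", "D", 60, 110, 1e-5, 40, True),
        ]
        result = find_homologs(Signature("X", frozenset({"D"})), hits, {"p1": "g1"})
        assert result == {"g1": ["p1"]}

    def test_zero_hit_genomes_listed_explicitly(self):
        hits = [DomainHit("p1", "D", 1, 50, 1e-5, 40, True)]
        result = find_homologs(
            Signature("X", frozenset({"D"})), hits, {"p1": "g1"}, genomes=["g1", "g2"]
        )
        assert result == {"g1": ["p1"], "g2": []}

    def test_cooccurrence_signature_requires_every_domain(self):
        hits = [
            DomainHit("p1", "D", 1, 50, 1e-5, 40, True),
            DomainHit("p2", "D", 1, 50, 1e-5, 40, True),
            DomainHit("p2", "E", 60, 90, 1e-5, 40, True),
        ]
        result = find_homologs(
            Signature("X", frozenset({"D", "E"})), hits, {"p1": "g", "p2": "g"}
        )
        assert result == {"g": ["p2"]}

    def test_synthetic_bundle_multicopy_genomes_match_planted_locus(
        self, small_pangenome
    ):
        bundle, truth = small_pangenome
        sig = Signature("SecA", frozenset({"SecA_DEAD"}))
        genome_of = {h.protein_id: h.protein_id.split("|")[0] for h in bundle.domain_hits}
        homologs = find_homologs(sig, bundle.domain_hits, genome_of)
        multi = {g for g, pids in homologs.items() if len(pids) >= 2}
        assert multi == set(truth.locus_positions)


class TestClassifyCopies:
    MODEL = 150

    def _call(self, copies_hits, **kw):
        genome_map = {"g": sorted({h.protein_id for h in copies_hits})}
        return classify_copies("SecA", genome_map, copies_hits, "SecA_SW",
                               model_length=self.MODEL, **kw)

    def test_single_full_copy_is_canonical(self):
        hits = [
            DomainHit("p1", "SecA_DEAD", 1, 390, 1e-100, 500, True),
            DomainHit("p1", "SecA_SW", 400, 549, 1e-40, 160, True),
        ]
        (call,) = self._call(hits)
        assert call.copy_count == 1
        assert call.copies == (("p1", "canonical"),)

    def test_copy_lacking_discriminator_is_secondary(self):
        hits = [
            DomainHit("p1", "SecA_DEAD", 1, 390, 1e-100, 500, True),
            DomainHit("p1", "SecA_SW", 400, 549, 1e-40, 160, True),
            DomainHit("p2", "SecA_DEAD", 1, 390, 1e-90, 450, True),
        ]
        (call,) = self._call(hits)
        assert dict(call.copies) == {"p1": "canonical", "p2": "secondary"}

    @pytest.mark.parametrize(
        "sw_len,expected",
        [(73, "secondary"), (75, "canonical")],  # 73/150 < 0.5 <= 75/150
    )
    def test_half_coverage_boundary_inclusive_on_canonical_side(self, sw_len, expected):
        hits = [
            DomainHit("p1", "SecA_DEAD", 1, 390, 1e-90, 450, True),
            DomainHit("p1", "SecA_SW", 400, 399 + sw_len, 1e-4, 20, False),
        ]
        (call,) = self._call(hits)
        assert call.copies == (("p1", expected),)

    def test_split_fragments_merge_before_coverage(self):
        # two overlapping fragments must not double-count coverage
        hits = [
            DomainHit("p1", "SecA_DEAD", 1, 390, 1e-90, 450, True),
            DomainHit("p1", "SecA_SW", 400, 449, 1e-4, 20, False),
            DomainHit("p1", "SecA_SW", 430, 469, 1e-4, 20, False),
        ]
        (call,) = self._call(hits)  # merged envelope 70 aa < 75
        assert call.copies == (("p1", "secondary"),)

    def test_two_canonical_copies_marked_ambiguous(self):
        hits = []
        for pid in ("p1", "p2"):
            hits += [
                DomainHit(pid, "SecA_DEAD", 1, 390, 1e-90, 450, True),
                DomainHit(pid, "SecA_SW", 400, 549, 1e-40, 160, True),
            ]
        (call,) = self._call(hits)
        assert set(call.classes) == {"ambiguous"}

    @given(st.integers(1, 150))
    def test_monotone_in_fragment_fraction(self, sw_len):
        hits = [
            DomainHit("p1", "SecA_DEAD", 1, 390, 1e-90, 450, True),
            DomainHit("p1", "SecA_SW", 400, 399 + sw_len, 1e-4, 20, False),
        ]
        classes = []
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
            (call,) = self._call(hits, fragment_fraction=frac)
            classes.append(call.copies[0][1])
        # raising the threshold can only flip canonical -> secondary
        seen_secondary = False
        for cls in classes:
            if cls == "secondary":
                seen_secondary = True
            assert not (seen_secondary and cls == "canonical")

    def test_unknown_model_length_falls_back_with_warning(self):
        hits = [
            DomainHit("p1", "SecA_DEAD", 1, 390, 1e-90, 450, True),
            DomainHit("p1", "SecA_SW", 400, 549, 1e-40, 160, True),
        ]
        with pytest.warns(UserWarning, match="longest observed"):
            (call,) = classify_copies("SecA", {"g": ["p1"]}, hits, "SecA_SW")
        assert call.copies == (("p1", "canonical"),)


class TestDetectRearrangement:
    REF = arch("ref", ("SecA_DEAD", 1, 390), ("SecA_SW", 400, 549))

    def test_identical_architecture_not_flagged(self):
        query = arch("q", ("SecA_DEAD", 1, 390), ("SecA_SW", 400, 549))
        assert not detect_rearrangement(query, self.REF, "SecA_SW").flag

    def test_split_watched_domain_flagged(self):
        query = arch(
            "q",
            ("SecA_SW", 1, 60),
            ("SecA_DEAD", 100, 489),
            ("SecA_SW", 500, 589),
        )
        call = detect_rearrangement(query, self.REF, "SecA_SW")
        assert call.flag and "split" in call.description

    def test_reversed_shared_order_flagged(self):
        query = arch("q", ("SecA_SW", 1, 150), ("SecA_DEAD", 160, 549))
        call = detect_rearrangement(query, self.REF, "SecA_SW")
        assert call.flag and "order" in call.description

    def test_small_gap_below_threshold_not_flagged(self):
        query = arch(
            "q", ("SecA_DEAD", 1, 390), ("SecA_SW", 400, 449), ("SecA_SW", 470, 549)
        )
        assert not detect_rearrangement(query, self.REF, "SecA_SW", gap_threshold=30).flag

    def test_watched_domain_absent_from_reference_is_error(self):
        query = arch("q", ("SecA_DEAD", 1, 390), ("Other", 400, 500))
        ref = arch("r", ("SecA_DEAD", 1, 390))
        with pytest.raises(ValueError):
            detect_rearrangement(query, ref, "Other")


class TestArchitectures:
    def test_ordered_by_envelope_start(self):
        hits = [
            DomainHit("p", "B", 100, 200, 1e-5, 40, True),
            DomainHit("p", "A", 1, 50, 1e-5, 40, True),
        ]
        archs = architectures_from_hits(hits)
        assert archs["p"].architecture_string == "A-B"
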