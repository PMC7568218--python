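"""Fingerprint construction, binary cosine similarity, pair enumeration, bins."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenolink import (
    DEFAULT_BINS,
    Fingerprint,
    ScoreBin,
    bin_scores,
    build_fingerprints,
    build_universe,
    candidate_pair_count,
    cosine_similarity,
    enumerate_similar_pairs,
)
from phenolink.errors import (
    BinSpecError,
    DimensionError,
    InsufficientInputError,
    UndefinedSimilarityError,
    UniverseError,
)
from phenolink.fingerprints import SimilarityRecord, validate_bins
from phenolink.pairs import DiseasePair
from phenolink.simulate import SimulationConfig, simulate_knowledge_graph

from conftest import curie, make_graph

PREFIXES = ("ORPHA", "OMIM", "UMLS")


def fp(bits, dim=16, disease="GARD:1"):
    return Fingerprint(disease=curie(disease), bits=frozenset(bits), dim=dim)


def dense_cosine(a: Fingerprint, b: Fingerprint) -> float:
    """Independent oracle: dense 0/1 vectors, numpy dot product over norms."""
    va = np.zeros(a.dim)
    vb = np.zeros(b.dim)
    va[list(a.bits)] = 1.0
    vb[list(b.bits)] = 1.0
    return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


class TestUniverse:
    def test_pooled_distinct_entries(self):
        g = make_graph([("GARD:1", ["ORPHA:1", "OMIM:2"]), ("GARD:2", ["OMIM:2", "UMLS:C3"])])
        uni = build_universe(g, "GARD", PREFIXES)
        assert [str(e) for e in uni.entries] == ["OMIM:2", "ORPHA:1", "UMLS:C3"]
        assert len(uni) == 3

    def test_dialects_collapse_to_one_entry(self):
        g = make_graph([("GARD:1", ["ORPHANET:945", "ORPHA:945"])])
        assert len(build_universe(g, "GARD", PREFIXES)) == 1

    def test_empty_universe_is_error(self):
        g = make_graph([("GARD:1", [])])
        with pytest.raises(UniverseError):
            build_universe(g, "GARD", PREFIXES)

    def test_dimension_matches_simulator_bookkeeping(self, noise_free_graph):
        graph, truth = noise_free_graph
        uni = build_universe(graph, "GARD", PREFIXES)
        assert len(uni) == truth.expected_universe_size


class TestCosine:
    def test_identical_triple_mapping_scores_one(self):
        shared = ["ORPHA:2311", "UMLS:C0265343", "OMIM:277300"]
        g = make_graph([("GARD:0006798", shared), ("GARD:0010726", shared)])
        uni = build_universe(g, "GARD", PREFIXES)
        fps = build_fingerprints(g, uni, "GARD", PREFIXES)
        score = cosine_similarity(fps[curie("GARD:0006798")], fps[curie("GARD:0010726")])
        assert score == 1.0

    def test_disjoint_scores_zero(self):
        assert cosine_similarity(fp({0, 1}), fp({2, 3})) == 0.0

    def test_one_of_two_shared(self):
        # |a|=1, |b|=2, 1 shared: 1/sqrt(2) (reported as 0.71 at 2 dp)
        score = cosine_similarity(fp({0}), fp({0, 1}))
        assert score == pytest.approx(1 / math.sqrt(2))
        assert f"{score:.2f}" == "0.71"

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            cosine_similarity(fp({0}, dim=4), fp({0}, dim=5))

    def test_empty_fingerprint_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            cosine_similarity(fp(set()), fp({1}))

    @given(
        a=st.sets(st.integers(0, 15), min_size=1),
        b=st.sets(st.integers(0, 15), min_size=1),
    )
    def test_set_form_equals_dense_oracle(self, a, b):
        got = cosine_similarity(fp(a), fp(b, disease="GARD:2"))
        assert got == pytest.approx(dense_cosine(fp(a), fp(b)), abs=1e-12)

    @given(
        a=st.sets(st.integers(0, 15), min_size=1),
        b=st.sets(st.integers(0, 15), min_size=1),
    )
    def test_symmetry_bounds_and_extremes(self, a, b):
        s = cosine_similarity(fp(a), fp(b))
        assert s == cosine_similarity(fp(b), fp(a))
        assert 0.0 <= s <= 1.0
        assert (s == 1.0) == (a == b)
        assert (s == 0.0) == (not a & b)

    @given(
        a=st.sets(st.integers(0, 14), min_size=1),
        b=st.sets(st.integers(0, 14), min_size=1),
    )
    def test_monotone_in_shared_and_unshared_bits(self, a, b):
        base = cosine_similarity(fp(a), fp(b))
        # adding a mapping shared by both never decreases the score
        grown = cosine_similarity(fp(a | {15}), fp(b | {15}))
        assert grown >= base - 1e-12
        # adding an unshared mapping to one side never increases it
        if 15 not in b:
            lopsided = cosine_similarity(fp(a | {15}), fp(b))
            assert lopsided <= base + 1e-12


class TestCandidatePairCount:
    def test_closed_form(self):
        assert candidate_pair_count(2) == 1
        assert candidate_pair_count(5236) == 13_705_230

    @given(st.integers(0, 10_000))
    def test_matches_binomial(self, n):
        assert candidate_pair_count(n) == math.comb(n, 2)


class TestEnumerateSimilarPairs:
    def brute_force(self, graph):
        """Exhaustive double loop over all eligible pairs."""
        uni = build_universe(graph, "GARD", PREFIXES)
        fps = build_fingerprints(graph, uni, "GARD", PREFIXES)
        out = []
        for d1, d2 in itertools.combinations(sorted(fps, key=str), 2):
            score = cosine_similarity(fps[d1], fps[d2])
            if score > 0:
                shared = fps[d1].bits & fps[d2].bits
                out.append(
                    SimilarityRecord(
                        pair=DiseasePair(d1, d2),
                        score=score,
                        n_shared=len(shared),
                        shared=frozenset(uni.entries[i] for i in shared),
                    )
                )
        out.sort(key=lambda r: (-r.score, r.pair))
        return out

    def test_no_shared_xref_gives_empty_list(self):
        g = make_graph([("GARD:1", ["OMIM:1"]), ("GARD:2", ["OMIM:2"])])
        assert enumerate_similar_pairs(g, "GARD", PREFIXES) == []

    def test_fewer_than_two_eligible_raises(self):
        g = make_graph([("GARD:1", ["OMIM:1"]), ("GARD:2", [])])
        with pytest.raises(InsufficientInputError):
            enumerate_similar_pairs(g, "GARD", PREFIXES)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_synthetic_graphs(self, seed):
        cfg = SimulationConfig(
            seed=seed, n_diseases=30, n_duplicate_pairs=3, n_subtype_pairs=3,
            n_sibling_families=2, family_size=3, n_collision_pairs=2,
        )
        graph, _ = simulate_knowledge_graph(cfg)
        assert enumerate_similar_pairs(graph, "GARD", PREFIXES) == self.brute_force(graph)

    def test_invariant_under_node_order_permutation(self, noise_free_graph):
        graph, _ = noise_free_graph
        from phenolink import KnowledgeGraph

        shuffled = KnowledgeGraph(
            nodes=dict(sorted(graph.nodes.items(), key=lambda kv: str(kv[0]), reverse=True)),
            tree_edges=graph.tree_edges,
            phenotype_edges=graph.phenotype_edges,
            gene_edges=graph.gene_edges,
        )
        assert enumerate_similar_pairs(shuffled, "GARD", PREFIXES) == enumerate_similar_pairs(
            graph, "GARD", PREFIXES
        )


class TestBins:
    def rec(self, score):
        return SimilarityRecord(
            pair=DiseasePair(curie("GARD:1"), curie("GARD:2")), score=score, n_shared=1
        )

    def test_default_layout_counts(self):
        counts = bin_scores([self.rec(s) for s in (1.0, 0.6, 0.3)])
        assert list(counts.values()) == [1, 1, 1]

    def test_empty_input_all_zero(self):
        assert all(v == 0 for v in bin_scores([]).values())

    def test_boundary_membership(self):
        counts = bin_scores([self.rec(0.5), self.rec(1.0), self.rec(0.499999)])
        assert counts["similarity = 1"] == 1
        assert counts["0.5 <= similarity < 1"] == 1
        assert counts["0 < similarity < 0.5"] == 1

    @pytest.mark.parametrize(
        "bad",
        [
            (ScoreBin("a", 0.0, 0.6, lo_open=True), ScoreBin("b", 0.5, 1.0)),  # overlap
            (ScoreBin("a", 0.0, 0.4, lo_open=True), ScoreBin("b", 0.5, 1.0)),  # gap
            (ScoreBin("a", 0.0, 1.0, lo_open=True, hi_open=True),),  # open at 1
            (),
        ],
    )
    def test_bad_specifications_rejected(self, bad):
        with pytest.raises(BinSpecError):
            validate_bins(list(bad))

    def test_counts_match_per_record_membership_oracle(self):
        rng = np.random.default_rng(42)
        records = [self.rec(float(s)) for s in rng.uniform(1e-9, 1.0, size=200)]
        counts = bin_scores(records, DEFAULT_BINS)
        # independent per-record classification
        oracle = {b.label: 0 for b in DEFAULT_BINS}
        for r in records:
            hits = [b.label for b in DEFAULT_BINS if b.contains(r.score)]
            assert len(hits) == 1
            oracle[hits[0]] += 1
        assert counts == oracle
        assert sum(counts.values()) == len(records)
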