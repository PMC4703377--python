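"""Context counting, G² weighting, composition, cosine, inventories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histmine.corpus_io import Thesaurus
from histmine.dsm import (ContextVector, CooccurrenceCounts, DsmConfig,
                          build_inventory, compose_bam, compose_bmm, cosine,
                          count_contexts, export_pairs, g2_statistic,
                          llr_weight, read_vectors, select_source_terms,
                          term_frequencies, top_k_neighbors, write_vectors,
                          TermInventory, NeighborList)
from histmine.preprocess import build_vocabulary

from conftest import make_tokens


def _vocab_from(streams, stop=frozenset()):
    return build_vocabulary(streams, cap=150_000, stopwords=stop)


class TestCountContexts:
    def test_window_hand_simulation(self):
        # "the fever caused death", window 3, stopset {the}:
        # slots for "fever" are {cause, death} once each
        stream = make_tokens([[("the", "the", "DET"), ("fever", "fever", "NOUN"),
                               ("caused", "cause", "VERB"),
                               ("death", "death", "NOUN")]])
        vocab = _vocab_from([stream], stop=frozenset({"the"}))
        counts = count_contexts([stream], ["fever"], DsmConfig(), vocab)
        assert counts.counts["fever"] == {"cause": 1, "death": 1}

    def test_term_at_sentence_start_collects_right_only(self):
        stream = make_tokens([[("fever", "fever", "NOUN"),
                               ("spread", "spread", "VERB"),
                               ("rapidly", "rapidly", "OTHER")]])
        vocab = _vocab_from([stream])
        counts = count_contexts([stream], ["fever"], DsmConfig(window=2), vocab)
        assert counts.counts["fever"] == {"spread": 1, "rapidly": 1}

    def test_multiword_window_from_phrase_boundaries(self):
        # interior words are never context; window hugs the phrase edges
        sent = [("rash", "rash", "NOUN"), ("then", "then", "OTHER"),
                ("scarlet", "scarlet", "ADJ"), ("fever", "fever", "NOUN"),
                ("killed", "kill", "VERB"), ("him", "him", "OTHER")]
        stream = make_tokens([sent])
        vocab = _vocab_from([stream])
        counts = count_contexts([stream], ["scarlet fever"],
                                DsmConfig(window=2), vocab)
        assert counts.counts["scarlet fever"] == {
            "rash": 1, "then": 1, "kill": 1, "him": 1}

    def test_window_truncates_at_sentence_boundary(self):
        stream = make_tokens([
            [("plague", "plague", "NOUN"), ("ended", "end", "VERB")],
            [("cholera", "cholera", "NOUN"), ("began", "begin", "VERB")],
        ])
        vocab = _vocab_from([stream])
        counts = count_contexts([stream], ["plague"], DsmConfig(window=3), vocab)
        assert "cholera" not in counts.counts["plague"]

    def test_empty_term_list_rejected(self):
        with pytest.raises(ValueError):
            count_contexts([], [], DsmConfig(), _vocab_from([]))

    def test_marginals_consistent(self, small_corpus_tokens):
        vocab = _vocab_from(small_corpus_tokens)
        counts = count_contexts(small_corpus_tokens, ["fever", "town"],
                                DsmConfig(), vocab)
        assert counts.total == sum(counts.term_totals().values())
        assert counts.total == sum(counts.unit_totals().values())


class TestG2:
    def test_independent_table_scores_zero(self):
        assert g2_statistic(10, 10, 10, 10) == 0.0

    def test_derived_value_against_direct_formula(self):
        # frozen from independent evaluation of
        # G² = 2 Σ k ln(k/E) on the table (30, 70 / 170, 730)
        assert g2_statistic(30, 70, 170, 730) == pytest.approx(
            6.337901126684379, rel=1e-12)

    def test_zero_k11_clamped_in_llr(self):
        counts = CooccurrenceCounts({"a": {"u": 0, "v": 10}, "b": {"u": 5}})
        vecs = llr_weight(counts)
        assert "u" not in vecs["a"].weights  # k11 = 0 <= E11 -> weight 0

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            g2_statistic(-1, 1, 1, 1)

    @given(st.tuples(st.integers(0, 200), st.integers(0, 200),
                     st.integers(0, 200), st.integers(0, 200)))
    @settings(deadline=None, derandomize=True)
    def test_matches_scipy_log_likelihood(self, cells):
        """scipy's log-likelihood power divergence is an independent oracle."""
        from scipy.stats import chi2_contingency
        k11, k12, k21, k22 = cells
        table = np.array([[k11, k12], [k21, k22]], dtype=float)
        # chi2_contingency needs positive marginals
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            return
        expected, _, _, _ = chi2_contingency(table, correction=False,
                                             lambda_="log-likelihood")
        assert g2_statistic(k11, k12, k21, k22) == pytest.approx(
            float(expected), rel=1e-10, abs=1e-10)


class TestComposition:
    def test_bam_hand_sum(self):
        a = ContextVector("a", "SA", {"a": 2.0, "b": 1.0})
        b = ContextVector("b", "SA", {"b": 3.0})
        assert compose_bam([a, b]).weights == {"a": 2.0, "b": 4.0}

    def test_bmm_hand_product(self):
        a = ContextVector("a", "SA", {"a": 2.0, "b": 3.0})
        b = ContextVector("b", "SA", {"b": 4.0, "c": 5.0})
        assert compose_bmm([a, b]).weights == {"b": 12.0}

    def test_disjoint_supports_give_zero_vector(self):
        a = ContextVector("a", "SA", {"a": 2.0})
        b = ContextVector("b", "SA", {"b": 4.0})
        assert compose_bmm([a, b]).weights == {}

    def test_composition_of_one_is_identity(self):
        v = ContextVector("v", "SA", {"x": 1.5, "y": 0.5})
        assert compose_bam([v]).weights == v.weights
        assert compose_bmm([v]).weights == v.weights

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compose_bam([])
        with pytest.raises(ValueError):
            compose_bmm([])

    @given(st.lists(
        st.dictionaries(st.sampled_from("abcdefgh"),
                        st.floats(0.01, 10.0), max_size=6),
        min_size=1, max_size=4))
    @settings(deadline=None, derandomize=True)
    def test_support_laws(self, weight_maps):
        vecs = [ContextVector(f"t{i}", "SA", w)
                for i, w in enumerate(weight_maps)]
        union = set().union(*(set(w) for w in weight_maps))
        inter = set(weight_maps[0])
        for w in weight_maps[1:]:
            inter &= set(w)
        assert set(compose_bam(vecs).weights) == union
        assert set(compose_bmm(vecs).weights) == inter


class TestCosine:
    def test_self_similarity_is_one(self):
        v = ContextVector("v", "SA", {"a": 2.0, "b": 1.0})
        assert cosine(v, v) == pytest.approx(1.0)

    def test_disjoint_supports_are_orthogonal(self):
        a = ContextVector("a", "SA", {"a": 1.0})
        b = ContextVector("b", "SA", {"b": 1.0})
        assert cosine(a, b) == 0.0

    def test_hand_value(self):
        a = ContextVector("a", "SA", {"a": 1.0, "b": 1.0})
        b = ContextVector("b", "SA", {"a": 1.0})
        assert cosine(a, b) == pytest.approx(1.0 / math.sqrt(2))

    def test_zero_vector_yields_zero(self):
        z = ContextVector("z", "SA", {})
        v = ContextVector("v", "SA", {"a": 1.0})
        assert cosine(z, v) == 0.0

    @given(st.dictionaries(st.sampled_from("abcde"), st.floats(0.01, 10.0),
                           min_size=1, max_size=5),
           st.dictionaries(st.sampled_from("abcde"), st.floats(0.01, 10.0),
                           min_size=1, max_size=5))
    @settings(deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, w1, w2):
        a = ContextVector("a", "SA", w1)
        b = ContextVector("b", "SA", w2)
        assert cosine(a, b) == pytest.approx(cosine(b, a))
        assert 0.0 <= cosine(a, b) <= 1.0

    @given(st.dictionaries(st.sampled_from("abcde"), st.floats(0.01, 10.0),
                           min_size=1, max_size=5),
           st.floats(0.1, 10.0))
    @settings(deadline=None, derandomize=True)
    def test_scaling_invariance(self, w, scale):
        a = ContextVector("a", "SA", w)
        b = ContextVector("b", "SA", {k: v * scale for k, v in w.items()})
        assert cosine(a, b) == pytest.approx(1.0)


class TestTopK:
    VECTORS = {
        "src": ContextVector("src", "SA", {"x": 1.0, "y": 1.0}),
        "near": ContextVector("near", "SA", {"x": 1.0, "y": 1.0}),
        "tie1": ContextVector("tie1", "SA", {"x": 1.0}),
        "tie2": ContextVector("tie2", "SA", {"y": 1.0}),
    }

    def test_k_exceeding_pool_returns_all(self):
        nl = top_k_neighbors("src", ["near", "tie1"], self.VECTORS, k=20)
        assert len(nl.neighbors) == 2

    def test_equal_similarities_break_lexicographically(self):
        nl = top_k_neighbors("src", ["tie2", "tie1"], self.VECTORS, k=2)
        assert nl.targets() == ["tie1", "tie2"]

    def test_source_excluded_from_own_list(self):
        nl = top_k_neighbors("src", ["src", "near"], self.VECTORS, k=5)
        assert "src" not in nl.targets()

    def test_missing_source_vector_rejected(self):
        with pytest.raises(KeyError):
            top_k_neighbors("ghost", ["near"], self.VECTORS, k=1)


class TestSelectSourceTerms:
    CONFIG = DsmConfig()

    def test_count_exactly_at_lower_bound_excluded(self):
        assert select_source_terms({"t": 20}, None, self.CONFIG) == []
        assert select_source_terms({"t": 21}, None, self.CONFIG) == ["t"]

    def test_count_exactly_at_upper_bound_excluded(self):
        assert select_source_terms({"t": 1000}, None, self.CONFIG) == []
        assert select_source_terms({"t": 999}, None, self.CONFIG) == ["t"]

    def test_fewer_qualifiers_than_n_sources(self):
        freqs = {"a": 30, "b": 40, "c": 50}
        assert select_source_terms(freqs, None, self.CONFIG) == ["c", "b", "a"]

    def test_thesaurus_restriction(self):
        thes = Thesaurus({"C1": {"plague"}})
        freqs = {"plague": 30, "uncovered": 30}
        assert select_source_terms(freqs, thes, self.CONFIG) == ["plague"]


class TestExportPairs:
    def _inv(self, lists):
        return TermInventory(
            {s: NeighborList(s, tuple(items)) for s, items in lists.items()},
            {})

    def test_threshold_is_inclusive(self):
        inv = self._inv({"a": [("b", 0.8)]})
        assert export_pairs(inv, 0.8) == [("a", "b", 0.8)]

    def test_all_below_threshold_is_empty(self):
        inv = self._inv({"a": [("b", 0.79)]})
        assert export_pairs(inv, 0.8) == []

    def test_unordered_dedup_keeps_max(self):
        inv = self._inv({"a": [("b", 0.9)], "b": [("a", 0.85)]})
        assert export_pairs(inv, 0.8) == [("a", "b", 0.9)]


class TestInventory:
    def test_planted_synonym_recovered(self, sa_inventory_noiseless,
                                       noiseless_corpus):
        hits = 0
        for source, nlist in sa_inventory_noiseless:
            syns = noiseless_corpus.thesaurus.synonyms_of(source)
            if syns & set(nlist.targets()):
                hits += 1
        assert hits == len(sa_inventory_noiseless)

    def test_k_one_caps_list_length(self, noiseless_corpus):
        inv = build_inventory(noiseless_corpus.documents[:10],
                              noiseless_corpus.terms,
                              DsmConfig(model="SA", k=1))
        assert all(len(nl.neighbors) <= 1 for _, nl in inv)

    def test_sa_and_bam_coincide_for_single_word_sources(self, noiseless_corpus):
        docs = noiseless_corpus.documents[:15]
        terms = noiseless_corpus.terms
        sa = build_inventory(docs, terms, DsmConfig(model="SA"))
        bam = build_inventory(docs, terms, DsmConfig(model="BAM"))
        for source in sa.lists:
            assert " " not in source
            assert sa.lists[source].targets() == bam.lists[source].targets()

    def test_term_frequencies_longest_match(self):
        stream = make_tokens([[("scarlet", "scarlet", "ADJ"),
                               ("fever", "fever", "NOUN"),
                               ("and", "and", "OTHER"),
                               ("fever", "fever", "NOUN")]])
        freqs = term_frequencies([stream], ["scarlet fever", "fever"])
        assert freqs["scarlet fever"] == 1
        assert freqs["fever"] == 1  # the occurrence inside the phrase is not counted

    def test_vector_store_round_trip(self, tmp_path):
        vecs = {
            "plague": ContextVector("plague", "SA", {"death": 2.5, "rat": 1.25}),
            "scarlet fever": ContextVector("scarlet fever", "BAM", {"rash": 0.5}),
        }
        path = tmp_path / "vectors.tsv"
        write_vectors(vecs, path)
        got = read_vectors(path)
        assert got.keys() == vecs.keys()
        for term in vecs:
            assert got[term].weights == vecs[term].weights
            assert got[term].model == vecs[term].model
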