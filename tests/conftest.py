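"""Shared fixtures: synthetic corpora and the inventories built from them.

Corpus generation and inventory building are the expensive steps, so they
are session-scoped; tests must not mutate them.
"""

import pytest

from histmine.dsm import DsmConfig, build_inventory
from histmine.preprocess import Token, lemmatize_pos, tokenize
from histmine.synthgen import SynthConfig, generate_corpus


def make_tokens(lemma_sentences):
    """Hand-built token streams with exact lemmas (oracle-friendly).

    ``lemma_sentences`` is a list of lists of (surface, lemma, pos)
    triples; offsets are synthesized as if words were space-joined.
    """
    tokens = []
    pos_cursor = 0
    for si, sent in enumerate(lemma_sentences):
        for surface, lemma, pos in sent:
            tokens.append(Token(surface, pos_cursor, pos_cursor + len(surface),
                                si, lemma, pos))
            pos_cursor += len(surface) + 1
    return tokens


@pytest.fixture(scope="session")
def noiseless_corpus():
    """Planted synonyms with noise-free concept signatures."""
    return generate_corpus(SynthConfig(seed=11, noise_rate=0.0))


@pytest.fixture(scope="session")
def default_corpus():
    """The bundled default scenario (10% window noise, single-word terms)."""
    return generate_corpus(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def multiword_corpus():
    """Default scenario with half the concepts using two-word terms."""
    return generate_corpus(SynthConfig(seed=23, multiword_fraction=0.5))


@pytest.fixture(scope="session")
def sa_inventory_noiseless(noiseless_corpus):
    return build_inventory(noiseless_corpus.documents, noiseless_corpus.terms,
                           DsmConfig(model="SA"), corpus_id="noiseless")


@pytest.fixture(scope="session")
def small_corpus_tokens():
    """A tiny preprocessed two-document corpus for windowing tests."""
    texts = [
        "The fever caused death. Fever spread in the town.",
        "Severe fever and cough. The town suffered greatly.",
    ]
    return [lemmatize_pos(tokenize(t)) for t in texts]
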