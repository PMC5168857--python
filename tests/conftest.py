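"""Shared fixtures: packaged examples and synthetic-corpus materialization."""

from io import StringIO

import pytest

from ino_mine import (
    generate_corpus,
    load_dictionary,
    load_lexicon,
    packaged_examples,
    read_conllu,
    read_corpus,
)


@pytest.fixture(scope="session")
def examples():
    return packaged_examples()


@pytest.fixture(scope="session")
def chain_ontology():
    """Three-term chain: regulation <- regulation_of_transcription <- promoter_based."""
    tsv = (
        "iri\tlabel\tparents\tkeywords\tdep_patterns\n"
        "T:root\tregulation\t\tregulates\t\n"
        "T:mid\tregulation of transcription\tT:root\ttranscription//regulated\t\n"
        "T:leaf\tpromoter-based regulation\tT:mid\tpromoter//regulated\t\n"
    )
    return load_dictionary(StringIO(tsv))


def materialize(bundle):
    """Turn a FixtureBundle's text artifacts into pipeline inputs."""
    ontology = load_dictionary(StringIO(bundle.dictionary))
    lexicon = load_lexicon(StringIO(bundle.lexicon))
    sentences = list(read_corpus(StringIO(bundle.corpus)))
    parses = {g.sentence_ref: g for _, g in read_conllu(StringIO(bundle.conllu))}
    return ontology, lexicon, sentences, parses


def gold_set(bundle):
    """The generator's gold records as a set of comparable tuples."""
    rows = bundle.gold.strip().split("\n")[1:]
    return {tuple(line.split("\t")) for line in rows}


def record_set(network):
    return {
        (r.sentence_id, r.entity_a, r.entity_b, r.term_iri, r.evidence,
         "//".join(r.keywords))
        for r in network.records
    }


@pytest.fixture(scope="session")
def synthetic_bundle():
    from ino_mine import FixtureConfig

    return generate_corpus(
        FixtureConfig(n_sentences=40, p_direct_edge=1.0, distractor_rate=0.0, seed=11)
    )
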