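"""Sentence classification -> typed gene-gene interaction records -> network.

Eligibility follows the mining rule: a sentence contributes interaction
records iff it has at least two distinct tagged entities and at least one
trigger-keyword mention.  Within an eligible sentence every unordered
entity pair is combined with the best-evidenced match per interaction type
(all-pairs pairing over-generates on sentences where only some pairs truly
interact; the run manifest flags this as a known false-positive source).

Records are undirected at the network level: the pair is stored in
canonical lexicographic order, direction surviving only inside the
evidence (the governor/dependent roles of the matched edge).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Optional, Sequence

import networkx as nx

from .depgraph import DependencyGraph, PatternMatch, classify_sentence
from .errors import InoMineError
from .ontology import Ontology
from .tagging import Lexicon, Mention, Sentence, tag_entities, tag_keywords

__all__ = [
    "InteractionRecord",
    "InteractionNetwork",
    "extract_interactions",
    "run_corpus",
    "write_network",
    "read_network_tsv",
    "NETWORK_COLUMNS",
]

logger = logging.getLogger(__name__)

Evidence = Literal["direct_dependency", "cooccurrence", "single_keyword"]
_EVIDENCE_RANK = {"direct_dependency": 0, "cooccurrence": 1, "single_keyword": 2}

NETWORK_COLUMNS = (
    "entity_a",
    "entity_b",
    "sentence_id",
    "term_iri",
    "term_label",
    "keywords",
    "evidence",
)


@dataclass(frozen=True)
class InteractionRecord:
    """One typed interaction between a canonical gene pair in one sentence."""

    sentence_id: str
    entity_a: str
    entity_b: str
    term_iri: str
    keywords: tuple[str, ...]
    evidence: Evidence

    def __post_init__(self):
        if self.entity_a == self.entity_b:
            raise ValueError("self-interaction records are not allowed")
        if self.entity_a > self.entity_b:
            raise ValueError("entity pair must be in canonical (sorted) order")
        if not self.keywords:
            raise ValueError("record must cite at least one keyword")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.entity_a, self.entity_b)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.entity_a, self.entity_b, self.sentence_id, self.term_iri)


@dataclass
class InteractionNetwork:
    """Undirected gene-gene network; each edge carries its evidence records."""

    edges: dict[tuple[str, str], list[InteractionRecord]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return {n for pair in self.edges for n in pair}

    @property
    def records(self) -> list[InteractionRecord]:
        return [r for pair in sorted(self.edges) for r in self.edges[pair]]

    def add(self, record: InteractionRecord) -> None:
        bucket = self.edges.setdefault(record.pair, [])
        if any(r.key == record.key for r in bucket):
            return  # at most one record per (pair, sentence, term)
        bucket.append(record)
        bucket.sort(key=lambda r: (r.sentence_id, r.term_iri))

    def __len__(self) -> int:
        return sum(len(v) for v in self.edges.values())


def _evidence_of(match: PatternMatch) -> Evidence:
    if match.evidence == "direct_dependency":
        return "direct_dependency"
    return "cooccurrence" if len(match.keyword_mentions) >= 2 else "single_keyword"


def extract_interactions(
    sentence: Sentence,
    graph: Optional[DependencyGraph],
    ontology: Ontology,
    lexicon: Lexicon,
    entity_mentions: Optional[Sequence[Mention]] = None,
    keyword_mentions: Optional[Sequence[Mention]] = None,
) -> list[InteractionRecord]:
    """Extract typed interaction records from one sentence.

    Pre-tagged mentions may be supplied; otherwise tagging runs here.
    Returns ``[]`` unless the sentence has >= 2 distinct entities and >= 1
    keyword mention.  For each interaction type matched in the sentence the
    top-ranked match is kept and crossed with every unordered entity pair.
    """
    if entity_mentions is None:
        entity_mentions = tag_entities(sentence, lexicon)
    if keyword_mentions is None:
        keyword_mentions = tag_keywords(sentence, ontology)
    symbols = sorted({m.ref for m in entity_mentions})
    if len(symbols) < 2 or not keyword_mentions:
        return []
    matches = classify_sentence(sentence, graph, keyword_mentions, ontology)
    best_per_term: dict[str, PatternMatch] = {}
    for m in matches:  # already ranked: first hit per term is its best
        best_per_term.setdefault(m.term_iri, m)
    records: list[InteractionRecord] = []
    for i in range(len(symbols)):
        for j in range(i + 1, len(symbols)):
            for iri in sorted(best_per_term):
                m = best_per_term[iri]
                records.append(
                    InteractionRecord(
                        sentence_id=sentence.id,
                        entity_a=symbols[i],
                        entity_b=symbols[j],
                        term_iri=iri,
                        keywords=tuple(x.matched for x in m.keyword_mentions),
                        evidence=_evidence_of(m),
                    )
                )
    return records


def run_corpus(
    corpus: Iterable[Sentence],
    parses: dict[str, DependencyGraph],
    ontology: Ontology,
    lexicon: Lexicon,
    require_parses: bool = False,
) -> tuple[InteractionNetwork, dict]:
    """Run extraction over a corpus; returns (network, run manifest).

    Sentences without a parse fall back to co-occurrence-only matching
    (logged), unless ``require_parses`` is set, in which case a missing
    parse is an error.  The manifest reports sentence, eligibility, record
    and term counts; the result is independent of sentence order.
    """
    network = InteractionNetwork()
    n_sentences = n_eligible = n_missing = 0
    term_iris: set[str] = set()
    for sentence in corpus:
        n_sentences += 1
        graph = parses.get(sentence.id)
        if graph is None:
            if require_parses:
                raise InoMineError(f"no parse for sentence {sentence.id!r}")
            n_missing += 1
            logger.warning(
                "sentence %r has no parse; co-occurrence-only matching", sentence.id
            )
        records = extract_interactions(sentence, graph, ontology, lexicon)
        if records:
            n_eligible += 1
        for r in records:
            term_iris.add(r.term_iri)
            network.add(r)
    manifest = {
        "sentences": n_sentences,
        "eligible_sentences": n_eligible,
        "sentences_without_parse": n_missing,
        "records": len(network),
        "distinct_terms": len(term_iris),
        "distinct_pairs": len(network.edges),
        "note": "all-pairs entity pairing within a sentence can over-generate "
        "pairs relative to manually annotated gold pairs",
    }
    return network, manifest


def _sorted_records(network: InteractionNetwork) -> list[InteractionRecord]:
    return sorted(network.records, key=lambda r: r.key)


def write_network(
    network: InteractionNetwork,
    stream: IO[str],
    fmt: str = "tsv",
    ontology: Optional[Ontology] = None,
) -> None:
    """Serialize the network as ``tsv``, ``json``, ``graphml`` or ``sif``.

    TSV rows are sorted by (pair, sentence, term) and round-trip through
    :func:`read_network_tsv`.  Term labels are filled from ``ontology``
    when given.
    """

    def label(iri: str) -> str:
        if ontology is not None and iri in ontology:
            return ontology[iri].label
        return ""

    records = _sorted_records(network)
    if fmt == "tsv":
        stream.write("\t".join(NETWORK_COLUMNS) + "\n")
        for r in records:
            stream.write(
                "\t".join(
                    [
                        r.entity_a,
                        r.entity_b,
                        r.sentence_id,
                        r.term_iri,
                        label(r.term_iri),
                        "//".join(r.keywords),
                        r.evidence,
                    ]
                )
                + "\n"
            )
    elif fmt == "json":
        json.dump(
            [
                {
                    "entity_a": r.entity_a,
                    "entity_b": r.entity_b,
                    "sentence_id": r.sentence_id,
                    "term_iri": r.term_iri,
                    "term_label": label(r.term_iri),
                    "keywords": list(r.keywords),
                    "evidence": r.evidence,
                }
                for r in records
            ],
            stream,
            indent=2,
        )
        stream.write("\n")
    elif fmt == "graphml":
        g = nx.MultiGraph()
        g.add_nodes_from(sorted(network.nodes))
        for r in records:
            g.add_edge(
                r.entity_a,
                r.entity_b,
                sentence_id=r.sentence_id,
                term_iri=r.term_iri,
                term_label=label(r.term_iri),
                keywords="//".join(r.keywords),
                evidence=r.evidence,
            )
        for line in nx.generate_graphml(g):
            stream.write(line + "\n")
    elif fmt == "sif":
        seen: set[tuple[str, str, str]] = set()
        for r in records:
            row = (r.entity_a, r.term_iri, r.entity_b)
            if row not in seen:
                seen.add(row)
                stream.write("\t".join(row) + "\n")
    else:
        raise InoMineError(f"unknown network format {fmt!r}")


def read_network_tsv(source: IO[str] | str) -> InteractionNetwork:
    """Read a network TSV written by :func:`write_network`."""
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            return read_network_tsv(fh)
    network = InteractionNetwork()
    header = source.readline().rstrip("\n").split("\t")
    if tuple(header) != NETWORK_COLUMNS:
        raise InoMineError(f"unexpected network TSV header {header}")
    for line in source:
        line = line.rstrip("\n")
        if not line:
            continue
        a, b, sid, iri, _, kws, ev = line.split("\t")
        network.add(
            InteractionRecord(
                sentence_id=sid,
                entity_a=a,
                entity_b=b,
                term_iri=iri,
                keywords=tuple(kws.split("//")),
                evidence=ev,  # type: ignore[arg-type]
            )
        )
    return network
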