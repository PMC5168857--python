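"""Dependency graphs, CoNLL-U I/O, and trigger-pair matching.

The central rule of the method lives here: two trigger keywords in one
sentence are considered *related* — jointly signalling one interaction type
— when they are directly connected by a single dependency edge.  Keyword
pairs that only co-occur without such an edge are kept as weaker,
co-occurrence-level evidence.

Edges are stored as ``(governor, dependent, label)`` token-index triples.
Connectivity ignores edge direction; pattern matching respects the
governor/dependent roles written in the dictionary (``nsubj(control,
expression)``).  Enhanced-representation subtype labels (``nmod:of``) are
normalized to their base (``nmod``) before comparison with dictionary
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Literal, NamedTuple, Optional, Sequence

from .errors import ConlluParseError, InvalidPairError
from .ontology import Ontology, base_label
from .tagging import Mention, Sentence, Token, keyword_matches_text

__all__ = [
    "DependencyGraph",
    "DirectConnection",
    "PatternMatch",
    "read_conllu",
    "write_conllu",
    "base_label",
    "directly_connected",
    "match_dependency_patterns",
    "match_cooccurrence_patterns",
    "classify_sentence",
]

Edge = tuple[int, int, str]  # (governor index, dependent index, label)


@dataclass(frozen=True)
class DependencyGraph:
    """Labeled directed dependency edges over one sentence's tokens.

    The root attachment (HEAD=0) is kept aside in ``root`` and never takes
    part in keyword connectivity.  Parallel edges between the same token
    pair are allowed with distinct labels (enhanced representations).
    """

    sentence_ref: str
    edges: frozenset[Edge]
    root: int | None = None

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


class DirectConnection(NamedTuple):
    gov_mention: Mention
    dep_mention: Mention
    label: str  # base label
    edge: Edge  # raw edge, original label


@dataclass(frozen=True)
class PatternMatch:
    """One interaction type assigned to a set of trigger mentions."""

    term_iri: str
    keyword_mentions: tuple[Mention, ...]
    evidence: Literal["direct_dependency", "cooccurrence"]
    edge: Optional[Edge] = None

    def __post_init__(self):
        if self.evidence == "direct_dependency" and self.edge is None:
            raise ValueError("direct_dependency match requires an edge")
        if self.evidence == "cooccurrence" and self.edge is not None:
            raise ValueError("cooccurrence match must not carry an edge")

    @property
    def mention_spans(self) -> frozenset[tuple[int, int]]:
        return frozenset((m.start, m.end) for m in self.keyword_mentions)


# ---------------------------------------------------------------------------
# CoNLL-U I/O


def read_conllu(source: IO[str] | str) -> list[tuple[Sentence, DependencyGraph]]:
    """Parse a CoNLL-U stream into (Sentence, DependencyGraph) pairs.

    Standard 10-column format: comment lines start with ``#`` (``# sent_id``
    is used as the sentence id when present), blank lines separate
    sentences.  Multiword-token ranges (``1-2``) and empty nodes (``1.1``)
    are skipped for graph purposes.  Basic-layer edges come from
    HEAD/DEPREL; the DEPS column contributes extra enhanced edges when
    filled.
    """
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            return read_conllu(fh)

    results: list[tuple[Sentence, DependencyGraph]] = []
    tokens: list[Token] = []
    edges: set[Edge] = set()
    root: int | None = None
    sent_id: str | None = None
    text: str | None = None
    count = 0

    def flush():
        nonlocal tokens, edges, root, sent_id, text, count
        if tokens:
            count += 1
            sid = sent_id if sent_id is not None else f"s{count}"
            sentence = Sentence(
                id=sid,
                text=text if text is not None else " ".join(t.surface for t in tokens),
                tokens=tokens,
            )
            graph = DependencyGraph(
                sentence_ref=sid, edges=frozenset(edges), root=root
            )
            results.append((sentence, graph))
        tokens, edges, root, sent_id, text = [], set(), None, None, None

    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("sent_id"):
                sent_id = body.split("=", 1)[1].strip() if "=" in body else sent_id
            elif body.startswith("text"):
                text = body.split("=", 1)[1].strip() if "=" in body else text
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ConlluParseError(
                f"expected 10 tab-separated columns, got {len(cols)}", lineno
            )
        tok_id, form, lemma, _, _, _, head, deprel, deps, _ = cols
        if "-" in tok_id or "." in tok_id:
            continue  # multiword range / empty node: no graph contribution
        try:
            idx = int(tok_id)
        except ValueError:
            raise ConlluParseError(f"non-integer token ID {tok_id!r}", lineno) from None
        if idx != len(tokens) + 1:
            raise ConlluParseError(
                f"token ID {idx} out of sequence (expected {len(tokens) + 1})", lineno
            )
        if not form:
            raise ConlluParseError("empty FORM", lineno)
        tokens.append(
            Token(index=idx, surface=form, lemma=None if lemma == "_" else lemma)
        )
        if head != "_":
            try:
                head_i = int(head)
            except ValueError:
                raise ConlluParseError(f"non-integer HEAD {head!r}", lineno) from None
            if head_i == 0:
                root = idx
            elif head_i > 0:
                if deprel == "_" or not deprel:
                    raise ConlluParseError("missing DEPREL for attached token", lineno)
                edges.add((head_i, idx, deprel))
        if deps and deps != "_":
            for item in deps.split("|"):
                if ":" not in item:
                    raise ConlluParseError(f"malformed DEPS item {item!r}", lineno)
                h, rel = item.split(":", 1)
                try:
                    h_i = int(h)
                except ValueError:
                    raise ConlluParseError(
                        f"non-integer DEPS head {h!r}", lineno
                    ) from None
                if h_i > 0:
                    edges.add((h_i, idx, rel))
    flush()

    # validate edge indices against token ranges
    for sentence, graph in results:
        n = len(sentence)
        for gov, dep, label in graph.edges:
            if not (1 <= gov <= n and 1 <= dep <= n):
                raise ConlluParseError(
                    f"edge ({gov},{dep},{label}) outside sentence {sentence.id!r} "
                    f"of length {n}"
                )
    return results


def write_conllu(
    pairs: Iterable[tuple[Sentence, DependencyGraph]], stream: IO[str]
) -> None:
    """Serialize (Sentence, DependencyGraph) pairs as basic-layer CoNLL-U.

    When a token carries several incoming edges the lexicographically first
    goes to HEAD/DEPREL and the rest to DEPS.
    """
    for sentence, graph in pairs:
        stream.write(f"# sent_id = {sentence.id}\n")
        stream.write(f"# text = {sentence.text}\n")
        incoming: dict[int, list[tuple[int, str]]] = {}
        for gov, dep, label in graph.sorted_edges():
            incoming.setdefault(dep, []).append((gov, label))
        for tok in sentence.tokens:
            if graph.root == tok.index:
                head, deprel = "0", "root"
                extra = incoming.get(tok.index, [])
            else:
                attached = incoming.get(tok.index, [])
                if attached:
                    head, deprel = str(attached[0][0]), attached[0][1]
                    extra = attached[1:]
                else:
                    head, deprel = "_", "_"
                    extra = []
            deps = "|".join(f"{h}:{r}" for h, r in extra) or "_"
            stream.write(
                "\t".join(
                    [
                        str(tok.index),
                        tok.surface,
                        tok.lemma or "_",
                        "_",
                        "_",
                        "_",
                        head,
                        deprel,
                        deps,
                        "_",
                    ]
                )
                + "\n"
            )
        stream.write("\n")


# ---------------------------------------------------------------------------
# Matching


def _span_tokens(m: Mention) -> range:
    return range(m.start, m.end + 1)


def directly_connected(
    graph: DependencyGraph, m1: Mention, m2: Mention
) -> Optional[DirectConnection]:
    """First dependency edge linking the two mention spans, if any.

    Direction is ignored for *connectivity* — the edge may run either way —
    but the returned tuple reports which mention sits on the governor side.
    Edges are scanned in ascending (governor, dependent, label) order, so
    the result is deterministic.  Overlapping mentions are rejected.
    """
    if m1.overlaps(m2):
        raise InvalidPairError(f"mentions overlap: {m1} / {m2}")
    s1, s2 = set(_span_tokens(m1)), set(_span_tokens(m2))
    for gov, dep, label in graph.sorted_edges():
        if gov in s1 and dep in s2:
            return DirectConnection(m1, m2, base_label(label), (gov, dep, label))
        if gov in s2 and dep in s1:
            return DirectConnection(m2, m1, base_label(label), (gov, dep, label))
    return None


def _distinct_spans(mentions: Sequence[Mention]) -> list[Mention]:
    """One representative mention per distinct (start, end, matched) span."""
    seen: dict[tuple[int, int, str], Mention] = {}
    for m in sorted(mentions, key=lambda m: (m.start, m.end, m.ref)):
        seen.setdefault((m.start, m.end, m.matched), m)
    return list(seen.values())


def _rebind(m: Mention, iri: str) -> Mention:
    return Mention(start=m.start, end=m.end, matched=m.matched, kind="keyword", ref=iri)


def match_dependency_patterns(
    sentence: Sentence,
    graph: DependencyGraph,
    keyword_mentions: Sequence[Mention],
    ontology: Ontology,
) -> list[PatternMatch]:
    """Match dictionary ``relation(governor, dependent)`` patterns on the graph.

    For every unordered pair of distinct keyword spans and every term, a
    pattern matches when an edge between the spans carries the pattern's
    base label, the governor-side mention text matches the governor keyword
    and the dependent-side text matches the dependent keyword (``GeneX-``
    placeholder and hyphen-suffix rules apply).  One match per
    (term, mention pair); deterministic order.
    """
    spans = _distinct_spans(keyword_mentions)
    out: list[PatternMatch] = []
    emitted: set[tuple[str, frozenset[tuple[int, int]]]] = set()
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            a, b = spans[i], spans[j]
            if a.overlaps(b):
                continue
            sa, sb = set(_span_tokens(a)), set(_span_tokens(b))
            for gov, dep, label in graph.sorted_edges():
                if gov in sa and dep in sb:
                    gov_m, dep_m = a, b
                elif gov in sb and dep in sa:
                    gov_m, dep_m = b, a
                else:
                    continue
                lab = base_label(label)
                for iri in sorted(ontology.terms):
                    term = ontology.terms[iri]
                    for dp in term.dep_patterns:
                        if dp.relation != lab:
                            continue
                        if not keyword_matches_text(dp.governor, gov_m.matched):
                            continue
                        if not keyword_matches_text(dp.dependent, dep_m.matched):
                            continue
                        key = (iri, frozenset({(a.start, a.end), (b.start, b.end)}))
                        if key in emitted:
                            continue
                        emitted.add(key)
                        out.append(
                            PatternMatch(
                                term_iri=iri,
                                keyword_mentions=tuple(
                                    _rebind(m, iri)
                                    for m in sorted(
                                        (gov_m, dep_m), key=lambda m: m.start
                                    )
                                ),
                                evidence="direct_dependency",
                                edge=(gov, dep, label),
                            )
                        )
    return out


def _best_assignment(
    keywords: Sequence[str], spans: Sequence[Mention]
) -> Optional[list[Mention]]:
    """Injective keyword -> mention assignment, leftmost-first.

    Backtracking search returning the assignment whose mention-position
    vector (in keyword order) is lexicographically smallest, or None when
    no full assignment exists.  Sizes are tiny (patterns have <= 4 keywords).
    """
    ordered = sorted(spans, key=lambda m: (m.start, m.end))

    def rec(k: int, used: set[int]) -> Optional[list[Mention]]:
        if k == len(keywords):
            return []
        for idx, m in enumerate(ordered):
            if idx in used:
                continue
            if keyword_matches_text(keywords[k], m.matched):
                rest = rec(k + 1, used | {idx})
                if rest is not None:
                    return [m] + rest
        return None

    return rec(0, set())


def match_cooccurrence_patterns(
    keyword_mentions: Sequence[Mention], ontology: Ontology
) -> list[PatternMatch]:
    """Match ``//`` keyword patterns by sentence-level co-occurrence.

    A pattern is covered when each of its keywords can be bound to a
    distinct keyword span (order-insensitive, leftmost available mention per
    keyword).  Single-keyword patterns need one mention.
    """
    spans = _distinct_spans(keyword_mentions)
    out: list[PatternMatch] = []
    for iri in sorted(ontology.terms):
        term = ontology.terms[iri]
        for pat in term.keyword_patterns:
            assignment = _best_assignment(pat.keywords, spans)
            if assignment is None:
                continue
            out.append(
                PatternMatch(
                    term_iri=iri,
                    keyword_mentions=tuple(
                        _rebind(m, iri)
                        for m in sorted(assignment, key=lambda m: m.start)
                    ),
                    evidence="cooccurrence",
                    edge=None,
                )
            )
    return out


_EVIDENCE_RANK = {"direct_dependency": 0, "cooccurrence": 1}


def _match_sort_key(ontology: Ontology, m: PatternMatch):
    return (
        _EVIDENCE_RANK[m.evidence],
        -ontology.depth(m.term_iri),
        m.term_iri,
        tuple(sorted((x.start, x.end) for x in m.keyword_mentions)),
        m.edge or (0, 0, ""),
    )


def classify_sentence(
    sentence: Sentence,
    graph: Optional[DependencyGraph],
    keyword_mentions: Sequence[Mention],
    ontology: Ontology,
) -> list[PatternMatch]:
    """Union of dependency and co-occurrence matches, ranked.

    De-duplicated per (term, mention-span set) keeping the stronger
    evidence; ranked by evidence (direct dependency first), then hierarchy
    depth (most specific first), then term IRI.  The ranking is total, so
    the output is invariant to input ordering.
    """
    if not keyword_mentions:
        return []
    matches: list[PatternMatch] = []
    if graph is not None:
        matches.extend(
            match_dependency_patterns(sentence, graph, keyword_mentions, ontology)
        )
    matches.extend(match_cooccurrence_patterns(keyword_mentions, ontology))
    best: dict[tuple[str, frozenset[tuple[int, int]]], PatternMatch] = {}
    for m in matches:
        key = (m.term_iri, m.mention_spans)
        cur = best.get(key)
        if cur is None or _match_sort_key(ontology, m) < _match_sort_key(ontology, cur):
            best[key] = m
    return sorted(best.values(), key=lambda m: _match_sort_key(ontology, m))
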