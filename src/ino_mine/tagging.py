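"""Sentence tokenization and dictionary tagging of trigger keywords and genes.

Tokenization is deliberately simple and deterministic: whitespace split,
then leading/trailing sentence punctuation is split off into its own tokens.
Hyphenated words stay intact (``sigmaK-dependent`` is one token) and
parentheses that are balanced inside a token are kept (``sigma(F)`` is one
token), since bacterial sigma-factor names are written that way.

Keyword matching is case-insensitive on the surface form (or on the lemma
when available and requested).  A dictionary keyword additionally matches a
hyphenated token that *ends* in it — ``dependent`` tags ``sigmaK-dependent``
— because regulation triggers are routinely realised as gene-prefixed
adjectives.  Gene/protein matching is exact and case-sensitive by default
(``sigE`` and ``SigE`` differ).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Literal

from .errors import EmptySentenceError, InvalidPairError
from .ontology import Ontology

__all__ = [
    "Token",
    "Sentence",
    "Mention",
    "Lexicon",
    "tokenize",
    "make_sentence",
    "tag_keywords",
    "tag_entities",
    "token_gap",
    "load_lexicon",
    "read_corpus",
    "keyword_matches_text",
]

#: characters split off token edges; hyphens are never stripped
_STRIP_CHARS = '.,;:!?"\'%'
_PUNCT_TOKENS = set('.,;:!?"\'%()[]{}-')


@dataclass(frozen=True)
class Token:
    index: int  # 1-based
    surface: str
    lemma: str | None = None

    @property
    def is_punct(self) -> bool:
        return all(c in _PUNCT_TOKENS for c in self.surface)


@dataclass
class Sentence:
    id: str
    text: str
    tokens: list[Token]

    def __post_init__(self):
        for i, tok in enumerate(self.tokens, start=1):
            if tok.index != i:
                raise ValueError(f"token indices must be 1..n without gaps, got {tok.index} at {i}")

    def span_text(self, start: int, end: int) -> str:
        return " ".join(t.surface for t in self.tokens[start - 1 : end])

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Mention:
    """A tagged span: a trigger keyword of one interaction type, or a gene."""

    start: int  # token index, inclusive
    end: int  # token index, inclusive
    matched: str  # normalized matched text
    kind: Literal["keyword", "entity"]
    ref: str  # term IRI (keyword) or canonical lexicon symbol (entity)

    def overlaps(self, other: "Mention") -> bool:
        return not (self.end < other.start or other.end < self.start)


def _split_token(word: str) -> list[str]:
    """Split leading/trailing punctuation off one whitespace-delimited chunk."""
    lead: list[str] = []
    trail: list[str] = []
    while word:
        c = word[0]
        if c in _STRIP_CHARS or (c == "(" and ")" not in word):
            lead.append(c)
            word = word[1:]
        else:
            break
    while word:
        c = word[-1]
        if c in _STRIP_CHARS or (c == ")" and "(" not in word):
            trail.append(c)
            word = word[:-1]
        else:
            break
    return [*lead, *( [word] if word else [] ), *reversed(trail)]


def tokenize(text: str) -> list[Token]:
    """Deterministic whitespace + edge-punctuation tokenizer (see module docs)."""
    if text is None or not text.strip():
        raise EmptySentenceError("cannot tokenize empty sentence")
    surfaces: list[str] = []
    for chunk in text.split():
        surfaces.extend(_split_token(chunk))
    return [Token(index=i, surface=s) for i, s in enumerate(surfaces, start=1)]


def make_sentence(sent_id: str, text: str) -> Sentence:
    return Sentence(id=sent_id, text=text, tokens=tokenize(text))


def keyword_matches_text(keyword: str, text: str) -> bool:
    """Does dictionary/pattern keyword ``keyword`` match normalized ``text``?

    Three routes: exact equality; the ``genex-`` placeholder (``genex-dependent``
    matches any hyphen-bearing token with suffix ``-dependent``); and the
    hyphen-suffix rule (``dependent`` matches ``sigmak-dependent``).
    """
    if keyword == text:
        return True
    if " " in text:  # suffix routes apply to single tokens only
        return False
    if keyword.startswith("genex-"):
        suffix = keyword[5:]  # "-dependent"
        return text.endswith(suffix) and len(text) > len(suffix)
    return text.endswith("-" + keyword) and len(text) > len(keyword) + 1


def _norm(s: str) -> str:
    return s.lower()


def tag_keywords(
    sentence: Sentence, ontology: Ontology, use_lemma: bool = False
) -> list[Mention]:
    """Tag trigger-keyword mentions by dictionary lookup.

    Every maximal token span whose normalized form matches a keyword of a
    term yields one :class:`Mention` per matching term.  Longest match wins
    at a given start position; matching is case-insensitive.  The result is
    sorted by (start, end, ref) and independent of dictionary row order.
    """
    idx = ontology.keyword_index()
    if not idx:
        return []
    max_len = max(len(kw.split()) for kw in idx)
    words = [
        (tok.lemma if use_lemma and tok.lemma else tok.surface) for tok in sentence.tokens
    ]
    norm_words = [_norm(w) for w in words]
    n = len(norm_words)
    mentions: list[Mention] = []
    start = 0
    while start < n:
        best_end = None
        best_hits: list[tuple[str, str]] = []  # (iri, matched text)
        for L in range(min(max_len, n - start), 0, -1):
            span = " ".join(norm_words[start : start + L])
            hits = [
                (iri, span)
                for kw, iris in idx.items()
                if keyword_matches_text(kw, span)
                for iri in iris
            ]
            if hits:
                best_end = start + L
                best_hits = hits
                break  # longest match wins at this start
        if best_end is None:
            start += 1
        else:
            for iri, span in sorted(set(best_hits)):
                mentions.append(
                    Mention(
                        start=start + 1,
                        end=best_end,
                        matched=span,
                        kind="keyword",
                        ref=iri,
                    )
                )
            start = best_end
    mentions.sort(key=lambda m: (m.start, m.end, m.ref))
    return mentions


@dataclass
class Lexicon:
    """Gene/protein symbol lexicon with synonym resolution."""

    canonical: dict[str, str] = field(default_factory=dict)  # surface -> symbol

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, Iterable[str]]]) -> "Lexicon":
        canon: dict[str, str] = {}
        for symbol, synonyms in rows:
            symbol = symbol.strip()
            if not symbol:
                continue
            canon.setdefault(symbol, symbol)
            for syn in synonyms:
                syn = syn.strip()
                if syn:
                    canon.setdefault(syn, symbol)
        return cls(canonical=canon)

    def __len__(self) -> int:
        return len(self.canonical)


def load_lexicon(source: IO[str] | str) -> Lexicon:
    """Read a lexicon TSV with columns ``symbol  synonyms`` ("|"-separated)."""
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            return load_lexicon(fh)
    reader = csv.DictReader(source, delimiter="\t")
    rows = []
    for row in reader:
        syns = (row.get("synonyms") or "").split("|")
        rows.append(((row.get("symbol") or ""), syns))
    return Lexicon.from_rows(rows)


def tag_entities(
    sentence: Sentence, lexicon: Lexicon, case_sensitive: bool = True
) -> list[Mention]:
    """Tag gene/protein mentions by exact span lookup in the lexicon.

    Case-sensitive by default (gene symbols are case-meaningful); longest
    match wins at a given start.  Entity mentions may overlap keyword
    mentions — they are different kinds.
    """
    if not lexicon.canonical:
        return []
    if case_sensitive:
        table = lexicon.canonical
        key = lambda s: s  # noqa: E731
    else:
        table = {k.lower(): v for k, v in lexicon.canonical.items()}
        key = str.lower
    max_len = max(len(k.split()) for k in table)
    words = [t.surface for t in sentence.tokens]
    n = len(words)
    mentions: list[Mention] = []
    start = 0
    while start < n:
        matched = False
        for L in range(min(max_len, n - start), 0, -1):
            span = " ".join(words[start : start + L])
            symbol = table.get(key(span))
            if symbol is not None:
                mentions.append(
                    Mention(
                        start=start + 1,
                        end=start + L,
                        matched=span,
                        kind="entity",
                        ref=symbol,
                    )
                )
                start += L
                matched = True
                break
        if not matched:
            start += 1
    return mentions


def token_gap(sentence: Sentence, m1: Mention, m2: Mention) -> int:
    """Number of *word* tokens strictly between two mentions.

    Punctuation tokens do not count, so in "The expression of rsfA is under
    the control ..." the triggers "expression" and "control" are 5 words
    apart.  Symmetric in its arguments; overlapping mentions are rejected.
    """
    if m1.overlaps(m2):
        raise InvalidPairError(f"mentions overlap: {m1} / {m2}")
    first, second = (m1, m2) if m1.end < m2.start else (m2, m1)
    for m in (first, second):
        if not (1 <= m.start <= m.end <= len(sentence)):
            raise InvalidPairError(f"mention {m} outside sentence {sentence.id!r}")
    between = sentence.tokens[first.end : second.start - 1]
    return sum(1 for t in between if not t.is_punct)


def read_corpus(source: IO[str] | str) -> Iterator[Sentence]:
    """Read a plain-text corpus: one sentence per line, optional ``id<TAB>`` prefix."""
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            yield from read_corpus(fh)
            return
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if "\t" in line:
            sent_id, text = line.split("\t", 1)
        else:
            sent_id, text = f"s{lineno}", line
        yield make_sentence(sent_id.strip(), text)
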