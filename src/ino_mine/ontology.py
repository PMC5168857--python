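"""Interaction-type dictionary: terms, keyword patterns, dependency patterns.

An interaction type (e.g. ``regulation of transcription``) is an ontology
class annotated with the textual evidence that signals it in a sentence:

* *keyword patterns* — one or more trigger keywords that jointly signal the
  type.  Components are separated by ``//`` in the annotation text, meaning
  the keywords co-occur in one sentence but need not be adjacent
  (``transcription//dependent``).
* *dependency patterns* — a single labeled grammatical relation between two
  trigger keywords, written ``relation(governor, dependent)``
  (``nsubj(control, expression)`` reads "expression is the nominal subject
  of control").

The dictionary is exchanged as a TSV with columns
``iri  label  parents  keywords  dep_patterns`` where ``parents`` and the
two pattern columns are ``|``-separated lists within a cell.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .errors import MalformedPatternError, OntologyError, TermNotFoundError

__all__ = [
    "KeywordPattern",
    "DependencyPatternSpec",
    "OntologyTerm",
    "Ontology",
    "parse_keyword_pattern",
    "parse_dependency_pattern",
    "load_dictionary",
    "write_dictionary",
    "ancestors",
    "extract_subset",
]

DICT_COLUMNS = ("iri", "label", "parents", "keywords", "dep_patterns")

#: base dependency label: lowercase letters/underscore (``nsubj``, ``acl``)
_LABEL_RE = re.compile(r"^[a-z_]+$")
_DEP_PATTERN_RE = re.compile(
    r"^\s*([A-Za-z_:]+)\s*\(\s*([^(),]+?)\s*,\s*([^(),]+?)\s*\)\s*$"
)


@dataclass(frozen=True)
class KeywordPattern:
    """A set of trigger keywords that jointly signal one interaction type.

    ``keywords`` preserves the order written in the annotation, but matching
    is order-insensitive: the dictionary lists both ``transcription//dependent``
    and ``regulated//transcription``, and sentences realise the components in
    either order.
    """

    keywords: tuple[str, ...]
    raw: str = field(compare=False)

    def __post_init__(self):
        if not self.keywords or any(not k for k in self.keywords):
            raise MalformedPatternError(f"empty keyword in pattern {self.raw!r}")

    @property
    def is_single(self) -> bool:
        return len(self.keywords) == 1

    def serialize(self) -> str:
        return "//".join(self.keywords)


@dataclass(frozen=True)
class DependencyPatternSpec:
    """``relation(governor, dependent)`` over trigger-keyword lemmas.

    The governor/dependent convention follows the Universal Dependencies
    reading: ``nsubj(control, expression)`` means "expression is the nominal
    subject of control".  ``relation`` is stored as a base label (subtype
    suffixes such as ``nmod:of`` are stripped to ``nmod``).
    """

    relation: str
    governor: str
    dependent: str

    def __post_init__(self):
        if not _LABEL_RE.match(self.relation):
            raise MalformedPatternError(
                f"bad dependency label {self.relation!r} (expected [a-z_]+)"
            )
        if not self.governor or not self.dependent:
            raise MalformedPatternError("governor/dependent must be non-empty")

    def serialize(self) -> str:
        return f"{self.relation}({self.governor}, {self.dependent})"


def parse_keyword_pattern(raw: str) -> KeywordPattern:
    """Parse a ``//``-separated keyword annotation into a :class:`KeywordPattern`.

    Components are trimmed and lowercased; single-keyword patterns (no
    ``//``) are valid.  Raises :class:`MalformedPatternError` on empty input
    or an empty component (``"a////b"``).
    """
    if raw is None or not raw.strip():
        raise MalformedPatternError("empty keyword pattern")
    parts = [p.strip().lower() for p in raw.split("//")]
    if any(not p for p in parts):
        raise MalformedPatternError(f"empty component in keyword pattern {raw!r}")
    return KeywordPattern(keywords=tuple(parts), raw=raw.strip())


def base_label(label: str) -> str:
    """Normalize an (enhanced) dependency label to its base: ``nmod:of`` -> ``nmod``."""
    return label.split(":", 1)[0].lower()


def parse_dependency_pattern(raw: str) -> DependencyPatternSpec:
    """Parse ``label(arg1, arg2)`` into a :class:`DependencyPatternSpec`.

    The label is lowercased and subtype-stripped; the two keyword arguments
    are lowercased.  Anything that is not exactly a two-argument application
    (missing parentheses or comma, extra arguments) raises
    :class:`MalformedPatternError`.
    """
    if raw is None or not raw.strip():
        raise MalformedPatternError("empty dependency pattern")
    m = _DEP_PATTERN_RE.match(raw)
    if not m:
        raise MalformedPatternError(f"malformed dependency pattern {raw!r}")
    rel, gov, dep = m.groups()
    return DependencyPatternSpec(
        relation=base_label(rel),
        governor=gov.strip().lower(),
        dependent=dep.strip().lower(),
    )


@dataclass
class OntologyTerm:
    """One interaction-type class with its hierarchy links and annotations."""

    iri: str
    label: str
    parent_iris: set[str] = field(default_factory=set)
    keyword_patterns: list[KeywordPattern] = field(default_factory=list)
    dep_patterns: list[DependencyPatternSpec] = field(default_factory=list)

    def all_keywords(self) -> set[str]:
        return {k for p in self.keyword_patterns for k in p.keywords}


class Ontology:
    """A validated, acyclic hierarchy of :class:`OntologyTerm`.

    Parents referenced but not defined in the file are tolerated as
    *external* (the dictionary is usually a subset of a larger ontology);
    they simply terminate ancestor walks.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        for t in terms:
            if t.iri in self.terms:
                raise OntologyError(f"duplicate IRI {t.iri!r}")
            self.terms[t.iri] = t
        self._check_acyclic()
        self._validate_dep_keywords()
        self._depth_cache: dict[str, int] = {}

    # -- structure ---------------------------------------------------------

    @property
    def roots(self) -> set[str]:
        return {
            iri
            for iri, t in self.terms.items()
            if not (t.parent_iris & self.terms.keys())
        }

    def external_parents(self) -> set[str]:
        return {
            p for t in self.terms.values() for p in t.parent_iris
        } - self.terms.keys()

    def _check_acyclic(self) -> None:
        # iterative three-color DFS over in-ontology parent links
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {iri: WHITE for iri in self.terms}
        for start in self.terms:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(sorted(self.terms[start].parent_iris)))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if parent not in self.terms:
                        continue
                    if color[parent] == GRAY:
                        raise OntologyError(
                            f"cyclic parent hierarchy involving {parent!r}"
                        )
                    if color[parent] == WHITE:
                        color[parent] = GRAY
                        stack.append(
                            (parent, iter(sorted(self.terms[parent].parent_iris)))
                        )
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    def _validate_dep_keywords(self) -> None:
        # Whether both dependency-pattern keywords must also appear among the
        # term's "//" keywords is unspecified in the annotation convention;
        # we warn rather than fail.
        for t in self.terms.values():
            kws = t.all_keywords()
            for dp in t.dep_patterns:
                for side in (dp.governor, dp.dependent):
                    bare = side[6:] if side.startswith("genex-") else side
                    if side not in kws and bare not in kws:
                        warnings.warn(
                            f"term {t.iri}: dependency-pattern keyword {side!r} "
                            f"not among its keyword patterns",
                            stacklevel=2,
                        )

    # -- traversal ---------------------------------------------------------

    def __contains__(self, iri: str) -> bool:
        return iri in self.terms

    def __getitem__(self, iri: str) -> OntologyTerm:
        try:
            return self.terms[iri]
        except KeyError:
            raise TermNotFoundError(f"unknown term {iri!r}") from None

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, iri: str) -> set[str]:
        """All in-ontology terms reachable by following parent links, excluding
        ``iri`` itself.  Diamond-shaped hierarchies contribute each ancestor
        once (set semantics)."""
        if iri not in self.terms:
            raise TermNotFoundError(f"unknown term {iri!r}")
        seen: set[str] = set()
        frontier = [iri]
        while frontier:
            node = frontier.pop()
            for parent in self.terms[node].parent_iris:
                if parent in self.terms and parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return seen

    def descendants(self, iri: str) -> set[str]:
        """Inverse of :meth:`ancestors` (excludes ``iri``)."""
        if iri not in self.terms:
            raise TermNotFoundError(f"unknown term {iri!r}")
        children: dict[str, set[str]] = {k: set() for k in self.terms}
        for t in self.terms.values():
            for p in t.parent_iris:
                if p in children:
                    children[p].add(t.iri)
        seen: set[str] = set()
        frontier = [iri]
        while frontier:
            node = frontier.pop()
            for c in children[node]:
                if c not in seen:
                    seen.add(c)
                    frontier.append(c)
        return seen

    def depth(self, iri: str) -> int:
        """Longest parent-chain length from ``iri`` to a root (root depth 0)."""
        if iri in self._depth_cache:
            return self._depth_cache[iri]
        if iri not in self.terms:
            raise TermNotFoundError(f"unknown term {iri!r}")
        parents = self.terms[iri].parent_iris & self.terms.keys()
        d = 0 if not parents else 1 + max(self.depth(p) for p in parents)
        self._depth_cache[iri] = d
        return d

    def extract_subset(self, seed_iris: Iterable[str]) -> "Ontology":
        """MIREOT-style subset: the seeds plus all their ancestors, with
        parent links restricted to the retained terms."""
        seeds = list(seed_iris)
        keep: set[str] = set()
        for s in seeds:
            if s not in self.terms:
                raise TermNotFoundError(f"unknown seed {s!r}")
            keep.add(s)
            keep |= self.ancestors(s)
        new_terms = []
        for iri in sorted(keep):
            t = self.terms[iri]
            new_terms.append(
                OntologyTerm(
                    iri=t.iri,
                    label=t.label,
                    parent_iris=set(t.parent_iris) & keep,
                    keyword_patterns=list(t.keyword_patterns),
                    dep_patterns=list(t.dep_patterns),
                )
            )
        return Ontology(new_terms)

    # -- keyword index -----------------------------------------------------

    def keyword_index(self) -> Mapping[str, set[str]]:
        """keyword -> set of term IRIs using it in any keyword pattern."""
        idx: dict[str, set[str]] = {}
        for t in self.terms.values():
            for kw in t.all_keywords():
                idx.setdefault(kw, set()).add(t.iri)
        return idx


# -- module-level functional API (mirrors the method surface) --------------


def ancestors(ontology: Ontology, iri: str) -> set[str]:
    return ontology.ancestors(iri)


def extract_subset(ontology: Ontology, seed_iris: Iterable[str]) -> Ontology:
    return ontology.extract_subset(seed_iris)


def _split_cell(cell: str) -> list[str]:
    return [p.strip() for p in cell.split("|") if p.strip()] if cell else []


def load_dictionary(source: IO[str] | str) -> Ontology:
    """Load an interaction-type dictionary from TSV.

    ``source`` is an open text stream or a path.  Rows with duplicate IRIs
    merge their pattern and parent lists; pattern-cell parse failures are
    re-raised with the offending row number.
    """
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            return load_dictionary(fh)
    reader = csv.DictReader(source, delimiter="\t")
    if reader.fieldnames is None:
        raise OntologyError("empty dictionary file")
    missing = set(DICT_COLUMNS) - set(reader.fieldnames)
    if missing:
        raise OntologyError(f"missing dictionary column(s): {sorted(missing)}")
    terms: dict[str, OntologyTerm] = {}
    for rownum, row in enumerate(reader, start=2):
        iri = (row["iri"] or "").strip()
        if not iri:
            raise OntologyError(f"row {rownum}: empty iri")
        try:
            kw_patterns = [
                parse_keyword_pattern(p) for p in _split_cell(row["keywords"] or "")
            ]
            dep_patterns = [
                parse_dependency_pattern(p)
                for p in _split_cell(row["dep_patterns"] or "")
            ]
        except MalformedPatternError as e:
            raise MalformedPatternError(f"row {rownum}: {e}") from e
        parents = set(_split_cell(row["parents"] or ""))
        if iri in terms:
            t = terms[iri]
            t.parent_iris |= parents
            known_kw = {p.serialize() for p in t.keyword_patterns}
            t.keyword_patterns.extend(
                p for p in kw_patterns if p.serialize() not in known_kw
            )
            known_dep = {p.serialize() for p in t.dep_patterns}
            t.dep_patterns.extend(
                p for p in dep_patterns if p.serialize() not in known_dep
            )
        else:
            terms[iri] = OntologyTerm(
                iri=iri,
                label=(row["label"] or "").strip(),
                parent_iris=parents,
                keyword_patterns=kw_patterns,
                dep_patterns=dep_patterns,
            )
    return Ontology(terms.values())


def write_dictionary(ontology: Ontology, stream: IO[str] | None = None) -> str:
    """Serialize an :class:`Ontology` back to dictionary TSV (stable row order)."""
    out = stream or io.StringIO()
    out.write("\t".join(DICT_COLUMNS) + "\n")
    for iri in sorted(ontology.terms):
        t = ontology.terms[iri]
        out.write(
            "\t".join(
                [
                    t.iri,
                    t.label,
                    "|".join(sorted(t.parent_iris)),
                    "|".join(p.serialize() for p in t.keyword_patterns),
                    "|".join(p.serialize() for p in t.dep_patterns),
                ]
            )
            + "\n"
        )
    return out.getvalue() if stream is None else ""
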