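"""Optional OWL/RDF-XML loader for the interaction-type dictionary.

The two annotation properties carrying the literature-mining annotations
are resolved *by label* — ``has literature mining keywords`` and
``has keyword dependency pattern`` — because labels are the only stable
anchor those properties have across ontology releases.  One annotation
literal may carry several comma-separated patterns (commas inside
``rel(gov, dep)`` parentheses do not split).

This is a convenience entry point; the canonical exchange format remains
the dictionary TSV (:func:`ino_mine.ontology.load_dictionary`).
"""

from __future__ import annotations

from rdflib import Graph, RDF, RDFS, OWL, URIRef

from .errors import OntologyError
from .ontology import (
    Ontology,
    OntologyTerm,
    parse_dependency_pattern,
    parse_keyword_pattern,
)

__all__ = ["load_owl", "KEYWORDS_PROPERTY_LABEL", "DEP_PATTERN_PROPERTY_LABEL"]

KEYWORDS_PROPERTY_LABEL = "has literature mining keywords"
DEP_PATTERN_PROPERTY_LABEL = "has keyword dependency pattern"


def _split_annotation(value: str) -> list[str]:
    """Split a comma-separated annotation literal, ignoring commas inside parentheses."""
    parts: list[str] = []
    depth = 0
    current: list[str] = []
    for ch in value:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        if ch == "," and depth == 0:
            parts.append("".join(current))
            current = []
        else:
            current.append(ch)
    parts.append("".join(current))
    return [p.strip() for p in parts if p.strip()]


def _property_by_label(graph: Graph, label: str) -> URIRef | None:
    for s in graph.subjects(RDFS.label, None):
        for lab in graph.objects(s, RDFS.label):
            if str(lab).strip().lower() == label:
                return s  # type: ignore[return-value]
    return None


def load_owl(source: str, fmt: str | None = None) -> Ontology:
    """Load an OWL/RDF file into an :class:`~ino_mine.ontology.Ontology`.

    Classes become terms (label from ``rdfs:label``), named-class
    ``rdfs:subClassOf`` links become parents (anonymous restriction
    superclasses are ignored), and the two annotation properties found by
    label populate the keyword and dependency patterns.
    """
    g = Graph()
    g.parse(source, format=fmt)
    kw_prop = _property_by_label(g, KEYWORDS_PROPERTY_LABEL)
    dep_prop = _property_by_label(g, DEP_PATTERN_PROPERTY_LABEL)

    terms: list[OntologyTerm] = []
    seen: set[str] = set()
    for cls in g.subjects(RDF.type, OWL.Class):
        if not isinstance(cls, URIRef):
            continue  # skip anonymous class expressions
        iri = str(cls)
        if iri in seen:
            raise OntologyError(f"duplicate class {iri!r} in OWL source")
        seen.add(iri)
        labels = [str(v) for v in g.objects(cls, RDFS.label)]
        parents = {
            str(p) for p in g.objects(cls, RDFS.subClassOf) if isinstance(p, URIRef)
        }
        kw_patterns = []
        dep_patterns = []
        if kw_prop is not None:
            for lit in g.objects(cls, kw_prop):
                for chunk in _split_annotation(str(lit)):
                    kw_patterns.append(parse_keyword_pattern(chunk))
        if dep_prop is not None:
            for lit in g.objects(cls, dep_prop):
                for chunk in _split_annotation(str(lit)):
                    dep_patterns.append(parse_dependency_pattern(chunk))
        terms.append(
            OntologyTerm(
                iri=iri,
                label=labels[0] if labels else "",
                parent_iris=parents,
                keyword_patterns=kw_patterns,
                dep_patterns=dep_patterns,
            )
        )
    terms.sort(key=lambda t: t.iri)
    return Ontology(terms)
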