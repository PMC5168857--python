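"""Hierarchical aggregation of interaction-type counts and enrichment tests.

Each interaction record carries exactly one interaction-type term.  The
*direct* count of a term is the number of records assigned exactly that
term; the *cumulative* count propagates every record to all ancestors with
set semantics — a record counts at most once per ancestor, so
multi-parent (diamond) hierarchies never double-count and the cumulative
count at any root equals the number of records under that root's closure.

Over/under-representation of a term in a foreground count table against a
background table uses the standard two-sided Fisher exact test on the 2x2
table (term vs not-term, foreground vs background-minus-foreground) with
Benjamini-Hochberg adjustment across the tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, NamedTuple, Optional, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import EnrichmentError, TermNotFoundError
from .ontology import Ontology
from .pipeline import InteractionRecord

__all__ = [
    "TermCountTable",
    "rollup_counts",
    "term_enrichment",
    "enrichment_table",
    "write_rollup",
    "render_tree",
]


@dataclass
class TermCountTable:
    """Per-term direct and cumulative record counts."""

    direct: dict[str, int] = field(default_factory=dict)
    cumulative: dict[str, int] = field(default_factory=dict)
    total: int = 0  # number of records counted

    def __post_init__(self):
        for iri, cum in self.cumulative.items():
            if cum < self.direct.get(iri, 0):
                raise ValueError(f"cumulative < direct for {iri!r}")


def rollup_counts(
    records: Sequence[InteractionRecord],
    ontology: Ontology,
    count_unit: str = "records",
) -> TermCountTable:
    """Aggregate record counts up the term hierarchy.

    ``count_unit`` selects what is counted: ``records`` counts one unit per
    (pair, sentence, term) record; ``pairs`` counts distinct gene pairs per
    term; ``sentences`` counts distinct sentences per term.  Records with a
    term outside the ontology raise an error listing the offending IRIs.
    """
    unknown = sorted({r.term_iri for r in records} - ontology.terms.keys())
    if unknown:
        raise TermNotFoundError(f"records reference unknown terms: {unknown}")
    if count_unit == "records":
        units = {r.key: r.term_iri for r in records}
        items = [(key, iri) for key, iri in units.items()]
    elif count_unit == "pairs":
        items = sorted({((r.entity_a, r.entity_b), r.term_iri) for r in records})
    elif count_unit == "sentences":
        items = sorted({(r.sentence_id, r.term_iri) for r in records})
    else:
        raise ValueError(f"unknown count unit {count_unit!r}")

    direct: dict[str, int] = {iri: 0 for iri in ontology.terms}
    cum_units: dict[str, set] = {iri: set() for iri in ontology.terms}
    for unit, iri in items:
        direct[iri] += 1
        cum_units[iri].add(unit)
        for anc in ontology.ancestors(iri):
            cum_units[anc].add(unit)
    return TermCountTable(
        direct=direct,
        cumulative={iri: len(s) for iri, s in cum_units.items()},
        total=len(items),
    )


class EnrichmentResult(NamedTuple):
    term_iri: str
    odds_ratio: float
    p_value: float
    adjusted_p: float


def _contingency(
    foreground: TermCountTable, background: TermCountTable, term: str
) -> tuple[int, int, int, int]:
    a = foreground.cumulative.get(term, 0)
    fg_total = foreground.total
    bg_term = background.cumulative.get(term, 0)
    bg_total = background.total
    if fg_total <= 0 or bg_total <= 0:
        raise EnrichmentError("foreground and background totals must be positive")
    if a > bg_term or fg_total > bg_total:
        raise EnrichmentError(
            f"foreground exceeds background for {term!r} "
            f"({a}/{fg_total} vs {bg_term}/{bg_total})"
        )
    b = fg_total - a
    c = bg_term - a
    d = (bg_total - bg_term) - b
    if d < 0:
        raise EnrichmentError(f"inconsistent totals for {term!r}")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise EnrichmentError(f"zero margin in 2x2 table for {term!r}")
    return a, b, c, d


def enrichment_table(
    foreground: TermCountTable,
    background: TermCountTable,
    terms: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Fisher exact test per term, BH-adjusted across all tested terms.

    Terms whose 2x2 table has a zero margin are silently dropped (the test
    is undefined there) unless explicitly requested via ``terms``, in which
    case the error propagates.
    """
    explicit = terms is not None
    candidates = list(terms) if explicit else sorted(background.cumulative)
    rows = []
    for term in candidates:
        try:
            a, b, c, d = _contingency(foreground, background, term)
        except EnrichmentError:
            if explicit:
                raise
            continue
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((term, odds, p))
    if not rows:
        return pd.DataFrame(columns=["term_iri", "odds_ratio", "p", "p_adj"])
    df = pd.DataFrame(rows, columns=["term_iri", "odds_ratio", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def term_enrichment(
    foreground: TermCountTable,
    background: TermCountTable,
    term: str,
    all_terms: Optional[Iterable[str]] = None,
) -> EnrichmentResult:
    """Enrichment of one term; the BH adjustment runs across ``all_terms``
    (default: every background term with a well-defined table)."""
    table = enrichment_table(foreground, background, terms=all_terms)
    if term not in set(table["term_iri"]):
        table = pd.concat(
            [table, enrichment_table(foreground, background, terms=[term])],
            ignore_index=True,
        )
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    row = table[table["term_iri"] == term].iloc[0]
    return EnrichmentResult(term, float(row.odds_ratio), float(row.p), float(row.p_adj))


def write_rollup(
    counts: TermCountTable,
    ontology: Ontology,
    stream: IO[str],
    enrichment: Optional[pd.DataFrame] = None,
) -> None:
    """Write the rollup TSV: term, depth, direct/cumulative counts, statistics."""
    enr = (
        enrichment.set_index("term_iri")
        if enrichment is not None
        else pd.DataFrame(columns=["odds_ratio", "p", "p_adj"])
    )
    stream.write(
        "term_iri\tterm_label\tdepth\tdirect\tcumulative\todds_ratio\tp\tp_adj\n"
    )
    for iri in sorted(ontology.terms):
        t = ontology.terms[iri]
        if iri in enr.index:
            row = enr.loc[iri]
            stats = [f"{row.odds_ratio:.6g}", f"{row.p:.6g}", f"{row.p_adj:.6g}"]
        else:
            stats = ["NA", "NA", "NA"]
        stream.write(
            "\t".join(
                [
                    iri,
                    t.label,
                    str(ontology.depth(iri)),
                    str(counts.direct.get(iri, 0)),
                    str(counts.cumulative.get(iri, 0)),
                    *stats,
                ]
            )
            + "\n"
        )


def render_tree(
    ontology: Ontology, counts: Optional[TermCountTable] = None, indent: str = "  "
) -> str:
    """Indented-text rendering of the hierarchy with per-term counts.

    Multi-parent terms appear once under each parent (display convention;
    the counts themselves are set-semantic and never double-counted).
    """
    children: dict[str, list[str]] = {iri: [] for iri in ontology.terms}
    for t in ontology.terms.values():
        for p in t.parent_iris:
            if p in children:
                children[p].append(t.iri)
    lines: list[str] = []

    def fmt(iri: str) -> str:
        label = ontology.terms[iri].label or iri
        if counts is None:
            return label
        return (
            f"{label} "
            f"[{counts.direct.get(iri, 0)}/{counts.cumulative.get(iri, 0)}]"
        )

    def walk(iri: str, depth: int) -> None:
        lines.append(indent * depth + fmt(iri))
        for child in sorted(children[iri]):
            walk(child, depth + 1)

    for root in sorted(ontology.roots):
        walk(root, 0)
    return "\n".join(lines) + "\n"
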