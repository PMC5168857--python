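"""Dictionary loading, pattern grammars, and hierarchy traversal."""

import random
from io import StringIO

import pytest

from ino_mine import (
    Ontology,
    OntologyTerm,
    load_dictionary,
    parse_dependency_pattern,
    parse_keyword_pattern,
    write_dictionary,
)
from ino_mine.errors import MalformedPatternError, OntologyError, TermNotFoundError


class TestKeywordPatternGrammar:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("transcription//dependent", ("transcription", "dependent")),
            ("dephosphorylation", ("dephosphorylation",)),
            ("Negatively Regulated//Expression", ("negatively regulated", "expression")),
            (" requires // transcription ", ("requires", "transcription")),
        ],
    )
    def test_split_trim_lowercase(self, raw, expected):
        assert parse_keyword_pattern(raw).keywords == expected

    @pytest.mark.parametrize("raw", ["", "   ", "a////b", "//a", "a//"])
    def test_malformed(self, raw):
        with pytest.raises(MalformedPatternError):
            parse_keyword_pattern(raw)

    def test_roundtrip_identity_up_to_whitespace(self):
        for raw in ["a//b//c", "one keyword", "x // y"]:
            pat = parse_keyword_pattern(raw)
            assert parse_keyword_pattern(pat.serialize()) == pat


class TestDependencyPatternGrammar:
    def test_table_convention(self):
        p = parse_dependency_pattern("nsubj(control, expression)")
        assert (p.relation, p.governor, p.dependent) == (
            "nsubj", "control", "expression",
        )

    def test_placeholder_argument_lowercased(self):
        p = parse_dependency_pattern("amod(transcription, GeneX-dependent)")
        assert p.dependent == "genex-dependent"

    def test_subtype_label_normalized(self):
        assert parse_dependency_pattern("nmod:of(a, b)").relation == "nmod"

    @pytest.mark.parametrize(
        "raw", ["nsubj(control)", "nsubj control, expression", "dobj(a, b, c)", "", "f(,b)"]
    )
    def test_malformed(self, raw):
        with pytest.raises(MalformedPatternError):
            parse_dependency_pattern(raw)

    def test_roundtrip(self):
        p = parse_dependency_pattern("dobj(inhibit, activity)")
        assert parse_dependency_pattern(p.serialize()) == p


class TestLoadDictionary:
    def test_minimal_chain(self, chain_ontology):
        assert len(chain_ontology) == 3
        assert chain_ontology.roots == {"T:root"}
        assert chain_ontology.depth("T:leaf") == 2

    def test_duplicate_iris_merge_patterns(self):
        tsv = (
            "iri\tlabel\tparents\tkeywords\tdep_patterns\n"
            "T:a\ta\t\tx//y\t\n"
            "T:a\ta\t\tz\tnsubj(x, y)\n"
        )
        onto = load_dictionary(StringIO(tsv))
        assert len(onto) == 1
        assert {p.serialize() for p in onto["T:a"].keyword_patterns} == {"x//y", "z"}
        assert len(onto["T:a"].dep_patterns) == 1

    def test_self_loop_is_cycle_error(self):
        tsv = "iri\tlabel\tparents\tkeywords\tdep_patterns\nT:a\ta\tT:a\t\t\n"
        with pytest.raises(OntologyError, match="cycl"):
            load_dictionary(StringIO(tsv))

    def test_two_node_cycle(self):
        tsv = (
            "iri\tlabel\tparents\tkeywords\tdep_patterns\n"
            "T:a\ta\tT:b\t\t\nT:b\tb\tT:a\t\t\n"
        )
        with pytest.raises(OntologyError, match="cycl"):
            load_dictionary(StringIO(tsv))

    def test_missing_column(self):
        with pytest.raises(OntologyError, match="missing"):
            load_dictionary(StringIO("iri\tlabel\nT:a\ta\n"))

    def test_malformed_cell_reports_row(self):
        tsv = "iri\tlabel\tparents\tkeywords\tdep_patterns\nT:a\ta\t\ta////b\t\n"
        with pytest.raises(MalformedPatternError, match="row 2"):
            load_dictionary(StringIO(tsv))

    def test_dep_keyword_not_in_keywords_warns_not_fails(self):
        tsv = (
            "iri\tlabel\tparents\tkeywords\tdep_patterns\n"
            "T:a\ta\t\tother\tnsubj(x, y)\n"
        )
        with pytest.warns(UserWarning, match="not among"):
            onto = load_dictionary(StringIO(tsv))
        assert len(onto) == 1

    def test_packaged_dictionary_roundtrips(self, examples):
        text = write_dictionary(examples.ontology)
        again = load_dictionary(StringIO(text))
        assert set(again.terms) == set(examples.ontology.terms)
        for iri, term in examples.ontology.terms.items():
            assert {p.serialize() for p in term.keyword_patterns} == {
                p.serialize() for p in again[iri].keyword_patterns
            }
            assert {p.serialize() for p in term.dep_patterns} == {
                p.serialize() for p in again[iri].dep_patterns
            }


def _closure_oracle(parents: dict[str, set[str]], start: str) -> set[str]:
    """Brute-force DFS over every parent path."""
    out: set[str] = set()

    def dfs(node):
        for p in parents.get(node, set()):
            if p in parents:
                out.add(p)
                dfs(p)

    dfs(start)
    return out


def _random_dag(rng, n):
    # edges only from higher to lower rank: acyclic by construction
    names = [f"N:{i}" for i in range(n)]
    parents = {nm: set() for nm in names}
    for i, nm in enumerate(names):
        for j in range(i):
            if rng.random() < 0.4:
                parents[nm].add(names[j])
    terms = [OntologyTerm(iri=nm, label=nm, parent_iris=set(ps))
             for nm, ps in parents.items()]
    return Ontology(terms), parents


class TestTraversal:
    def test_chain_closure(self, chain_ontology):
        assert chain_ontology.ancestors("T:leaf") == {"T:mid", "T:root"}
        assert chain_ontology.ancestors("T:root") == set()

    def test_unknown_iri(self, chain_ontology):
        with pytest.raises(TermNotFoundError):
            chain_ontology.ancestors("T:nope")

    def test_diamond_counts_grandparent_once(self):
        terms = [
            OntologyTerm("T:g", "g"),
            OntologyTerm("T:p1", "p1", {"T:g"}),
            OntologyTerm("T:p2", "p2", {"T:g"}),
            OntologyTerm("T:c", "c", {"T:p1", "T:p2"}),
        ]
        onto = Ontology(terms)
        assert onto.ancestors("T:c") == {"T:p1", "T:p2", "T:g"}

    def test_random_dags_match_path_enumeration_oracle(self):
        rng = random.Random(0)
        for _ in range(50):
            onto, parents = _random_dag(rng, rng.randint(1, 8))
            for node in parents:
                assert onto.ancestors(node) == _closure_oracle(parents, node)

    def test_external_parents_terminate_walks(self):
        onto = Ontology([OntologyTerm("T:a", "a", {"EXT:missing"})])
        assert onto.ancestors("T:a") == set()
        assert onto.external_parents() == {"EXT:missing"}


class TestExtractSubset:
    def test_all_seeds_is_identity(self, examples):
        sub = examples.ontology.extract_subset(examples.ontology.terms)
        assert set(sub.terms) == set(examples.ontology.terms)

    def test_leaf_seed_keeps_chain(self, chain_ontology):
        sub = chain_ontology.extract_subset(["T:leaf"])
        assert set(sub.terms) == {"T:leaf", "T:mid", "T:root"}
        assert sub.depth("T:leaf") == 2

    def test_unknown_seed(self, chain_ontology):
        with pytest.raises(TermNotFoundError):
            chain_ontology.extract_subset(["T:nope"])

    def test_random_dag_equals_closure_union_and_is_idempotent(self):
        rng = random.Random(1)
        for _ in range(30):
            onto, parents = _random_dag(rng, 10)
            seeds = rng.sample(sorted(parents), 3)
            sub = onto.extract_subset(seeds)
            expected = set(seeds)
            for s in seeds:
                expected |= _closure_oracle(parents, s)
            assert set(sub.terms) == expected
            again = sub.extract_subset(seeds)
            assert set(again.terms) == set(sub.terms)
            for iri in again.terms:
                assert again[iri].parent_iris == sub[iri].parent_iris


class TestOwlLoader:
    def test_owl_matches_tsv(self, tmp_path, examples):
        rdflib = pytest.importorskip("rdflib")
        from rdflib import RDF, RDFS, OWL, Graph, Literal, URIRef

        from ino_mine.owl import (
            DEP_PATTERN_PROPERTY_LABEL,
            KEYWORDS_PROPERTY_LABEL,
            load_owl,
        )

        g = Graph()
        kw_prop = URIRef("http://example.org/kwprop")
        dep_prop = URIRef("http://example.org/depprop")
        g.add((kw_prop, RDF.type, OWL.AnnotationProperty))
        g.add((kw_prop, RDFS.label, Literal(KEYWORDS_PROPERTY_LABEL)))
        g.add((dep_prop, RDF.type, OWL.AnnotationProperty))
        g.add((dep_prop, RDFS.label, Literal(DEP_PATTERN_PROPERTY_LABEL)))
        for iri, term in examples.ontology.terms.items():
            c = URIRef(iri)
            g.add((c, RDF.type, OWL.Class))
            g.add((c, RDFS.label, Literal(term.label)))
            for p in term.parent_iris:
                g.add((c, RDFS.subClassOf, URIRef(p)))
            if term.keyword_patterns:
                # one comma-separated literal, as the annotations are written
                g.add((c, kw_prop, Literal(
                    ", ".join(p.serialize() for p in term.keyword_patterns))))
            for dp in term.dep_patterns:
                g.add((c, dep_prop, Literal(dp.serialize())))
        path = tmp_path / "mini.owl"
        g.serialize(destination=str(path), format="xml")

        onto = load_owl(str(path))
        assert set(onto.terms) == set(examples.ontology.terms)
        for iri, term in examples.ontology.terms.items():
            assert onto[iri].label == term.label
            assert onto[iri].parent_iris == term.parent_iris
            assert {p.serialize() for p in onto[iri].keyword_patterns} == {
                p.serialize() for p in term.keyword_patterns
            }
            assert {p.serialize() for p in onto[iri].dep_patterns} == {
                p.serialize() for p in term.dep_patterns
            }
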