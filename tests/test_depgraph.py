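"""CoNLL-U reading, direct-connection decisions, and pattern matching."""

import random
from io import StringIO

import pytest

from ino_mine import (
    DependencyGraph,
    Mention,
    base_label,
    classify_sentence,
    directly_connected,
    load_dictionary,
    make_sentence,
    match_cooccurrence_patterns,
    match_dependency_patterns,
    read_conllu,
    tag_keywords,
    write_conllu,
)
from ino_mine.errors import ConlluParseError, InvalidPairError
from ino_mine.fixtures import ANCHORED_PATTERNS, INDIRECT_EXAMPLE_ID, WORKED_EXAMPLE_ID


def _single_pattern_dict(relation, gov, dep):
    """A dictionary containing exactly one term with exactly one dependency pattern."""
    gov_kw = gov[6:] if gov.lower().startswith("genex-") else gov
    return load_dictionary(StringIO(
        "iri\tlabel\tparents\tkeywords\tdep_patterns\n"
        f"T:only\tprobe term\t\t{gov_kw}//{dep}\t{relation}({gov}, {dep})\n"
    ))


class TestReadConllu:
    def test_packaged_file_edges(self, examples):
        g = examples.graph(WORKED_EXAMPLE_ID)
        assert (8, 2, "nsubj") in g.edges
        assert g.root == 8

    def test_enhanced_deps_column_adds_edge(self, examples):
        g = examples.graph("lll-nsubjpass-recognized-promoter")
        assert (11, 3, "nsubjpass") in g.edges  # basic layer
        assert (14, 3, "nsubjpass") in g.edges  # enhanced layer via DEPS

    def test_single_token_sentence(self):
        pairs = read_conllu(StringIO("1\tHello\t_\t_\t_\t_\t0\troot\t_\t_\n"))
        [(s, g)] = pairs
        assert len(s) == 1 and len(g.edges) == 0 and g.root == 1

    def test_non_integer_head(self):
        with pytest.raises(ConlluParseError, match="HEAD"):
            read_conllu(StringIO("1\tword\t_\t_\t_\t_\tX\tdep\t_\t_\n"))

    def test_wrong_column_count(self):
        with pytest.raises(ConlluParseError, match="10"):
            read_conllu(StringIO("1\tword\t_\n"))

    def test_multiword_range_skipped(self):
        text = (
            "1-2\tdon't\t_\t_\t_\t_\t_\t_\t_\t_\n"
            "1\tdo\t_\t_\t_\t_\t0\troot\t_\t_\n"
            "2\tnot\t_\t_\t_\t_\t1\tadvmod\t_\t_\n"
        )
        [(s, g)] = read_conllu(StringIO(text))
        assert len(s) == 2 and (1, 2, "advmod") in g.edges

    def test_roundtrip_through_writer(self, examples):
        out = StringIO()
        pairs = [examples.items[i] for i in examples.sentence_ids]
        write_conllu(pairs, out)
        again = read_conllu(StringIO(out.getvalue()))
        assert [(s.id, g.edges, g.root) for s, g in again] == [
            (s.id, g.edges, g.root) for s, g in pairs
        ]


class TestBaseLabel:
    @pytest.mark.parametrize(
        "raw, expected",
        [("nmod:of", "nmod"), ("nsubj", "nsubj"), ("acl:relcl", "acl"),
         ("NMOD:Agent", "nmod")],
    )
    def test_definition(self, raw, expected):
        assert base_label(raw) == expected

    def test_idempotent(self):
        for lab in ["nmod:of", "nsubj", "cc:preconj"]:
            assert base_label(base_label(lab)) == base_label(lab)


def _kw(start, end, text):
    return Mention(start, end, text, "keyword", "T:probe")


class TestDirectlyConnected:
    def test_worked_pair_is_nsubj_with_governor_control(self, examples):
        s = examples.sentence(WORKED_EXAMPLE_ID)
        g = examples.graph(WORKED_EXAMPLE_ID)
        exp, ctl = _kw(2, 2, "expression"), _kw(8, 8, "control")
        conn = directly_connected(g, exp, ctl)
        assert conn is not None
        assert conn.label == "nsubj"
        assert conn.gov_mention.matched == "control"

    def test_indirect_pair_absent(self, examples):
        g = examples.graph(INDIRECT_EXAMPLE_ID)
        binds, proms = _kw(2, 2, "binds"), _kw(10, 10, "promoters")
        assert directly_connected(g, binds, proms) is None

    def test_symmetric_same_edge(self, examples):
        g = examples.graph(WORKED_EXAMPLE_ID)
        a, b = _kw(2, 2, "expression"), _kw(8, 8, "control")
        c1, c2 = directly_connected(g, a, b), directly_connected(g, b, a)
        assert c1.edge == c2.edge and c1.gov_mention == c2.gov_mention

    def test_overlap_rejected(self, examples):
        g = examples.graph(WORKED_EXAMPLE_ID)
        with pytest.raises(InvalidPairError):
            directly_connected(g, _kw(1, 2, "x"), _kw(2, 3, "y"))

    def test_matches_exhaustive_edge_scan(self):
        rng = random.Random(9)
        for _ in range(200):
            n = rng.randint(3, 10)
            edges = set()
            for dep in range(2, n + 1):
                edges.add((rng.randint(1, dep - 1), dep, rng.choice(
                    ["nsubj", "dobj", "nmod:of", "amod"])))
            g = DependencyGraph(sentence_ref="s", edges=frozenset(edges))
            i = rng.randint(1, n)
            j = rng.choice([x for x in range(1, n + 1) if x != i])
            m1, m2 = _kw(i, i, f"w{i}"), _kw(j, j, f"w{j}")
            got = directly_connected(g, m1, m2)
            oracle = [
                e for e in sorted(edges)
                if {e[0], e[1]} == {i, j}
            ]
            if not oracle:
                assert got is None
            else:
                assert got is not None and got.edge == oracle[0]


class TestMatchDependencyPatterns:
    @pytest.mark.parametrize("sid", sorted(ANCHORED_PATTERNS))
    def test_each_curated_sentence_matches_its_own_pattern(self, examples, sid):
        relation, gov, dep, _ = ANCHORED_PATTERNS[sid]
        # rebuild the printed pattern form (placeholder for the amod row)
        if dep.endswith("-dependent"):
            dep_arg = "GeneX-dependent"
        else:
            dep_arg = dep
        onto = _single_pattern_dict(relation, gov, dep_arg)
        s, g = examples.items[sid]
        mentions = tag_keywords(s, onto)
        matches = match_dependency_patterns(s, g, mentions, onto)
        assert any(
            m.term_iri == "T:only" and base_label(m.edge[2]) == relation
            for m in matches
        ), f"{sid}: no {relation} match"

    def test_placeholder_matches_hyphen_prefixed_token(self, examples):
        onto = _single_pattern_dict("amod", "transcription", "GeneX-dependent")
        s, g = examples.items["lll-amod-dependent-transcription"]
        mentions = tag_keywords(s, onto)
        [match] = match_dependency_patterns(s, g, mentions, onto)
        assert {m.matched for m in match.keyword_mentions} == {
            "sigmak-dependent", "transcription",
        }

    def test_no_edges_between_keywords(self, examples):
        onto = _single_pattern_dict("nsubj", "binds", "promoters")
        s, g = examples.items[INDIRECT_EXAMPLE_ID]
        mentions = tag_keywords(s, onto)
        assert match_dependency_patterns(s, g, mentions, onto) == []


class TestMatchCooccurrencePatterns:
    def _onto(self, patterns):
        rows = "".join(
            f"T:{i}\tterm{i}\t\t{pat}\t\n" for i, pat in enumerate(patterns)
        )
        return load_dictionary(StringIO(
            "iri\tlabel\tparents\tkeywords\tdep_patterns\n" + rows))

    def test_pair_covered(self):
        onto = self._onto(["requires//transcription"])
        s = make_sentence("s1", "sspG transcription also requires the protein GerE.")
        mentions = tag_keywords(s, onto)
        [match] = match_cooccurrence_patterns(mentions, onto)
        assert {m.matched for m in match.keyword_mentions} == {
            "requires", "transcription",
        }

    def test_incomplete_coverage(self):
        onto = self._onto(["requires//transcription"])
        s = make_sentence("s1", "transcription happens here.")
        mentions = tag_keywords(s, onto)
        assert match_cooccurrence_patterns(mentions, onto) == []

    def test_three_keyword_pattern_leftmost_binding(self):
        onto = self._onto(["low concentration//activated//transcription"])
        s = make_sentence(
            "s1",
            "A low concentration of GerE activated cotB transcription and more "
            "transcription followed.",
        )
        mentions = tag_keywords(s, onto)
        [match] = match_cooccurrence_patterns(mentions, onto)
        starts = sorted(m.start for m in match.keyword_mentions)
        # leftmost "transcription" (token 8) chosen over the later repeat
        assert starts == [2, 6, 8]
        # cross-check against exhaustive assignment enumeration
        from itertools import permutations

        spans = sorted({(m.start, m.end, m.matched) for m in mentions})
        keywords = ("low concentration", "activated", "transcription")
        feasible = []
        for perm in permutations(spans, len(keywords)):
            from ino_mine.tagging import keyword_matches_text

            if all(keyword_matches_text(k, sp[2]) for k, sp in zip(keywords, perm)):
                feasible.append(tuple(sp[0] for sp in perm))
        assert tuple(
            m.start for m in sorted(match.keyword_mentions, key=lambda m: m.start)
        ) == tuple(sorted(min(feasible)))


class TestClassifySentence:
    def test_dependency_match_outranks_cooccurrence(self, examples):
        s, g = examples.items[WORKED_EXAMPLE_ID]
        mentions = tag_keywords(s, examples.ontology)
        ranked = classify_sentence(s, g, mentions, examples.ontology)
        assert ranked[0].evidence == "direct_dependency"
        assert examples.ontology[ranked[0].term_iri].label == "regulation of gene expression"

    def test_no_keywords_no_matches(self, examples):
        s, g = examples.items[WORKED_EXAMPLE_ID]
        assert classify_sentence(s, g, [], examples.ontology) == []

    def test_stable_under_input_permutation(self, examples):
        s, g = examples.items["lll-nsubjpass-recognized-promoter"]
        mentions = tag_keywords(s, examples.ontology)
        base = classify_sentence(s, g, mentions, examples.ontology)
        rng = random.Random(4)
        for _ in range(5):
            shuffled = list(mentions)
            rng.shuffle(shuffled)
            assert classify_sentence(s, g, shuffled, examples.ontology) == base

    def test_deduplicated_per_term_and_mention_set(self, examples):
        s, g = examples.items[WORKED_EXAMPLE_ID]
        mentions = tag_keywords(s, examples.ontology)
        ranked = classify_sentence(s, g, mentions, examples.ontology)
        keys = [(m.term_iri, m.mention_spans) for m in ranked]
        assert len(keys) == len(set(keys))
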