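"""Synthetic corpora with planted interactions, and packaged worked examples.

The generator emulates LLL-style gene-regulation sentences from *Bacillus
subtilis* abstracts: short sentences with 2 gene mentions, 1-4 trigger
keywords, and dependency trees in which a planted trigger pair is directly
edge-connected (with the intended labeled relation) when a per-sentence
coin with probability ``p_direct_edge`` succeeds, and otherwise separated
by a path of >= 2 edges.  Five sentence templates instantiate the five
canonical relation shapes (nsubj, nsubjpass, dobj, amod with a
gene-prefixed adjective, nmod), plus a single-keyword template.  Every
output (corpus, CoNLL-U parses, gold record table, dictionary, lexicon) is
plain text and byte-identical for a fixed seed.

What the generator does *not* emulate: real B. subtilis biology, parser
noise, anaphora, or sentences whose trigger pair is a false positive — the
planted gold is exact by construction.

The packaged examples are seven hand-curated sentences with dependency
parses reproducing the relations each one is known for (one anchored edge
per sentence; the remaining attachments are plain left-headed/UD-style
choices of ours), together with a 10-term mini-dictionary of regulation
types and a small gene lexicon.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from pathlib import Path

from .depgraph import DependencyGraph, read_conllu
from .errors import InoMineError
from .ontology import Ontology, load_dictionary
from .tagging import Lexicon, Sentence, load_lexicon

__all__ = [
    "FixtureConfig",
    "FixtureBundle",
    "generate_corpus",
    "ExampleBundle",
    "packaged_examples",
]


# ---------------------------------------------------------------------------
# Synthetic generator


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic corpus."""

    n_sentences: int = 77
    keywords_min: int = 1
    keywords_max: int = 4
    entities_per_sentence: int = 2
    p_direct_edge: float = 1.0
    distractor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_direct_edge <= 1.0):
            raise InoMineError("p_direct_edge must be in [0, 1]")
        if not (0.0 <= self.distractor_rate <= 1.0):
            raise InoMineError("distractor_rate must be in [0, 1]")
        if self.n_sentences < 0:
            raise InoMineError("n_sentences must be >= 0")
        if not (1 <= self.keywords_min <= self.keywords_max <= 4):
            raise InoMineError("keyword range must satisfy 1 <= min <= max <= 4")
        if self.entities_per_sentence != 2:
            raise InoMineError("templates currently plant exactly 2 entities")
        if not isinstance(self.seed, int):
            raise InoMineError("seed must be an integer")


@dataclass
class FixtureBundle:
    """The five text artifacts of one generated corpus."""

    corpus: str
    conllu: str
    gold: str
    dictionary: str
    lexicon: str
    config: FixtureConfig = field(default=None)  # type: ignore[assignment]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, content in [
            ("corpus.txt", self.corpus),
            ("parses.conllu", self.conllu),
            ("gold.tsv", self.gold),
            ("dictionary.tsv", self.dictionary),
            ("lexicon.tsv", self.lexicon),
        ]:
            p = out / name
            p.write_text(content, encoding="utf-8")
            paths[name] = p
        return paths


_SYN_DICT_ROWS = [
    # iri, label, parents, keywords, dep_patterns
    ("SYN:0000000", "interaction", "", "", ""),
    ("SYN:0000001", "regulation", "SYN:0000000", "", ""),
    (
        "SYN:0000010",
        "regulation of expression",
        "SYN:0000001",
        "expression//control",
        "nsubj(control, expression)",
    ),
    (
        "SYN:0000011",
        "regulation by promoter recognition",
        "SYN:0000001",
        "recognized//promoter",
        "nsubjpass(recognized, promoter)",
    ),
    (
        "SYN:0000012",
        "inhibition of activity",
        "SYN:0000001",
        "inhibit//activity",
        "dobj(inhibit, activity)",
    ),
    (
        "SYN:0000013",
        "factor-dependent regulation of transcription",
        "SYN:0000001",
        "transcription//dependent",
        "amod(transcription, GeneX-dependent)",
    ),
    (
        "SYN:0000014",
        "requirement for expression",
        "SYN:0000001",
        "essential//expression",
        "nmod(essential, expression)",
    ),
    ("SYN:0000020", "phosphorylation", "SYN:0000001", "phosphorylates", ""),
    ("SYN:0000021", "stimulation", "SYN:0000001", "stimulates", ""),
]

# template: words with {A}/{B} entity slots, (head, label) per token,
# gov/dep keyword token positions (1-based), direct edge spec, and the
# re-attachment (token, new_head, new_label) used for the indirect variant.
_TEMPLATES = [
    {
        "term": "SYN:0000010",
        "relation": "nsubj",
        "words": "The expression of {A} is under the control of {B} .".split(),
        "heads": [2, 8, 4, 2, 8, 8, 8, 0, 10, 8, 8],
        "labels": [
            "det", "nsubj", "case", "nmod:of", "cop", "case", "det",
            "root", "case", "nmod:of", "punct",
        ],
        "gov": 8,
        "dep": 2,
        "indirect": (2, 5, "nsubj"),
        "entities": {"A": 4, "B": 10},
    },
    {
        "term": "SYN:0000011",
        "relation": "nsubjpass",
        "words": "The {A} promoter is recognized by {B} in vivo .".split(),
        "heads": [3, 3, 5, 5, 0, 7, 5, 9, 5, 5],
        "labels": [
            "det", "compound", "nsubjpass", "auxpass", "root", "case",
            "nmod:agent", "case", "nmod:in", "punct",
        ],
        "gov": 5,
        "dep": 3,
        "indirect": (3, 4, "nsubjpass"),
        "entities": {"A": 2, "B": 7},
    },
    {
        "term": "SYN:0000012",
        "relation": "dobj",
        "words": "{A} may inhibit {B} activity late in growth .".split(),
        "heads": [3, 3, 0, 5, 3, 3, 8, 6, 3],
        "labels": [
            "nsubj", "aux", "root", "compound", "dobj", "advmod", "case",
            "nmod:in", "punct",
        ],
        "gov": 3,
        "dep": 5,
        "indirect": (5, 6, "dobj"),
        "entities": {"A": 1, "B": 4},
    },
    {
        "term": "SYN:0000013",
        "relation": "amod",
        "words": "{A}-dependent transcription of {B} involves {A} directly .".split(),
        "heads": [2, 5, 4, 2, 0, 5, 5, 5],
        "labels": [
            "amod", "nsubj", "case", "nmod:of", "root", "dobj", "advmod",
            "punct",
        ],
        "gov": 2,
        "dep": 1,
        "indirect": (1, 4, "amod"),
        "entities": {"A": 6, "B": 4},
    },
    {
        "term": "SYN:0000014",
        "relation": "nmod",
        "words": "{A} is essential for {B} expression in cells .".split(),
        "heads": [3, 3, 0, 6, 6, 3, 8, 3, 3],
        "labels": [
            "nsubj", "cop", "root", "case", "compound", "nmod:for", "case",
            "nmod:in", "punct",
        ],
        "gov": 3,
        "dep": 6,
        "indirect": (6, 8, "nmod"),
        "entities": {"A": 1, "B": 5},
    },
]

_SINGLE_TEMPLATE = {
    "term": "SYN:0000020",
    "keyword": "phosphorylates",
    "words": "{A} phosphorylates {B} in vitro .".split(),
    "heads": [2, 0, 2, 5, 2, 2],
    "labels": ["nsubj", "root", "dobj", "case", "nmod:in", "punct"],
    "kw_token": 2,
    "entities": {"A": 1, "B": 3},
}

_EXTRA_SINGLES = [("SYN:0000020", "phosphorylates"), ("SYN:0000021", "stimulates")]
_DISTRACTORS = ["modulates", "affects", "influences", "alters"]


def _gene_name(rng: random.Random, used: set[str]) -> str:
    while True:
        name = (
            "".join(rng.choice(string.ascii_lowercase) for _ in range(3))
            + rng.choice(string.ascii_uppercase)
        )
        if name not in used:
            used.add(name)
            return name


def generate_corpus(config: FixtureConfig) -> FixtureBundle:
    """Generate one deterministic synthetic corpus (see module docstring)."""
    rng = random.Random(config.seed)
    used_genes: set[str] = set()
    corpus_lines: list[str] = []
    conllu = StringIO()
    gold_lines = ["sentence_id\tentity_a\tentity_b\tterm_iri\tevidence\tkeywords"]

    for i in range(config.n_sentences):
        sid = f"syn{i + 1:04d}"
        k = rng.randint(config.keywords_min, config.keywords_max)
        gene_a = _gene_name(rng, used_genes)
        gene_b = _gene_name(rng, used_genes)
        pair = tuple(sorted((gene_a, gene_b)))

        if k == 1:
            tpl = _SINGLE_TEMPLATE
            words = [
                w.replace("{A}", gene_a).replace("{B}", gene_b)
                for w in tpl["words"]
            ]
            heads = list(tpl["heads"])
            labels = list(tpl["labels"])
            planted = [(tpl["term"], "single_keyword", (tpl["keyword"],))]
        else:
            tpl = _TEMPLATES[rng.randrange(len(_TEMPLATES))]
            words = [
                w.replace("{A}", gene_a).replace("{B}", gene_b)
                for w in tpl["words"]
            ]
            heads = list(tpl["heads"])
            labels = list(tpl["labels"])
            direct = rng.random() < config.p_direct_edge
            if not direct:
                tok, new_head, new_label = tpl["indirect"]
                heads[tok - 1] = new_head
                labels[tok - 1] = new_label
            gov_kw = words[tpl["gov"] - 1].lower()
            dep_kw = words[tpl["dep"] - 1].lower()
            evidence = "direct_dependency" if direct else "cooccurrence"
            in_order = (  # keywords cited in sentence order, as the pipeline does
                (dep_kw, gov_kw) if tpl["dep"] < tpl["gov"] else (gov_kw, dep_kw)
            )
            planted = [(tpl["term"], evidence, in_order)]
            # extra single-keyword triggers for 3- and 4-keyword sentences,
            # appended before the final period and attached to the root
            root_idx = heads.index(0) + 1
            for extra_i in range(k - 2):
                term, kw = _EXTRA_SINGLES[extra_i]
                insert_at = len(words) - 1  # before the period
                words.insert(insert_at, kw)
                heads = [h if h <= insert_at else h + 1 for h in heads]
                heads.insert(insert_at, root_idx if root_idx <= insert_at else root_idx + 1)
                labels.insert(insert_at, "conj")
                planted.append((term, "single_keyword", (kw,)))

        if rng.random() < config.distractor_rate:
            root_idx = heads.index(0) + 1
            insert_at = len(words) - 1
            words.insert(insert_at, rng.choice(_DISTRACTORS))
            heads = [h if h <= insert_at else h + 1 for h in heads]
            heads.insert(insert_at, root_idx if root_idx <= insert_at else root_idx + 1)
            labels.insert(insert_at, "advcl")

        text = " ".join(words)
        corpus_lines.append(f"{sid}\t{text}")
        conllu.write(f"# sent_id = {sid}\n# text = {text}\n")
        for idx, (w, h, lab) in enumerate(zip(words, heads, labels), start=1):
            conllu.write(f"{idx}\t{w}\t_\t_\t_\t_\t{h}\t{lab}\t_\t_\n")
        conllu.write("\n")
        # gold: keywords ordered by sentence position
        for term, evidence, kws in planted:
            gold_lines.append(
                "\t".join([sid, pair[0], pair[1], term, evidence, "//".join(kws)])
            )

    dict_lines = ["iri\tlabel\tparents\tkeywords\tdep_patterns"]
    dict_lines += ["\t".join(r) for r in _SYN_DICT_ROWS]
    lex_lines = ["symbol\tsynonyms"]
    lex_lines += [f"{g}\t" for g in sorted(used_genes)]

    return FixtureBundle(
        corpus="\n".join(corpus_lines) + ("\n" if corpus_lines else ""),
        conllu=conllu.getvalue(),
        gold="\n".join(gold_lines) + "\n",
        dictionary="\n".join(dict_lines) + "\n",
        lexicon="\n".join(lex_lines) + "\n",
        config=config,
    )


# ---------------------------------------------------------------------------
# Packaged worked examples


@dataclass
class ExampleBundle:
    """Hand-curated example sentences + parses + mini-dictionary + lexicon."""

    ontology: Ontology
    lexicon: Lexicon
    items: dict[str, tuple[Sentence, DependencyGraph]]
    #: sentence id -> (relation, governor keyword, dependent keyword, term IRI)
    anchored_patterns: dict[str, tuple[str, str, str, str]]

    @property
    def sentence_ids(self) -> list[str]:
        return list(self.items)

    def sentence(self, sent_id: str) -> Sentence:
        return self.items[sent_id][0]

    def graph(self, sent_id: str) -> DependencyGraph:
        return self.items[sent_id][1]


_INO = "http://purl.obolibrary.org/obo/INO_"

ANCHORED_PATTERNS = {
    "lll-nsubj-control-expression": ("nsubj", "control", "expression", _INO + "0000038"),
    "lll-nsubjpass-recognized-promoter": (
        "nsubjpass", "recognized", "promoter", _INO + "0000042",
    ),
    "lll-dobj-inhibit-activity": ("dobj", "inhibit", "activity", _INO + "0000044"),
    "lll-amod-dependent-transcription": (
        "amod", "transcription", "sigmak-dependent", _INO + "0000032",
    ),
    "lll-nmod-essential-expression": (
        "nmod", "essential", "expression", _INO + "0000038",
    ),
}

WORKED_EXAMPLE_ID = "lll-worked-regulation-of-expression"
INDIRECT_EXAMPLE_ID = "lll-indirect-binds-promoters"


def _data_text(name: str) -> str:
    return (resources.files("ino_mine") / "data" / name).read_text(encoding="utf-8")


def packaged_examples() -> ExampleBundle:
    """Load the seven curated sentences, mini-dictionary, and lexicon."""
    ontology = load_dictionary(StringIO(_data_text("example_dictionary.tsv")))
    lexicon = load_lexicon(StringIO(_data_text("example_lexicon.tsv")))
    pairs = read_conllu(StringIO(_data_text("example_sentences.conllu")))
    items = {s.id: (s, g) for s, g in pairs}
    return ExampleBundle(
        ontology=ontology,
        lexicon=lexicon,
        items=items,
        anchored_patterns=dict(ANCHORED_PATTERNS),
    )
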