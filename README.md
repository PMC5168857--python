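# ino-mine

Ontology-backed mining of **multi-keyword gene–gene interaction types** from
dependency-parsed biomedical sentences.

Many regulatory relations in the literature are not signalled by a single
trigger word. In

> *"The expression of rsfA is under the control of both sigma(F) and sigma(G)."*

neither *expression* nor *control* alone names the relation — **together**
they signal *regulation of gene expression*, even though they sit five words
apart. `ino-mine` implements the dictionary-and-dependency approach to this
problem, for anyone building typed gene/protein interaction networks from
text: an interaction-type hierarchy in which each type carries

* **keyword patterns** — `//`-separated trigger combinations that must
  co-occur in one sentence but need not be adjacent
  (`expression//control`, `requires//transcription`), and
* **dependency patterns** — a single labeled grammatical relation
  `rel(governor, dependent)` between two triggers
  (`nsubj(control, expression)` reads "*expression* is the nominal subject
  of *control*").

Given a dependency parse, two trigger mentions joined by **one dependency
edge** whose label and governor/dependent words match a dictionary pattern
give the strongest (`direct_dependency`) evidence for the type; trigger
sets that merely co-occur give weaker (`cooccurrence`) evidence; one-word
types give `single_keyword` evidence. Sentences with ≥ 2 tagged
genes/proteins and ≥ 1 trigger yield typed interaction records, which
aggregate into an undirected network and roll up the type hierarchy with
set semantics (a record counts once per ancestor, diamonds never
double-count). Count tables can be compared by a two-sided Fisher exact
test with Benjamini–Hochberg adjustment.

## Worked example

```python
from ino_mine import (packaged_examples, tag_keywords, token_gap,
                      directly_connected, classify_sentence)
from ino_mine.fixtures import WORKED_EXAMPLE_ID

ex = packaged_examples()                # 7 curated sentences + parses,
s, g = ex.items[WORKED_EXAMPLE_ID]      # 10-term dictionary, gene lexicon
kws = tag_keywords(s, ex.ontology)
print(sorted({m.matched for m in kws}))
exp = next(m for m in kws if m.matched == "expression")
ctl = next(m for m in kws if m.matched == "control")
print(token_gap(s, exp, ctl))
print(directly_connected(g, exp, ctl).label)
top = classify_sentence(s, g, kws, ex.ontology)[0]
print(top.evidence, ex.ontology[top.term_iri].label)
```

prints

```
['control', 'expression']
5
nsubj
direct_dependency regulation of gene expression
```

i.e. the two triggers are tagged, are 5 words apart, are joined by a single
`nsubj` edge (governor *control*), and the top-ranked interaction type is
*regulation of gene expression* with direct-dependency evidence. The
companion negative example (`lll-indirect-binds-promoters`: *"GerE binds to
a site on one of these promoters, …"*) tags *binds* and *promoters* but
finds **no** connecting edge, so the binding-to-promoter type is assigned
with co-occurrence evidence only.

## Command line

```bash
ino-mine --seed 9 fixtures --out fix/          # synthetic corpus bundle
ino-mine extract --dict fix/dictionary.tsv --lexicon fix/lexicon.tsv \
    --conllu fix/parses.conllu --corpus fix/corpus.txt --out net.tsv
ino-mine rollup --dict fix/dictionary.tsv --network net.tsv --out roll.tsv --tree
ino-mine tag --dict fix/dictionary.tsv --lexicon fix/lexicon.tsv --corpus fix/corpus.txt
```

`fixtures` writes a deterministic synthetic corpus (sentences, CoNLL-U
parses, gold records, dictionary, lexicon) with planted trigger pairs;
`extract` builds the interaction network (`tsv`, `json`, `graphml` or
`sif`); `rollup` aggregates counts up the hierarchy and can print an
indented tree such as

```
interaction [0/130]
  regulation [0/130]
    regulation of expression [8/8]
    ...
```

(`direct/cumulative` counts per term).

## File formats

* **Dictionary TSV** — `iri  label  parents  keywords  dep_patterns`;
  `|`-separated lists within cells; an optional OWL/RDF loader
  (`ino_mine.owl.load_owl`) resolves the two annotation properties by their
  labels *has literature mining keywords* / *has keyword dependency pattern*.
* **Lexicon TSV** — `symbol  synonyms` (`|`-separated synonyms mapping to
  the canonical symbol).
* **Corpus** — one sentence per line, optional `id<TAB>` prefix.
* **Parses** — standard 10-column CoNLL-U; `# sent_id` comments link parses
  to corpus sentences; the DEPS column may add enhanced edges.

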