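# Methods

## The model

`ino-mine` treats interaction-type assignment as dictionary-driven pattern
matching over dependency parses. An interaction type is an ontology class
(e.g. *regulation of transcription*) annotated with two kinds of textual
evidence:

1. **Keyword patterns** (`kw1//kw2//...`): a set of 1–n trigger keywords
   that jointly signal the type when they all occur in one sentence.
   Component order is stored but matching is order-insensitive — the same
   type legitimately carries both `transcription//dependent` and
   `regulated//transcription`, and sentences realise the components in
   either order.
2. **Dependency patterns** (`rel(governor, dependent)`): a single labeled
   grammatical relation between two trigger lemmas, read with the Universal
   Dependencies convention (`nsubj(control, expression)` = "*expression* is
   the nominal subject of *control*").

The core assumption is the **direct-connection criterion**: two trigger
mentions jointly signal one interaction type when a single dependency edge
links them. This captures long-distance pairings (the worked example's
triggers are 5 words apart but one `nsubj` edge apart) while rejecting
accidental co-occurrence. Pairs that are only path-connected (≥ 2 edges)
are demoted to co-occurrence evidence rather than discarded; an optional
extension to longer paths was considered and deliberately left out —
pattern matching is strictly single-edge, and everything else flows through
the co-occurrence route.

Evidence is ordered `direct_dependency > cooccurrence > single_keyword`.
Sentence classification ranks matches by evidence, then hierarchy depth
(most specific type first), then IRI — a total order, so results are
invariant to input ordering.

## Matching details and edge cases

* **Labels.** Enhanced-representation subtypes are normalized to base
  labels before comparison (`nmod:of` → `nmod`); dictionaries are written
  with base labels. `base_label` is idempotent.
* **Direction.** Connectivity ignores edge direction; pattern matching
  respects the governor/dependent roles. The root attachment (HEAD = 0)
  never participates in connectivity.
* **`GeneX-` placeholder.** A pattern keyword `GeneX-dependent` matches any
  hyphen-bearing single token with that suffix (`sigmaK-dependent`,
  `B-dependent`). Complementarily, a plain dictionary keyword `k` also
  matches a single token ending in `-k`, which is what makes gene-prefixed
  adjectives taggable at all. Both suffix routes are restricted to
  spaceless (single-token) spans.
* **Ties.** `directly_connected` scans edges in ascending
  (governor, dependent, label) order and returns the first hit; multi-way
  keyword-to-mention assignment in co-occurrence matching is the
  lexicographically leftmost injective assignment (backtracking over ≤ 4
  keywords). Both tie-breaks are deterministic and permutation-stable.
* **Degenerate inputs.** Empty sentences, overlapping mention pairs,
  cyclic hierarchies, unknown IRIs, and zero-margin 2×2 tables raise typed
  errors; a dependency pattern whose keywords are missing from the term's
  own keyword patterns only warns, since the annotation convention does not
  require the redundancy.

## Tokenization

Whitespace split, then leading/trailing sentence punctuation is split into
separate tokens. Hyphenated words stay intact (`sigmaK-dependent`), tokens
with internally balanced parentheses stay intact (`sigma(F)`), and a
leading hyphen is never stripped (`-35`). Under these rules the worked
example tokenizes to 13 word tokens plus the final period, and the two
triggers are exactly 5 *word* tokens apart (punctuation is excluded from
the gap count). No stemming or lemmatization is applied by default —
dictionaries already list inflected forms (`regulated`, `requires`) — but
keyword matching can use CoNLL-U lemmas via a flag.

## Pipeline policies

* **Eligibility**: a sentence contributes records iff ≥ 2 distinct tagged
  entities and ≥ 1 trigger mention.
* **All-pairs pairing**: every unordered entity pair in an eligible
  sentence receives every matched type (best evidence per type). This
  over-generates on sentences where only some pairs truly interact — in the
  worked example the sigF–sigG pair is a known false positive — and the run
  manifest flags this. Gold-pair filtering is a classifier's job, not this
  package's.
* **Undirected records**: pairs are stored in lexicographic order;
  direction survives only inside the evidence (governor/dependent roles).
  One record per (pair, sentence, term).

## Rollup and statistics

Direct counts are per exact term; cumulative counts propagate each record
to all ancestors with **set semantics**, so multi-parent terms never
double-count and any root's cumulative count equals the number of records
in its descendant closure (conservation; monotone along child → parent).
Because published summaries are ambiguous about whether such tables count
sentences or gene pairs, `rollup_counts` takes
`count_unit = records | pairs | sentences` and asserts neither as canonical.

Enrichment of a foreground count table against a background uses the
standard two-sided Fisher exact test on (term vs not-term) ×
(foreground vs background-minus-foreground), with Benjamini–Hochberg
adjustment across tested terms. The literature this method descends from
mentions a "modified" Fisher variant without specifying it; the
modification is explicitly out of scope here, and the implementation is
verified against an exhaustive hypergeometric enumeration oracle (agreement
to < 1e-12 for margins ≤ 30).

## Synthetic data

The generator emulates LLL-style gene-regulation sentences: per sentence,
two fresh gene symbols (3 lowercase + 1 uppercase letter, the *B. subtilis*
shape), 1–4 planted triggers, and a dependency tree from one of five
templates instantiating the five canonical relation shapes (nsubj,
nsubjpass, dobj, amod via a gene-prefixed adjective, nmod), plus a
single-keyword template. Defaults: 77 sentences (the size of the benchmark
corpus this setting is modeled on), keyword range 1–4, 2 entities,
`p_direct_edge = 1.0`, `distractor_rate = 0.0`.

With probability `p_direct_edge` the planted pair is connected by the
intended labeled edge; otherwise the dependent trigger is re-attached to an
intervening token so the pair is ≥ 2 edges apart (gold evidence becomes
`cooccurrence`). Distractors are trigger-like verbs absent from the
dictionary, attached to the root. The gold file is the *expected pipeline
output* by construction, so with `p_direct_edge = 1.0` and no distractors
the pipeline's precision and recall against gold are exactly 1.0 — this
validates the machinery, not performance on real text: real corpora add
parser errors, unseen trigger vocabulary, nested/coordinated structures,
and genuinely interacting-pair ambiguity that the templates do not model.

Acceptance runs use 12-sentence corpora across 20 seeds (≈ 200 planted
direct records per run), a size chosen to exercise every template and
evidence route while keeping the whole script under a minute.

## Curated examples

Seven packaged sentences carry hand-written CoNLL-U parses. One edge per
sentence is anchored to the relation the sentence is known for
(`nsubj(control, expression)`, `nsubjpass(recognized, promoter)`,
`dobj(inhibit, activity)`, `amod(transcription, sigmaK-dependent)`,
`nmod(essential, expression)`, and the negative binds/promoters case where
the triggers are deliberately 3 edges apart); all remaining attachments are
our own plain UD-style choices and are not claimed to match any particular
parser's output. Exact reproduction of parse-dependent corpus statistics is
therefore out of reach by design — parser version changes the trees — and
the packaged suite instead guarantees 100 % recovery of the anchored
pattern edges.

## Known limitations

* No statistical NER, abbreviation resolution, or species disambiguation;
  entity tagging is exact lexicon lookup (case-sensitive by default because
  gene symbols are case-meaningful).
* Interactions signaled by > 2 keywords are matched by co-occurrence only;
  chained multi-edge dependency validation is not attempted.
* Cross-sentence interactions are out of scope.
* The benchmark annotation file whose headline counts motivated this design
  is supplementary material of its publication and is not redistributed;
  `ino_mine.lll` parses any table of that shape and recomputes the summary
  statistics, verified on synthetic tables with hand-counted totals.
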