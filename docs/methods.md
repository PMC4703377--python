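# Methods

## Problem setting

Historical medical archives refer to one concept by many terms, and the
terms drift across decades (*phthisis* and *consumption* give way to
*pulmonary tuberculosis* and *TB*). Modern thesauri cover today's
terminology well but historical variants poorly, so query expansion and
entity linking over such archives need a corpus-driven inventory of
related terms. histmine builds that inventory with count-based
distributional semantics and ships the evaluation machinery the task
needs.

## Distributional model

**Context collection.** Documents are tokenized (hyphenated words stay
single tokens), sentence-split (terminal punctuation followed by
whitespace and an uppercase letter, with an abbreviation guard), and
lemmatized. For each occurrence of a term — longest-match,
non-overlapping, left-to-right over lemma sequences — up to `window`
(default 3) raw token positions on each side of the phrase boundaries are
collected. Stop-words and out-of-vocabulary lemmas *occupy* window
positions but are dropped from the collected slots; the window does not
extend to compensate. Windows do not cross sentence boundaries by default
(`cross_sentence` flag). Interior words of a multi-word occurrence are
never context. The lexical-unit vocabulary is the `cap` (default 150,000)
most frequent non-stop-word lemmas, ties broken lexicographically.

**Weighting.** Each (term *t*, unit *u*) pair is scored by Dunning's G²
over the 2×2 table `k11 = c(t,u)`, `k12 = c(·,u) − k11`,
`k21 = c(t,·) − k11`, `k22 = N − k11 − k12 − k21`, where marginals and N
are row/column/grand sums of the slot-count matrix. G² is a log-likelihood
ratio of association; the convention `0·ln 0 = 0` applies. Weights are
clamped to zero when `k11 ≤ E11` (negative association), which keeps
vectors non-negative and cosine similarity on [0, 1] — the scale the 0.8
pair-export threshold presumes.

**Composition.** The additive model (BAM) sums constituent vectors over
the union of supports. "Combining into one large vector" admits a
concatenation reading, but cosine between vectors of different
dimensionality is undefined, so element-wise sum over the shared unit
space is the implementation. The multiplicative model (BMM) multiplies
element-wise over the intersection of supports: only context shared by
*all* constituents survives, which is more faithful for non-compositional
phrases but needs far more data. For single-word terms SA, BAM and BMM
coincide (composition of one is the identity).

**Neighbor search.** Top-k (default 20) candidates by cosine, excluding
the source and any candidate whose normalized form equals it; exact float
comparison then lexicographic tie-break makes orderings
platform-deterministic. The candidate pool defaults to every single-word
lexical unit with corpus frequency ≥ `inventory_min_freq` (default 5) plus
any multi-word source; an explicit pool (entity-recognizer output, a
thesaurus term list) can be passed instead, since the right pool is
corpus- and application-specific.

**Source-term selection.** Terms with corpus frequency strictly greater
than `source_min_count` (20) and strictly less than `source_max_count`
(1000), optionally restricted to thesaurus members, ranked by frequency,
truncated at `n_sources` (500). Both bounds are deliberately strict and
the 0.8 pair-export threshold deliberately inclusive; both conventions are
pinned by tests.

**Per-collection builds.** Vectors are built per archive by default
(`per_collection`), since context statistics differ across archives with
different registers; a merged build is one flag away.

## Evaluation apparatus

**Thesaurus-driven P/R@k.** Per source: precision@k is 1 if any top-k
target shares a thesaurus concept with the source; recall@k is the
fraction of the source's thesaurus synonyms (all co-concept terms, source
excluded) found in the top-k. Both are macro-averaged; sources absent
from the thesaurus (precision) or without synonyms (recall) are excluded
from the respective means. The macro choice follows from the per-source
definitions; the recall denominator counts *all* synonyms, including ones
unattainable in the corpus, which depresses absolute recall exactly as
multi-synonym concepts should. Curves over k = 1..20 are monotone by
nestedness of top-k lists.

**Relation summaries.** The nine expert categories (Synonym, isA,
isParent, Affects, isAffectedBy, SpatiallyRelated, OtherRelation,
Unrelated, Non-disease pair) are totalled with whole-percent shares under
round-half-away-from-zero; the first seven aggregate to "semantically
related". The published categorisation table this reproduces is
internally inconsistent by two pairs (its nine counts sum to 346 against
a printed total of 348 and a printed aggregate of 216). Raising the
Affects count from 10 to 12 is the unique single-cell correction that
makes counts, total, aggregate and every printed percentage mutually
consistent, so the acceptance assets use that reconstruction and the raw
printed counts side by side; `summarize_relations` itself always computes
the total from its inputs.

**Span matching.** Exact mode requires identical (document, start, end,
category); relaxed mode requires the category to agree and intervals to
overlap by ≥ 1 character, with one-to-one assignment greedy by descending
overlap (ties: earlier gold start, then earlier pred start). Relaxed
matching is category-constrained because relaxed scores are reported per
category. Overall rows are micro-averages over pooled TP/FP/FN. Every
exact match is a relaxed match, so F(exact) ≤ F(relaxed) holds for all
inputs; swapping annotator roles swaps P and R and preserves F. An empty
gold *and* empty prediction set scores 1.0 with a degenerate flag.

**Agreement.** Cohen's kappa with chance agreement from the product of
marginal distributions; perfect observed agreement returns 1.0 even when
the chance term degenerates.

**Thesaurus linking.** A historical concept links to a modern concept
when any historical term equals, or lies within a length-scaled
Levenshtein distance (≤ max(1, ⌊len/10⌋)) of, any modern term — a concrete
instantiation of "matched or closely resembled" that tolerates one edit
for short terms (*tumour*/*tumor*) and scales gently for long ones.
Distances come from the edlib bindings.

**k-fold splitting.** Stratified by (archive, decade): within each
stratum documents are shuffled by a stream derived from the seed and
dealt round-robin with a rotating starting fold, so per-stratum fold
sizes differ by at most one.

## Dictionary pre-annotation

External-category → target-category rules carry optional filters:
`min_tokens` (strict length), `require_noun_head` (final token tagged
noun), `require_noun_phrase` (candidate within one maximal DET/ADJ/NOUN
run — the bundled chunker approximation; the chunker is pluggable).
Filters are monotone: enabling one never adds spans. Matching is on
lemmas, longest-match, non-overlapping; when two rules map one candidate
to different targets the lexicographically first target wins, keeping
output spans disjoint.

## Lemmatizer

The linguistic backend is an interface; the bundled default is a
deterministic rule system (closed-class lexica; plural→singular suffix
rules; -ing/-ed stripping with an exception list; suffix-based coarse
POS). It exists so the full pipeline is reproducible with no external
models and is adequate for frequency ranking and window collection; it is
not a tagging benchmark, and a statistical tagger can be plugged in where
tagging quality matters.

## Synthetic-data generator

The generator emulates the one statistical assumption the models rely on:
synonymous terms share context distributions. Each concept owns
`signature_size` (8) dedicated signature words, disjoint across concepts
so recovery has a well-defined ceiling; each sentence plants one term
surrounded by `window_words` (3) draws per side from a
(1 − noise_rate)·signature + noise_rate·background mixture, padded with
background words. The default scenario — 20 concepts × 2 synonyms, a
400-word background vocabulary, 10% noise, 80 documents × 100 sentences
(≈ 200 mentions per term), years uniform over 1850–1969 — is sized so
that context vectors are well-estimated but the whole pipeline runs in
seconds. Multi-word synonyms pair a synonym-specific modifier with a
shared per-concept head ("scarlet fever" / "scarlatinal fever"). Era maps
assign synonyms to hard year ranges; synonym choice is then deterministic
given the document year, emulating diachronic replacement. Gold spans are
recorded at exact character offsets, the gold thesaurus lists every
planted synonym set, and identical configs (seed included) produce
byte-identical artifacts.

What the generator does *not* emulate: English grammar, OCR noise,
polysemy, frequency skew (Zipfian tails), or signature overlap between
related concepts (signatures are disjoint by construction).
Passing recovery tests therefore demonstrates correctness of the counting,
weighting, composition and ranking machinery under the model's own
assumptions — not absolute performance on real archives, which depends on
corpus size, OCR quality and thesaurus coverage.

## Numerical and format choices

- Offsets are 0-based, end-exclusive, over unicode code points (the brat
  convention). Discontinuous brat spans are rejected; attribute/relation
  lines pass through unparsed.
- Metadata is UTF-8 TSV with a header; thesauri are
  `concept<TAB>term[<TAB>external_category]` rows, normalized to
  lowercase with collapsed whitespace (hyphen folding opt-in).
- Accumulation in double precision; G² evaluated vectorized with
  `0·ln 0 = 0` handled explicitly; a tiny-negative guard clamps round-off.
- The vector store is a self-contained delimited text format (term, model,
  unit=weight pairs) with full `repr` precision, so stores round-trip
  exactly.
- One global seed fans out to per-stage seeds by mixing a stable CRC of
  the stage name, keeping stages independently reproducible and all
  derived seeds below 2³¹.

## Known limitations

- The rule lemmatizer over-stems rare irregular forms; this perturbs unit
  identities uniformly across models and does not affect comparisons.
- BMM on small corpora is exactly as brittle as its definition implies;
  with concept-pure constituents (as in the generator's multi-word
  scenario) it can tie BAM, so the BAM ≥ BMM comparison is asserted as an
  inequality, not a gap.
- Annotation counts over the released historical gold-standard corpus
  require that corpus to be downloaded; the counting path is instead
  verified end-to-end on generated brat corpora with exactly known
  counts.
- Absolute P/R@k on real archives (and trained-tagger F-scores) require
  licensed resources and full archives, and are out of scope; the
  evaluation here pins definitions, conventions and curve shapes.
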