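# Methods

## The triage model

Triage is cast as ranked retrieval: for a query consisting of a gene symbol
(plus optional synonyms) and a curation axis (PPI or PTM), every abstract in
the corpus receives a score and the curator reads from the top. The score has
two parts.

**Engine score.** Okapi BM25 over lowercased word tokens of title +
abstract, with k₁ = 1.2 and b = 0.75. The idf uses the `ln(1 + …)` form so
scores are never negative; a negative engine score would silently invert the
meaning of the fusion weights. Repeated query terms contribute once. Ranking
ties break by PMID descending, which makes every ranking fully
deterministic.

**Concept density.** Each axis has a small controlled vocabulary
(`litriage/data/*.tsv`). Concepts are matched by *stem prefix* over word
tokens: the stem `phosphorylat` matches any token that starts with it. This
is deliberately not a stemming algorithm applied to the text — the
vocabulary lists truncated forms, and prefix matching against them is both
faster and exactly reproducible. Multi-token stems (e.g. `two hybrid`)
match a window of consecutive tokens, each by prefix, and multi-word
canonical labels additionally match by exact lowercase phrase equality.
Hyphens and slashes separate tokens, so "ubiquitin-mediated" exposes
"ubiquitin" and "ADP-ribosylation" exposes "ribosylation"; digits stay
inside tokens. When candidate matches overlap, the longest wins and matches
never overlap. Offsets are 0-based half-open positions in
`title + " " + abstract`, and each match records the index of the sentence
that contains it (sentences split after `.`/`!`/`?` followed by whitespace
and an uppercase letter or digit — a simple rule that knowingly splits
"Fig. 2").

From the annotations of a document we keep, per concept, the term frequency
`tf_c` and the canonical-label length `len_c` (characters; a crude
specificity proxy — longer descriptor names tend to be more specific), and
the distinct-concept count `D`.

**Fusion.** The fused score is `α·s + β·density` with the density term
either `D` (variant `distinct_count`) or `Σ_c ln(1 + len_c·tf_c)` (variant
`log_len_tf`; natural log, fixed). The four shipped presets are
PPI_base (0.9, 1.5), PTM_base (0.9, 1.7), PPI_refined (1.0, 0.1 on
log_len_tf) and PTM_refined (1.4, 1.3). Engine scores enter raw — the
weights are absolute and no per-query normalization is applied (a min–max
switch exists in the API but defaults off). Re-ranking never adds or drops
documents; documents with no axis concept keep `D = 0` rather than being
filtered.

**Query refinement** appends axis trigger keywords to the engine query:
`binds, interacts, associates` (PPI) or `phosphorylates` (PTM). These
keywords affect the engine score only; they are never counted as concept
descriptors, keeping the two fusion components independent.

**Boolean baseline.** The traditional search mode: documents matching an
AND/OR condition ranked by publication date, most recent first (undated
documents last, ties by PMID descending). This stands in for date-driven
Boolean bibliographic search; a proprietary live relevance sort is
deliberately not emulated, since it is unpublished and network-dependent.

## Corpus handling

MEDLINE XML (`PubmedArticleSet` subset: PMID, ArticleTitle, AbstractText,
PubDate, PublicationTypeList) and a TSV dialect are supported. Dates with
missing month/day are completed as January 1st, which turns a
"published after December 2013" cut-off into a pure year test when only the
year is known. Filters (date window, publication-type exclusion with
case-insensitive labels, explicit PMID exclusion) are pure and idempotent;
undated documents are kept unless a date bound is set, in which case they
are dropped with a warning (the conservative reading of a hard temporal
cut). The typical evaluation filter excludes `Review` and
`Retracted Publication` types, which curators do not annotate from.

## Bundled vocabularies

The PTM thesaurus lists the 16 most frequently curated modification types
(phosphorylation, methylation, dephosphorylation, glycosylation,
nitrosylation, palmitoylation, deubiquitination, polyADP-ribosylation,
acetylation, desumoylation, myristoylation, deacetylation, farnesylation,
ubiquitination, sumoylation, protein cleavage). The PPI thesaurus has 23
concepts: 14 interaction-term stems and 9 experimental interaction-detection
methods. The interaction stems are a **reconstruction**: the published
vocabulary is only partially enumerated in public sources, so the file
completes the named exemplars (bind, interact, associate, complex) with
common PPI trigger verbs and PSI-MI-style assay names, and its header says
so. Counts and structure are faithful; the exact word list is not
guaranteed to match the original resource.

## Evaluation

Qrels are binary; graded judgements are rejected. P@1 is reported alongside
MRR rather than conflated with it (the two coincide only when the first
relevant document is at rank 1 for every query); MAP divides by the total
number of relevant documents in the qrels, so unretrieved relevant documents
count against a run. Queries judged but absent from a run contribute 0 to
every mean — the TREC convention, which penalizes empty retrieval. Relative
improvement is `100·(value − baseline)/baseline` and requires a positive
baseline.

## Synthetic benchmark

The generator plants the relevance signal the fusion method exploits. For
each of `n_queries` queries, `relevant_per_query` documents receive
`1 + Poisson(λ_rel)` mentions of the query gene and `1 + Poisson(μ_c)`
distinct axis concepts (each rendered once as a random morphological
variant: stem + random suffix, or the multi-word label). Every document
additionally mentions each other gene `Poisson(λ_irr)` times, and
non-relevant documents carry each concept independently with probability
`p_bg`. Filler tokens pad documents to a Poisson length, publication years
are uniform over `year_range`, and a fixed seed yields byte-identical
output. Defaults: 500 docs, 20 queries, 5 relevant/query, λ_rel = 3,
λ_irr = 0.3, μ_c = 1.5, p_bg = 0.05, ~120 tokens/doc, years 1990–2013,
filler vocabulary 1000 (a size chosen so filler terms are individually rare,
like real vocabulary tails). Text is token soup by design: BM25 and stem
matching see only tokens, so fluency would add nothing testable.

What the generator does *not* emulate: topical correlation between genes
(real papers discuss related kinases together), vocabulary burstiness and
Zipfian frequencies, genuine sentence structure, and the fact that in real
literature concept-rich papers are usually *about* the proteins they test.
Passing benchmarks on this generator therefore demonstrates mechanical
correctness of the pipeline and directional behaviour of the signals, not
real-world effectiveness.

## Behaviour at desk scale — a known limitation

On the default 500-document benchmark the BM25 engine alone already places
a relevant document at rank 1 for essentially every query (planted gene
mentions of ~4 versus a 0.3 background are an easy separation), and the
density-fused rankings score *below* the engine at P@1 while still far above
the Boolean recency baseline. This inversion is a corpus-scale artifact of
the absolute fusion weights: in a 500-document corpus a gene's idf is
ln(1 + (500 − df + 0.5)/(df + 0.5)) ≈ 1.3, so engine scores span roughly
1–2.5 while β·D spans 0–9, and the handful of background documents with
many distinct concepts outweigh the engine's evidence. In a multi-million
document collection the same gene's idf is an order of magnitude larger and
the density term acts as a tiebreaker among near-equal engine scores, which
is the regime the weights were tuned for. The package reports what it
measures; it does not rescale the weights to force the large-corpus
ordering at small scale. Users applying the presets to small corpora should
either enable score normalization or retune β downward.

## Numerical and design choices

- Natural logarithms throughout; fusion arithmetic is plain float64.
- BM25 parameters are configurable but fixed defaults (k₁ = 1.2, b = 0.75)
  are used everywhere for reproducibility; no DFR or other weighting models.
- Tie-breaks are always PMID descending, at every ranking stage.
- `SynthParams` permits λ_rel = λ_irr so a no-signal null corpus can be
  generated for sanity checks (all systems collapse toward chance).
- The generator's distinct-concept draw is capped at the thesaurus size;
  with the defaults the cap is effectively never hit
  (P(Poisson(1.5) ≥ 23) ≈ 0).
- Benchmark problem sizes (500 docs × 20 queries, medians over 5–10 seeds)
  keep the full ladder under ~10 s while leaving the Poisson separations
  clearly resolvable.

## Known limitations

- Gene/protein named-entity recognition is out of scope: queries match the
  literal gene symbol and synonyms as tokens. Homonymous symbols (e.g.
  *CAT*) would need synonym curation by the user.
- The sentence splitter is rule-based and knowingly imperfect around
  abbreviations; sentence indices are informative, not authoritative.
- The PPI interaction-stem list is a reconstruction (see above).
- The Boolean baseline models recency ranking only, not any engine's
  proprietary relevance sort.
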