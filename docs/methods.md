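# Methods

## Problem and model

`varlit` ranks literature for genomic-variant curation queries and ranks a
patient's variants by the volume and quality of literature retrieved for
each. The retrieval model is a two-step recall-then-precision design:

1. **Recall.** A triplet query (variant in a gene for a diagnosis) is
   compiled into a boolean `must`/`should` tree. Each entity contributes one
   must-clause; the disease and gene clauses pair the surface term with the
   lexicon concept id (so any annotated synonym of the concept matches); the
   variant clause holds one sub-clause per nomenclature synonym. Three
   relaxed queries, each omitting one entity, recover documents that miss
   one facet (an abstract on the same variant in another disease is still
   clinically useful). Each query returns at most 1000 documents.

2. **Precision.** Candidates (the union of the four queries' results) are
   re-scored with a linear fusion of five components (weights in
   parentheses): normalized BM25 retrieval status value (1.0), constraint
   relaxation (0.65), named-entity density (0.1), demographic concordance
   (0.05), predefined keywords (0.1). Non-English documents are placed in a
   second tier after all English documents.

Variant prioritization reuses the ranker per variant and scores each variant
by the sum of its documents' fused scores over the top 100 hits; a variant
without literature scores exactly 0.

## Parameters

All tuned constants live in `ScoringConfig` and can be overridden from a
flat `key=value` file. The defaults are the grid-searched optimum of the
deployed system this package re-implements:

| group | parameter | default |
|---|---|---|
| relaxation | disease+gene / disease+variant / gene+variant | 0.95 / 0.07 / 0.05 |
| NE density | disease / gene / drug | 0.97 / 0.51 / 0.57 |
| demographics | age weight / gender weight | 0.7 / 0.5 |
| demographics | bonus match / unmentioned / mismatch | 0.7 / 0.4 / 0.0 |
| keywords | bonus per positive, penalty per negative occurrence | +0.2 / −0.1 |
| keywords | positive stems | treat, drug, therap, prognos, surviv |
| keywords | negative stems | immuno, marker, detect |
| fusion | rsv / relax / ne / demo / kw | 1.0 / 0.65 / 0.1 / 0.05 / 0.1 |
| retrieval | clause-query depth / per-variant aggregation depth | 1000 / 100 |

BM25 uses k1 = 1.2, b = 0.75 and idf = ln(1 + (N − df + 0.5)/(df + 0.5)),
the default configuration of the search engine the design is modeled on.
Title tokens are indexed with the body, unweighted — there is no evidence a
field boost belongs in the reference configuration.

## Design choices where the design was open

- **RSV normalization.** BM25 is unbounded while the other four components
  live in [0, 1] (keywords in [−1, 1]), so the full-query RSV is min–max
  normalized over the candidate set before fusion; documents reached only by
  a relaxed query take RSV 0. A result list whose scores are all equal
  normalizes to 1 (those documents are its best results).
- **Combining relaxed queries.** Per document, the weighted normalized
  scores of the three relaxed queries are summed and clipped at 1 — a sum
  (rather than a max) rewards documents matching several relaxed facets.
- **NE density.** "Density" is realized as the saturating ratio
  c/(c+1) per entity type, weight-averaged over the three types: bounded,
  monotone in the counts, and indifferent to document length.
- **Demographic mismatch.** Only match and unmentioned bonuses are part of
  the tuned configuration; a document that contradicts the queried age group
  or gender gets bonus 0.0, the strongest penalty the bonus scale allows.
  Query ages map to MeSH-style check-tag bins: 0–1 infant, 2–5 preschool
  child, 6–12 child, 13–18 adolescent, 19–44 adult, 45–64 middle aged,
  ≥65 aged. The score normalizes over the attributes present in the query,
  and is 0 when the query carries no demographics.
- **Keyword matching.** The keyword lists are truncation stems (e.g.
  `prognos` covers prognosis/prognostic), so matching is prefix-on-token
  after lower-casing; counting is per occurrence, and the component clips at
  ±1 so pathological keyword stuffing cannot dominate the fusion.
- **Language downgrading.** Realized as a two-tier stable sort rather than a
  score multiplier: any English document precedes any non-English one, which
  is the literal reading of "ranked after".
- **Tie-breaking.** Final score descending, then publication date
  descending, then doc_id ascending — fully deterministic output.
- **Two-entity queries.** A query with only two of the three entities issues
  the full two-clause query and no relaxed queries (single-entity queries
  would be unweightable); the relaxation component is 0 for such queries.
- **Synonym inventory.** The expansion emits the protein dialects all
  printed examples use (HGVS three-/one-letter with and without `p.`/
  parentheses, bare forms) plus two colloquial arrow dialects, then compact
  and spaced coding-DNA descriptors; order is most-specific-HGVS-first,
  deduplicated, capped at 50. Genomic-level (`g.`) descriptors are omitted:
  they require transcript-to-genome structure the package deliberately does
  not model. Stop-codon and extension variants are rejected — the unit of
  expansion is a single-residue substitution between the 20 standard amino
  acids. An inconsistent registered CDS (wrong isoform, too short) yields no
  transcript-level forms rather than an error.
- **Normalization.** Tokens are lower-cased; hyphens joining alphanumerics
  are dropped (`B-RAF` ≡ `BRAF`); periods are dropped between alphanumerics
  *except* after a single-letter HGVS level prefix, so `p.Val600Glu`
  survives as one token. Multi-token variant forms (`1799 T > A`) are
  matched as positional phrases.
- **Comparison arithmetic.** Means and percentage gains are reported to one
  decimal and the common-document share to an integer percent; the gains on
  the mean rows are computed from the rounded (displayed) means, matching
  how such tables are read. Queries with an empty pooled union are excluded
  from the per-query content mean. Standard NDCG is implemented; the
  sampling-based inferred variant is out of scope because it depends on
  externally sampled judgment files.
- **Prioritizer aggregation** defaults to the fused score (`aggregate=rsv`
  switches to the normalized BM25 component alone) at depth 100 per
  variant, which bounds runtime without affecting the actionable/silent
  separation.

## Synthetic study conditions

The fixture generator defines the conditions every end-to-end result is
measured under. The default corpus plants three oncogene triplets
(BRAF V600E / melanoma, NRAS Q61R / melanoma, BRCA1 P871L / breast cancer),
six relevant documents per triplet, thirty distractors (documents mentioning
at most a partial triplet), and four non-English documents mentioning a full
triplet. Variant mentions are drawn from a fixed dialect mix — 30 %
one-letter, 20 % three-letter, 20 % HGVS protein, 15 % compact cDNA, 15 %
spaced cDNA — so each synonym mode has headroom to demonstrate its recall.
A CDS is generated per gene with the planted codon chosen so the protein
change is reachable by one nucleotide substitution. Half the documents carry
demographic subject tags; 40 % / 30 % carry positive / negative keyword
sentences (a relevant document with two positive sentences is graded 2,
otherwise 1). Case suites for prioritization follow an eight-case
composition — five cases with one gold variant, three with two, eleven gold
variants in total — each padded with silent variants whose genes the corpus
never mentions.

What passing on these fixtures shows: the pipeline's mechanics — synonym
expansion, boolean retrieval, fusion arithmetic, aggregation — behave as
specified, and recall ordering across synonym modes follows from dialect
coverage alone. What it does not show: performance on real biomedical prose
(the templates have near-degenerate token statistics), robustness to variant
mentions the expansion inventory misses, or calibration of the tuned weights
on real relevance judgments, all of which require external benchmark
collections.

## Numerical notes and edge cases

- Scores are plain double-precision sums; the fused score is reproducible
  from its stored components to 1e−9.
- `evaluate_clauses` on an empty corpus or an unmatched query returns an
  empty list, never an error; ranking an all-zero case returns every variant
  with aggregate 0 and a deterministic lexicographic order.
- R-Precision is undefined for queries without relevant documents; such
  queries are excluded from the macro average and logged.
- Relative gain against a zero baseline is 0 when both sides are 0 and +inf
  otherwise.
- All randomness flows from a single integer seed through `random.Random`;
  identical seeds give byte-identical fixtures.

## Problem sizes

Default verification sizes: brute-force BM25/metric equality on randomized
corpora of up to 50 documents and 200 random metric cases; codon
back-translation checked exhaustively over all 61 sense codons × 20 target
residues; fixture corpora of ~50 documents and case suites of 8 cases × 10
variants. These sizes make every property checkable exhaustively or
near-exhaustively while keeping the full suite in the low seconds.

## Known limitations

- Only single-residue protein substitutions are modeled: no indels, fusions,
  splice or regulatory variants, and no rsid/locus grouping.
- The dictionary annotator is exact-match over normalized tokens; it does
  not handle morphological variation beyond the normalization rules.
- The in-memory index is rebuilt per CLI invocation; the package targets
  desk-scale corpora, not a production index.
- Demographic scoring depends on subject tags (MeSH-style check tags);
  collections without such metadata always take the "unmentioned" bonus.
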