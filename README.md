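# varlit

Literature triage and variant prioritization for genomic variants.

Curating a genomic variant — deciding whether, say, BRAF V600E is clinically
actionable for a melanoma patient — requires searching the literature, and
the literature is hostile to exact-match search: the same substitution is
written `V600E`, `Val600Glu`, `p.Val600Glu`, or at the transcript level as
`c.1799T>A` / `1799 T > A`, and most mentioned variants appear in only a
handful of papers. `varlit` implements a high-recall retrieval pipeline for
(gene, variant, disease, demographics) queries plus the evaluation tooling
to measure it, entirely self-contained: a seeded synthetic-corpus generator
replaces any external collection.

## What it computes

**Synonym expansion.** A protein substitution `ref pos alt` is expanded into
up to 50 surface forms: HGVS protein dialects, bare one-/three-letter forms,
arrow colloquialisms, and — when a coding sequence is registered for the
gene — every single-nucleotide CDS substitution whose mutated codon
translates to the alternate residue (codon *n* spans CDS positions
3n−2…3n, so V600E on a GTG codon yields exactly `c.1799T>A`).

**Retrieval and re-ranking.** Documents are annotated with gene/disease/drug
lexicons and indexed in a two-field inverted index (text tokens with
positions; annotation concept ids). A query becomes a boolean tree of
`must`/`should` clauses — one must-clause per triplet entity, the variant
clause holding one sub-clause per synonym — scored with Okapi BM25
(k1 = 1.2, b = 0.75, idf = ln(1 + (N − df + 0.5)/(df + 0.5))). Because the
full triplet is often too strict, three relaxed queries each omitting one
entity are fused in. Every candidate document *d* is re-scored with

    score(d) = 1.0·RSV(d) + 0.65·relax(d) + 0.1·ne(d) + 0.05·demo(d) + 0.1·kw(d)

where RSV is the min–max-normalized full-query BM25 score; relax is the
weighted sum of normalized relaxed-query scores (disease+gene 0.95,
disease+variant 0.07, gene+variant 0.05); ne is a saturating density of
disease (0.97), gene (0.51) and drug (0.57) annotations; demo scores
age (0.7) / gender (0.5) concordance with the record's subject tags (bonus
0.7 match / 0.4 unmentioned / 0.0 mismatch); and kw adds +0.2 per
positive-keyword token (treat, drug, therap, prognos, surviv) and −0.1 per
negative one (immuno, marker, detect), clipped to [−1, 1]. Non-English
records always rank after English ones.

**Variant prioritization.** A case's variants are each searched with the
case's diagnosis and demographics; a variant's score is the sum of its
retrieved documents' fused scores, so variants with no literature rank last.

**Evaluation.** P@k, R-Precision, NDCG, top-k variant recall, TREC
qrels/run I/O, and a five-measure comparison of two systems' per-query
result sets (document means, pooled-content share, totals, more-results
counts, silence) with relative gains.

## Worked example

```
$ varlit make-fixture --seed 0 --out fix
wrote fixture with 52 documents to fix

$ varlit synonyms --variant V600E --mode all --cds fix/cds.fasta --gene BRAF
p.Val600Glu
p.V600E
p.(Val600Glu)
Val600Glu
V600E
c.1799T>A
1799 T > A
Val600→Glu
600 V→E

$ varlit search --gene BRAF --variant V600E --disease melanoma \
      --index fix --top 3 --format trec
q1 Q0 d0006 1 0.828262 varlit
q1 Q0 d0004 2 0.810596 varlit
q1 Q0 d0002 3 0.761939 varlit
```

The synonym list shows the full expansion: five protein dialects, the two
transcript-level descriptors derived from the registered CDS (the GTG→GAG
edit at CDS position 1799 is the only single-nucleotide path from valine to
glutamate), and two colloquial arrow forms. The search output is a TREC run:
the top documents are the planted relevant records for the BRAF triplet,
ordered by the fused score in column five.

```
$ varlit rank-variants --case fix/case.tsv --index fix
1	NRAS	Q61R	7.8360	10
2	BRAF	V600E	5.5106	8
3	BRCA1	P871L	0.6561	8
4	BRCA2	P51Q	0.0000	0
5	EGFR	P498L	0.0000	0
...
```

The three planted (actionable) variants accumulate positive aggregates from
their retrieved documents and occupy the top ranks; the silent padding
variants retrieve nothing and tie at zero. BRCA1 P871L scores lower than the
melanoma variants because the case's diagnosis is melanoma while its
literature is about breast cancer, so its documents are recovered only
through the gene+variant relaxed query — exactly the constraint-relaxation
behavior the fusion weights encode.

`varlit evaluate --run run.txt --qrels fix/qrels.txt` and
`varlit compare --a a.json --b b.json` score runs and contrast two systems.

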