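"""Synthetic corpora, lexicons, cases and relevance judgments.

Every other module is exercised against corpora generated here, so no
external collection is needed.  A fixture plants (gene, variant, disease)
triplets into templated abstract-like documents whose variant mention is
drawn from a controlled mix of surface dialects (one-letter, three-letter,
HGVS protein, compact/spaced coding-DNA), surrounded by distractor documents
mentioning only part of a triplet and by non-English documents.  A coding
sequence is generated for each planted gene whose planted codon is chosen so
the protein change is reachable by a single-nucleotide substitution, keeping
the cDNA surface forms consistent with the protein forms.  Relevance
judgments follow directly from the planting rules (grade 2 when a relevant
document also carries at least two positive-keyword sentences), so fixture
qrels are complete by construction.

Everything is driven by a single integer seed and is byte-identical across
runs with the same spec.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .corpus import Document, Lexicon, annotate_collection, write_jsonl, write_lexicons_tsv
from .nomenclature import (
    AA_1TO3,
    CODON_TO_AA,
    NUCLEOTIDES,
    ProteinVariant,
    cdna_synonyms,
    protein_synonyms,
    render_cdna,
)
from .prioritizer import CaseFile
from .triage import EntityRef, TripletQuery

__all__ = [
    "Fixture",
    "FixtureSpec",
    "FixtureSpecError",
    "default_spec",
    "generate_case",
    "generate_case_suite",
    "generate_corpus",
    "write_fixture",
]

SURFACE_FORMS = ("one_letter", "three_letter", "hgvs_p", "cdna_compact", "cdna_spaced")

_SENSE_CODONS = sorted(CODON_TO_AA)


class FixtureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic corpus.

    The defaults emulate a small triage study: a handful of well-known
    oncogene triplets, an order of magnitude more distractors than relevant
    documents per triplet, a sprinkle of non-English records, an even mix of
    protein-level dialects with a substantial coding-DNA share (the forms
    only full synonym expansion can recover), and moderate keyword/
    demographic salting so every scoring component is exercised.
    """

    seed: int = 0
    n_relevant: int = 6            # relevant docs per planted triplet
    n_distractor: int = 30
    n_foreign: int = 4             # non-English docs mentioning a triplet
    surface_form_mix: tuple[tuple[str, float], ...] = (
        ("one_letter", 0.30),
        ("three_letter", 0.20),
        ("hgvs_p", 0.20),
        ("cdna_compact", 0.15),
        ("cdna_spaced", 0.15),
    )
    triplets: tuple[tuple[str, ProteinVariant, str], ...] = ()
    demographic_rate: float = 0.5  # chance a doc carries age/gender tags
    positive_kw_rate: float = 0.4  # chance of a treatment/outcome sentence
    negative_kw_rate: float = 0.3  # chance of a biomarker/assay sentence

    def __post_init__(self) -> None:
        if min(self.n_relevant, self.n_distractor, self.n_foreign) < 0:
            raise FixtureSpecError("document counts must be non-negative")
        names = [n for n, _ in self.surface_form_mix]
        if sorted(names) != sorted(set(names)) or not set(names) <= set(SURFACE_FORMS):
            raise FixtureSpecError(f"surface forms must be among {SURFACE_FORMS}")
        total = sum(w for _, w in self.surface_form_mix)
        if abs(total - 1.0) > 1e-9:
            raise FixtureSpecError("surface_form_mix must sum to 1")
        if self.n_relevant > 0 and not self.triplets:
            raise FixtureSpecError("relevant documents require at least one planted triplet")


def default_spec(seed: int = 0, **overrides) -> FixtureSpec:
    """The default study conditions: three planted oncogene triplets."""
    triplets = (
        ("BRAF", ProteinVariant("V", 600, "E"), "melanoma"),
        ("NRAS", ProteinVariant("Q", 61, "R"), "melanoma"),
        ("BRCA1", ProteinVariant("P", 871, "L"), "breast cancer"),
    )
    return FixtureSpec(seed=seed, triplets=triplets, **overrides)


@dataclass(frozen=True)
class Fixture:
    """A generated corpus bundle."""

    documents: tuple[Document, ...]
    lexicons: tuple[Lexicon, ...]
    qrels: dict[tuple[str, str], int]
    cds_by_gene: dict[str, str]
    queries: dict[str, TripletQuery]       # query id → triplet query
    #: query id → doc ids planted as relevant (equals the qrels support)
    relevant_docs: dict[str, tuple[str, ...]]


# --------------------------------------------------------------------------
# CDS construction
# --------------------------------------------------------------------------

def _codon_for(ref: str, alt: str, rng: random.Random) -> str:
    """A codon encoding ``ref`` preferring one a single substitution away
    from encoding ``alt``."""
    reachable = []
    fallback = []
    for codon in _SENSE_CODONS:
        if CODON_TO_AA[codon] != ref:
            continue
        fallback.append(codon)
        for i in range(3):
            if any(
                CODON_TO_AA.get(codon[:i] + nt + codon[i + 1:]) == alt
                for nt in NUCLEOTIDES if nt != codon[i]
            ):
                reachable.append(codon)
                break
    pool = reachable or fallback
    return rng.choice(pool)


def _make_cds(v: ProteinVariant, rng: random.Random) -> str:
    """Random sense-codon CDS long enough for ``v``, with the planted codon
    chosen so the substitution is single-nucleotide reachable."""
    n_codons = v.position + rng.randint(1, 5)
    codons = ["ATG"] + [rng.choice(_SENSE_CODONS) for _ in range(n_codons - 1)]
    codons[v.position - 1] = _codon_for(v.ref_aa, v.alt_aa, rng)
    return "".join(codons)


# --------------------------------------------------------------------------
# Lexicons
# --------------------------------------------------------------------------

_DRUGS = ("vemurafenib", "trametinib", "olaparib", "dabrafenib")


def _build_lexicons(triplets: Sequence[tuple[str, ProteinVariant, str]]) -> list[Lexicon]:
    genes: dict[str, tuple[str, ...]] = {}
    diseases: dict[str, tuple[str, ...]] = {}
    for gene, _, disease in triplets:
        syns = [gene, f"{gene[0]}-{gene[1:]}", f"{gene} gene"]
        if gene == "BRAF":
            syns = ["BRAF", "BRAF1", "RAFB1", "B-RAF"]
        genes[f"GENE:{gene}"] = tuple(syns)
        key = f"DIS:{disease.upper().replace(' ', '_')}"
        diseases[key] = (disease, f"{disease} tumor", f"advanced {disease}")
    drugs = {f"DRUG:{d.upper()}": (d,) for d in _DRUGS}
    return [
        Lexicon("gene", genes),
        Lexicon("disease", diseases),
        Lexicon("drug", drugs),
    ]


# --------------------------------------------------------------------------
# Document templating
# --------------------------------------------------------------------------

_RELEVANT_FRAMES = (
    "Patients with {disease} harboring the {gene} {variant} mutation were studied.",
    "We report a cohort of {disease} cases carrying {variant} in the {gene} gene.",
    "The {gene} {variant} substitution was frequent in {disease} specimens.",
    "Activating {gene} mutations such as {variant} drive progression of {disease}.",
)
_POSITIVE_SENTENCES = (
    "Targeted treatment improved survival in the treated arm.",
    "Combination drug therapy yielded a favorable prognosis.",
)
_NEGATIVE_SENTENCES = (
    "The variant served as a diagnostic marker in an immunoassay.",
    "Detection relied on immunohistochemistry marker panels.",
)
_DISTRACTOR_FRAMES = (
    "Expression of {gene} was profiled in normal tissue.",
    "Epidemiology of {disease} in a population registry.",
    "A screen of {gene} alterations in {disease} cell lines found no hotspot.",
    "Histology atlas of benign lesions and reactive stroma.",
)
_FILLER = (
    "Samples were processed following standard operating procedures.",
    "Clinical records were reviewed retrospectively by two readers.",
    "Statistical analysis used nonparametric rank methods.",
    "The study protocol was approved by the institutional board.",
)

_AGE_TAG_POOL = ("adult", "middle aged", "aged", "child", "adolescent")
_GENDER_TAG_POOL = ("female", "male")
_FOREIGN_LANGS = ("fr", "de", "es")


def _surface_form(
    kind: str, v: ProteinVariant, cds: str, rng: random.Random
) -> tuple[str, str]:
    """Render the variant in the requested dialect; returns (form, realized
    kind) — cDNA kinds fall back to the protein form if no single-nucleotide
    path exists."""
    if kind == "one_letter":
        return str(v), kind
    if kind == "three_letter":
        return v.three_letter, kind
    if kind == "hgvs_p":
        return f"p.{v.three_letter}", kind
    cdna = cdna_synonyms(v, cds)
    if not cdna:
        return str(v), "one_letter"
    cv = rng.choice(cdna)
    if kind == "cdna_compact":
        return render_cdna(cv), kind
    return render_cdna(cv, spaced=True), kind


def _pick_form_kind(spec: FixtureSpec, rng: random.Random) -> str:
    r = rng.random()
    acc = 0.0
    for name, w in spec.surface_form_mix:
        acc += w
        if r < acc:
            return name
    return spec.surface_form_mix[-1][0]


def _random_date(rng: random.Random) -> str:
    return f"{rng.randint(2012, 2021)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"


def _demo_tags(spec: FixtureSpec, rng: random.Random) -> tuple[str, ...]:
    tags: list[str] = []
    if rng.random() < spec.demographic_rate:
        tags.append(rng.choice(_AGE_TAG_POOL))
    if rng.random() < spec.demographic_rate:
        tags.append(rng.choice(_GENDER_TAG_POOL))
    return tuple(tags)


def generate_corpus(spec: FixtureSpec) -> Fixture:
    """Generate the full fixture bundle for a spec (see module docstring)."""
    rng = random.Random(spec.seed)
    cds_by_gene = {g: _make_cds(v, rng) for g, v, _ in spec.triplets}
    lexicons = _build_lexicons(spec.triplets)

    docs: list[Document] = []
    qrels: dict[tuple[str, str], int] = {}
    relevant_docs: dict[str, list[str]] = {}
    queries: dict[str, TripletQuery] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"d{counter:04d}"

    for t_idx, (gene, v, disease) in enumerate(spec.triplets, 1):
        qid = f"q{t_idx}"
        queries[qid] = TripletQuery(
            gene=EntityRef(gene, f"GENE:{gene}"),
            variant=v,
            disease=EntityRef(disease, f"DIS:{disease.upper().replace(' ', '_')}"),
        )
        relevant_docs[qid] = []
        for _ in range(spec.n_relevant):
            kind = _pick_form_kind(spec, rng)
            form, _ = _surface_form(kind, v, cds_by_gene[gene], rng)
            frame = rng.choice(_RELEVANT_FRAMES)
            sentences = [frame.format(gene=gene, variant=form, disease=disease)]
            n_pos = 0
            if rng.random() < spec.positive_kw_rate:
                n_pos = rng.randint(1, 2)
                sentences.extend(rng.sample(_POSITIVE_SENTENCES, n_pos))
            if rng.random() < spec.negative_kw_rate:
                sentences.append(rng.choice(_NEGATIVE_SENTENCES))
            if rng.random() < 0.5:
                sentences.append(rng.choice(_DRUGS).capitalize()
                                 + " was administered to a subset of patients.")
            sentences.append(rng.choice(_FILLER))
            did = next_id()
            docs.append(Document(
                doc_id=did,
                title=f"{gene} variation in {disease}: report {did}",
                body=" ".join(sentences),
                language="en",
                subject_tags=_demo_tags(spec, rng),
                pub_date=_random_date(rng),
            ))
            qrels[(qid, did)] = 2 if n_pos >= 2 else 1
            relevant_docs[qid].append(did)

    # non-English documents: mention a full triplet but in another language tier
    for _ in range(spec.n_foreign):
        if not spec.triplets:
            break
        t_idx = rng.randrange(len(spec.triplets))
        gene, v, disease = spec.triplets[t_idx]
        qid = f"q{t_idx + 1}"
        did = next_id()
        docs.append(Document(
            doc_id=did,
            title=f"Etude de {gene} {v} dans {disease}",
            body=f"La mutation {gene} {v} est observee dans {disease}. "
                 + rng.choice(_FILLER),
            language=rng.choice(_FOREIGN_LANGS),
            subject_tags=_demo_tags(spec, rng),
            pub_date=_random_date(rng),
        ))
        qrels[(qid, did)] = 1
        relevant_docs[qid].append(did)

    # distractors: at most a partial triplet, never the planted variant
    for _ in range(spec.n_distractor):
        if spec.triplets:
            gene, v, disease = spec.triplets[rng.randrange(len(spec.triplets))]
        else:
            gene, v, disease = "GENEX", ProteinVariant("A", 5, "T"), "carcinoma"
        frame = rng.choice(_DISTRACTOR_FRAMES)
        sentences = [frame.format(gene=gene, disease=disease)]
        if rng.random() < spec.positive_kw_rate:
            sentences.append(rng.choice(_POSITIVE_SENTENCES))
        if rng.random() < spec.negative_kw_rate:
            sentences.append(rng.choice(_NEGATIVE_SENTENCES))
        sentences.append(rng.choice(_FILLER))
        did = next_id()
        docs.append(Document(
            doc_id=did,
            title=f"Background study {did}",
            body=" ".join(sentences),
            language="en",
            subject_tags=_demo_tags(spec, rng),
            pub_date=_random_date(rng),
        ))

    annotated = annotate_collection(docs, lexicons)
    return Fixture(
        documents=tuple(annotated),
        lexicons=tuple(lexicons),
        qrels=qrels,
        cds_by_gene=cds_by_gene,
        queries=queries,
        relevant_docs={q: tuple(ds) for q, ds in relevant_docs.items()},
    )


# --------------------------------------------------------------------------
# Case generation (variant prioritization fixtures)
# --------------------------------------------------------------------------

_CASE_GENE_POOL = (
    "BRAF", "NRAS", "BRCA1", "BRCA2", "KRAS", "EGFR", "TP53", "PIK3CA",
    "PTEN", "ALK", "KIT", "MET", "RET", "ERBB2", "NOTCH1", "FBXW7",
)
_AA = sorted(AA_1TO3)


def _random_variant(rng: random.Random) -> ProteinVariant:
    while True:
        ref, alt = rng.sample(_AA, 2)
        pos = rng.randint(10, 900)
        return ProteinVariant(ref, pos, alt)


def generate_case(
    spec: FixtureSpec,
    n_actionable: int = 2,
    n_silent: int = 10,
    case_id: str = "case1",
    diagnosis: str = "melanoma",
) -> tuple[CaseFile, Fixture]:
    """A patient case plus its companion corpus.

    Actionable variants are planted with ``spec.n_relevant`` (≥ 5) relevant
    documents each; silent variants get none (the corpus only ever mentions
    their genes in distractor frames), so the prioritizer's gold ranking is
    actionable-above-silent by construction.
    """
    if n_actionable < 1:
        raise FixtureSpecError("a case needs at least one actionable variant")
    rng = random.Random(spec.seed)
    genes = list(_CASE_GENE_POOL)
    rng.shuffle(genes)
    if n_actionable + n_silent > len(genes):
        raise FixtureSpecError("gene pool too small for the requested case size")
    actionable = [(genes[i], _random_variant(rng)) for i in range(n_actionable)]
    silent = [
        (genes[n_actionable + i], _random_variant(rng)) for i in range(n_silent)
    ]
    corpus_spec = replace(
        spec,
        seed=rng.randrange(2 ** 31),
        n_relevant=max(spec.n_relevant, 5),
        triplets=tuple((g, v, diagnosis) for g, v in actionable),
    )
    fixture = generate_corpus(corpus_spec)
    case = CaseFile(
        case_id=case_id,
        diagnosis=diagnosis,
        variants=tuple(actionable + silent),
        age=rng.choice((None, 34, 61, 70)),
        gender=rng.choice((None, "female", "male")),
    )
    return case, fixture


def generate_case_suite(
    spec: FixtureSpec,
    composition: Sequence[int] = (1, 1, 1, 1, 1, 2, 2, 2),
    n_silent: int = 10,
    diagnosis: str = "melanoma",
) -> list[tuple[CaseFile, Fixture]]:
    """A suite of cases, one corpus each; ``composition`` gives the number of
    actionable (gold) variants per case.  The default composition — five
    single-relevant and three double-relevant cases, eleven gold variants in
    total — mirrors a small tumor-board study."""
    rng = random.Random(spec.seed)
    suite = []
    for i, n_act in enumerate(composition, 1):
        case_spec = replace(spec, seed=rng.randrange(2 ** 31))
        suite.append(generate_case(
            case_spec, n_actionable=n_act, n_silent=n_silent,
            case_id=f"case{i}", diagnosis=diagnosis,
        ))
    return suite


# --------------------------------------------------------------------------
# Fixture persistence
# --------------------------------------------------------------------------

def write_fixture(fixture: Fixture, out_dir: str, case: Optional[CaseFile] = None) -> None:
    """Write corpus.jsonl, lexicons.tsv, qrels.txt, cds.fasta (and case.tsv)."""
    os.makedirs(out_dir, exist_ok=True)
    write_jsonl(fixture.documents, os.path.join(out_dir, "corpus.jsonl"))
    write_lexicons_tsv(fixture.lexicons, os.path.join(out_dir, "lexicons.tsv"))
    with open(os.path.join(out_dir, "qrels.txt"), "w", encoding="utf-8") as fh:
        for (qid, did), grade in sorted(fixture.qrels.items()):
            fh.write(f"{qid} 0 {did} {grade}\n")
    with open(os.path.join(out_dir, "cds.fasta"), "w", encoding="utf-8") as fh:
        for gene, cds in sorted(fixture.cds_by_gene.items()):
            fh.write(f">{gene}\n")
            for i in range(0, len(cds), 60):
                fh.write(cds[i:i + 60] + "\n")
    if case is not None:
        with open(os.path.join(out_dir, "case.tsv"), "w", encoding="utf-8") as fh:
            fh.write(f"case_id\t{case.case_id}\n")
            fh.write(f"diagnosis\t{case.diagnosis}\n")
            if case.age is not None:
                fh.write(f"age\t{case.age}\n")
            if case.gender is not None:
                fh.write(f"gender\t{case.gender}\n")
            fh.write("gene\tvariant\n")
            for gene, pv in case.variants:
                fh.write(f"{gene}\t{pv}\n")
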