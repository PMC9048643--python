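"""Variant prioritization: rank a patient case's variants by literature volume.

The working assumption is that a clinically actionable variant accumulates
publications while a silent or uninterpretable one does not, so a useful
prioritization signal is the summed relevance score of the documents
retrieved for each (gene, variant, diagnosis) query.  Each variant of a case
is searched with the triage ranker (carrying the case's diagnosis and
demographics) and scored by the sum of its retrieved documents' scores over
the top retrieval depth; variants are then ranked by that aggregate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .corpus import Index
from .nomenclature import ProteinVariant, VariantParseError, parse_variant
from .triage import EntityRef, ScoringConfig, TripletQuery, rank

__all__ = [
    "CaseFile",
    "CaseInputError",
    "VariantScore",
    "prioritize",
    "read_case",
    "read_case_tsv",
    "read_case_vcf",
]

logger = logging.getLogger(__name__)


class CaseInputError(ValueError):
    """A case file yields no usable variants."""


@dataclass(frozen=True)
class CaseFile:
    """One patient case: a diagnosis, optional demographics, and the SNVs."""

    case_id: str
    diagnosis: str
    variants: tuple[tuple[str, ProteinVariant], ...]
    age: Optional[int] = None
    gender: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.variants:
            raise CaseInputError(f"case {self.case_id!r} has no variants")
        if len(set(self.variants)) != len(self.variants):
            raise CaseInputError(f"case {self.case_id!r} has duplicate variants")


@dataclass(frozen=True)
class VariantScore:
    gene: str
    variant: ProteinVariant
    aggregate: float
    n_docs: int
    rank: int


# --------------------------------------------------------------------------
# Case input
# --------------------------------------------------------------------------

_META_KEYS = {"case_id", "diagnosis", "age", "gender"}


def read_case_tsv(path: str) -> CaseFile:
    """TSV case dialect: a ``key<TAB>value`` metadata block (case_id,
    diagnosis, optional age/gender) followed by ``gene<TAB>variant`` rows."""
    meta: dict[str, str] = {}
    variants: list[tuple[str, ProteinVariant]] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CaseInputError(f"{path}:{ln}: expected 2 tab-separated fields")
            key, value = parts[0].strip(), parts[1].strip()
            if key.lower() in _META_KEYS:
                meta[key.lower()] = value
                continue
            if key.lower() == "gene" and value.lower() == "variant":
                continue        # optional column header row
            try:
                variants.append((key, parse_variant(value)))
            except VariantParseError:
                skipped += 1
    if skipped:
        logger.info("read_case_tsv(%s): skipped %d non-SNV rows", path, skipped)
    if not variants:
        raise CaseInputError(f"{path}: no parseable variant rows")
    age = int(meta["age"]) if meta.get("age") else None
    return CaseFile(
        case_id=meta.get("case_id", path),
        diagnosis=meta.get("diagnosis", ""),
        variants=tuple(variants),
        age=age,
        gender=meta.get("gender") or None,
    )


_HGVS_P_RE = re.compile(r"p\.\(?[A-Za-z]{3}\d+[A-Za-z]{3}\)?|p\.[A-Z]\d+[A-Z]")


def read_case_vcf(
    path: str,
    case_id: Optional[str] = None,
    diagnosis: str = "",
    age: Optional[int] = None,
    gender: Optional[str] = None,
) -> CaseFile:
    """Read a single-sample VCF whose records carry a protein change in an
    ANN/CSQ-style annotation INFO field.

    Only records with a parseable protein-level single-residue substitution
    are kept; everything else (indels, splice/fusion annotations, synonymous
    changes) is skipped with a logged count.  The gene symbol is taken from
    the annotation's gene subfield when present, else from a GENE INFO key.
    """
    import pysam

    variants: list[tuple[str, ProteinVariant]] = []
    skipped = 0
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            ann_raw = None
            for key in ("ANN", "CSQ"):
                if key in rec.info:
                    val = rec.info[key]
                    ann_raw = val if isinstance(val, str) else "|".join(val)
                    break
            gene = None
            hgvs_p = None
            if ann_raw:
                first = ann_raw.split(",")[0]
                subfields = first.split("|")
                if len(subfields) > 3 and subfields[3]:
                    gene = subfields[3]
                m = _HGVS_P_RE.search(first)
                if m:
                    hgvs_p = m.group()
            if gene is None and "GENE" in rec.info:
                val = rec.info["GENE"]
                gene = val if isinstance(val, str) else val[0]
            if not gene or not hgvs_p:
                skipped += 1
                continue
            try:
                pv = parse_variant(hgvs_p)
            except VariantParseError:
                skipped += 1
                continue
            entry = (gene, pv)
            if entry not in variants:
                variants.append(entry)
    if skipped:
        logger.info("read_case_vcf(%s): skipped %d non-SNV records", path, skipped)
    if not variants:
        raise CaseInputError(f"{path}: no usable protein-level SNV records")
    return CaseFile(
        case_id=case_id or path,
        diagnosis=diagnosis,
        variants=tuple(variants),
        age=age,
        gender=gender,
    )


def read_case(path: str, **kwargs) -> CaseFile:
    """Dispatch on extension: ``.vcf`` → VCF reader, anything else → TSV."""
    if path.lower().endswith((".vcf", ".vcf.gz")):
        return read_case_vcf(path, **kwargs)
    if kwargs:
        raise TypeError("metadata keyword arguments apply only to VCF input")
    return read_case_tsv(path)


# --------------------------------------------------------------------------
# Prioritization
# --------------------------------------------------------------------------

def prioritize(
    case: CaseFile,
    index: Index,
    cfg: Optional[ScoringConfig] = None,
    cds_by_gene: Optional[dict[str, str]] = None,
    gene_concepts: Optional[dict[str, str]] = None,
    disease_concept: Optional[str] = None,
    synonym_mode: str = "all",
) -> list[VariantScore]:
    """Rank the case's variants by aggregated document scores.

    For each variant a triplet query (gene, variant, case diagnosis, case
    demographics) is ranked; the variant's aggregate is the sum of the final
    fused scores (or raw normalized BM25 when ``cfg.aggregate == "rsv"``)
    over the top ``cfg.top_docs_per_variant`` documents.  Ties break by
    number of documents, then gene/variant lexicographically.
    """
    cfg = cfg or ScoringConfig()
    cds_by_gene = cds_by_gene or {}
    gene_concepts = gene_concepts or {}
    rows: list[tuple[float, int, str, str, ProteinVariant]] = []
    for gene, pv in case.variants:
        q = TripletQuery(
            gene=EntityRef(gene, gene_concepts.get(gene)),
            variant=pv,
            disease=EntityRef(case.diagnosis, disease_concept) if case.diagnosis else None,
            age=case.age,
            gender=case.gender,
            synonym_mode=synonym_mode,
        )
        hits = rank(q, index, cfg, cds=cds_by_gene.get(gene),
                    limit=cfg.top_docs_per_variant)
        if cfg.aggregate == "rsv":
            agg = sum(h.rsv_norm for h in hits)
        else:
            agg = sum(h.final for h in hits)
        rows.append((agg, len(hits), gene, str(pv), pv))
    rows.sort(key=lambda r: (-r[0], -r[1], r[2], r[3]))
    return [
        VariantScore(gene=g, variant=pv, aggregate=agg, n_docs=n, rank=i + 1)
        for i, (agg, n, g, _, pv) in enumerate(rows)
    ]
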