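"""Triplet-query construction, constraint relaxation, and re-ranking.

A query is a triplet — a variant in a gene for a diagnosis — optionally with
patient demographics.  Retrieval runs in two steps:

1. *recall*: a boolean query with one must-clause per entity is issued, each
   entity expanded into a should-clause pairing its surface text with its
   lexicon concept id (and, for the variant, one sub-clause per nomenclature
   synonym).  Because the full triplet is often too strict, three relaxed
   queries are also issued, each omitting one entity, and their results are
   fused into the candidate set.

2. *precision*: every candidate is re-scored with a linear combination of
   five components —

   ========================  ======  =======================================
   component                 weight  meaning
   ========================  ======  =======================================
   BM25 retrieval status     1.0     min–max-normalized full-query BM25
   constraint relaxation     0.65    weighted sum of normalized relaxed-query
                                     scores (disease+gene 0.95,
                                     disease+variant 0.07, gene+variant 0.05)
   named-entity density      0.1     saturating counts of disease (0.97),
                                     gene (0.51) and drug (0.57) annotations
   demographic concordance   0.05    age (0.7) / gender (0.5) agreement with
                                     the record's subject tags (bonus 0.7
                                     match, 0.4 unmentioned, 0.0 mismatch)
   predefined keywords       0.1     +0.2 per positive-stem token (treat,
                                     drug, therap, prognos, surviv), −0.1 per
                                     negative-stem token (immuno, marker,
                                     detect), clipped to [−1, 1]
   ========================  ======  =======================================

   Non-English records are downgraded to rank after all English records
   regardless of score.  Ties break by publication date (newest first) then
   doc_id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from datetime import date
from typing import Optional, Sequence

from .corpus import (
    Concept,
    Document,
    Index,
    Must,
    Should,
    evaluate_clauses,
    leaf_for_text,
    tokenize,
)
from .nomenclature import ProteinVariant, protein_synonyms

__all__ = [
    "EntityRef",
    "QueryError",
    "RankedHit",
    "ScoringConfig",
    "TripletQuery",
    "build_queries",
    "demographic_score",
    "keyword_score",
    "ne_density_score",
    "rank",
    "relax_score",
]


class QueryError(ValueError):
    """The triplet query cannot be turned into a retrieval plan."""


# --------------------------------------------------------------------------
# Configuration: every tuned weight, bonus, penalty and keyword list
# --------------------------------------------------------------------------

@dataclass
class ScoringConfig:
    """Tuned scoring parameters; defaults are the grid-searched optimum."""

    # constraint-relaxation weights per remaining entity pair
    relax_dg: float = 0.95      # disease + gene
    relax_dv: float = 0.07      # disease + variant
    relax_gv: float = 0.05      # gene + variant
    # named-entity density weights per entity type
    ne_disease: float = 0.97
    ne_gene: float = 0.51
    ne_drug: float = 0.57
    # demographic concordance
    demo_age_weight: float = 0.7
    demo_gender_weight: float = 0.5
    demo_match: float = 0.7
    demo_unmentioned: float = 0.4
    demo_mismatch: float = 0.0
    # keyword component
    kw_bonus: float = 0.2
    kw_penalty: float = -0.1
    positive_stems: tuple[str, ...] = ("treat", "drug", "therap", "prognos", "surviv")
    negative_stems: tuple[str, ...] = ("immuno", "marker", "detect")
    # final linear combination
    w_rsv: float = 1.0
    w_relax: float = 0.65
    w_ne: float = 0.1
    w_demo: float = 0.05
    w_kw: float = 0.1
    # variant-prioritization settings
    aggregate: str = "fused"            # "fused" | "rsv"
    top_docs_per_variant: int = 100

    def __post_init__(self) -> None:
        self.positive_stems = tuple(self.positive_stems)
        self.negative_stems = tuple(self.negative_stems)
        unit = [
            self.relax_dg, self.relax_dv, self.relax_gv,
            self.ne_disease, self.ne_gene, self.ne_drug,
            self.demo_age_weight, self.demo_gender_weight,
            self.demo_match, self.demo_unmentioned, self.demo_mismatch,
            self.kw_bonus,
            self.w_rsv, self.w_relax, self.w_ne, self.w_demo, self.w_kw,
        ]
        if any(not (0.0 <= w <= 1.0) for w in unit):
            raise ValueError("scoring weights must lie in [0, 1]")
        if not (-1.0 <= self.kw_penalty <= 0.0):
            raise ValueError("keyword penalty must lie in [-1, 0]")
        if self.aggregate not in ("fused", "rsv"):
            raise ValueError("aggregate must be 'fused' or 'rsv'")

    @classmethod
    def from_file(cls, path: str) -> "ScoringConfig":
        """Flat ``key=value`` config; unset keys keep the tuned defaults.
        Tuple fields take comma-separated values."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        with open(path, encoding="utf-8") as fh:
            for ln, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
                if key in ("positive_stems", "negative_stems"):
                    kwargs[key] = tuple(s.strip() for s in value.split(",") if s.strip())
                elif key == "aggregate":
                    kwargs[key] = value
                elif key == "top_docs_per_variant":
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = float(value)
        return cls(**kwargs)


# --------------------------------------------------------------------------
# Query model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EntityRef:
    """An entity as surface text plus (optionally) its lexicon concept id."""
    text: str
    concept_id: Optional[str] = None


@dataclass(frozen=True)
class TripletQuery:
    gene: Optional[EntityRef] = None
    variant: Optional[ProteinVariant] = None
    variant_text: Optional[str] = None
    disease: Optional[EntityRef] = None
    age: Optional[int] = None
    gender: Optional[str] = None
    synonym_mode: str = "all"

    def __post_init__(self) -> None:
        if self.gene is None and self.variant is None and self.disease is None:
            raise QueryError("query needs at least one of gene / variant / disease")
        if self.age is not None and self.age < 0:
            raise QueryError("age must be non-negative")
        if self.gender is not None and self.gender not in ("female", "male"):
            raise QueryError(f"unknown gender token: {self.gender!r}")
        if self.synonym_mode not in ("none", "basic", "all"):
            raise QueryError(f"unknown synonym mode: {self.synonym_mode!r}")


def _entity_should(ref: EntityRef) -> Should:
    children: list = [leaf_for_text(ref.text)]
    if ref.concept_id:
        children.append(Concept(ref.concept_id))
    return Should(tuple(children))


def _variant_should(q: TripletQuery, cds: Optional[str]) -> Should:
    assert q.variant is not None
    syns = protein_synonyms(q.variant, q.synonym_mode, cds=cds, surface=q.variant_text)
    return Should(tuple(leaf_for_text(f) for f in syns))


def build_queries(
    q: TripletQuery, cds: Optional[str] = None
) -> tuple[Must, dict[str, Must]]:
    """The full must-tree plus the relaxed trees, keyed by remaining pair.

    A full triplet yields relaxed trees ``dg`` (disease+gene), ``dv``
    (disease+variant) and ``gv`` (gene+variant).  With only two entities
    present no relaxation is performed and the relaxed set is empty.
    """
    clauses: dict[str, Should] = {}
    if q.disease is not None:
        clauses["d"] = _entity_should(q.disease)
    if q.gene is not None:
        clauses["g"] = _entity_should(q.gene)
    if q.variant is not None:
        clauses["v"] = _variant_should(q, cds)
    if len(clauses) < 2:
        raise QueryError(
            "constraint relaxation undefined: at least two triplet entities required"
        )
    full = Must(tuple(clauses[k] for k in ("d", "g", "v") if k in clauses))
    relaxed: dict[str, Must] = {}
    if len(clauses) == 3:
        relaxed = {
            "dg": Must((clauses["d"], clauses["g"])),
            "dv": Must((clauses["d"], clauses["v"])),
            "gv": Must((clauses["g"], clauses["v"])),
        }
    return full, relaxed


# --------------------------------------------------------------------------
# Component scores
# --------------------------------------------------------------------------

def _minmax(results: Sequence[tuple[str, float]]) -> dict[str, float]:
    """Min–max-normalize a result list's scores to [0, 1] (all-equal → 1)."""
    if not results:
        return {}
    scores = [s for _, s in results]
    lo, hi = min(scores), max(scores)
    if hi == lo:
        return {d: 1.0 for d, _ in results}
    return {d: (s - lo) / (hi - lo) for d, s in results}


def relax_score(
    doc_id: str,
    relaxed_results: dict[str, Sequence[tuple[str, float]]],
    cfg: ScoringConfig,
) -> float:
    """Weighted sum of the document's normalized scores over the relaxed
    queries, clipped to 1."""
    weights = {"dg": cfg.relax_dg, "dv": cfg.relax_dv, "gv": cfg.relax_gv}
    total = 0.0
    for label, results in relaxed_results.items():
        w = weights.get(label)
        if w is None:
            raise QueryError(f"unknown relaxed-query label: {label!r}")
        total += w * _minmax(results).get(doc_id, 0.0)
    return min(total, 1.0)


def ne_density_score(doc: Document, cfg: ScoringConfig) -> float:
    """Saturating, weight-normalized density of disease/gene/drug annotations:
    ``Σ_t w_t · c_t/(c_t+1) / Σ_t w_t``."""
    counts = {"disease": 0, "gene": 0, "drug": 0}
    for ann in doc.annotations:
        if ann.entity_type in counts:
            counts[ann.entity_type] += 1
    weights = {"disease": cfg.ne_disease, "gene": cfg.ne_gene, "drug": cfg.ne_drug}
    wsum = sum(weights.values())
    if wsum == 0:
        return 0.0
    return sum(w * counts[t] / (counts[t] + 1) for t, w in weights.items()) / wsum


#: query age (years) → MeSH-style age-group check tag
AGE_BINS: tuple[tuple[int, int, str], ...] = (
    (0, 1, "infant"),
    (2, 5, "child, preschool"),
    (6, 12, "child"),
    (13, 18, "adolescent"),
    (19, 44, "adult"),
    (45, 64, "middle aged"),
    (65, 10 ** 9, "aged"),
)
AGE_TAGS = frozenset(tag for _, _, tag in AGE_BINS)
GENDER_TAGS = frozenset(("female", "male"))


def age_group(age: int) -> str:
    for lo, hi, tag in AGE_BINS:
        if lo <= age <= hi:
            return tag
    raise ValueError(f"age out of range: {age}")


def _normalize_tag(tag: str) -> str:
    return re.sub(r"[\s\-]+", " ", tag.strip().lower())


def demographic_score(q: TripletQuery, doc: Document, cfg: ScoringConfig) -> float:
    """Concordance of the record's demographic subject tags with the query.

    Per attribute the bonus is 0.7 on a match, 0.4 when the record carries no
    tag for that attribute, 0.0 on a contradiction; the attribute bonuses are
    combined with weights 0.7 (age) and 0.5 (gender), normalized over the
    attributes actually present in the query.  No query demographics → 0.
    """
    tags = {_normalize_tag(t) for t in doc.subject_tags}
    parts: list[tuple[float, float]] = []      # (weight, bonus)
    if q.age is not None:
        doc_ages = tags & AGE_TAGS
        if not doc_ages:
            b = cfg.demo_unmentioned
        elif age_group(q.age) in doc_ages:
            b = cfg.demo_match
        else:
            b = cfg.demo_mismatch
        parts.append((cfg.demo_age_weight, b))
    if q.gender is not None:
        doc_genders = tags & GENDER_TAGS
        if not doc_genders:
            b = cfg.demo_unmentioned
        elif q.gender in doc_genders:
            b = cfg.demo_match
        else:
            b = cfg.demo_mismatch
        parts.append((cfg.demo_gender_weight, b))
    if not parts:
        return 0.0
    wsum = sum(w for w, _ in parts)
    return sum(w * b for w, b in parts) / wsum


def keyword_score(doc: Document, cfg: ScoringConfig) -> float:
    """Per-occurrence keyword bonus/penalty, clipped to [−1, 1].

    A token counts once per list: +0.2 if it starts with any positive stem,
    −0.1 if it starts with any negative stem (the stems are truncation
    prefixes, so prefix matching on the lowercased token is equivalent to
    matching on a stemmed token)."""
    pos = neg = 0
    for tok, _, _ in tokenize(doc.text):
        if any(tok.startswith(s) for s in cfg.positive_stems):
            pos += 1
        if any(tok.startswith(s) for s in cfg.negative_stems):
            neg += 1
    return max(-1.0, min(1.0, cfg.kw_bonus * pos + cfg.kw_penalty * neg))


# --------------------------------------------------------------------------
# Ranking
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedHit:
    doc_id: str
    rsv_norm: float
    relax: float
    ne_density: float
    demo: float
    kw: float
    final: float
    language_tier: str          # "english" | "other"


def _date_ordinal(iso: str) -> int:
    if not iso:
        return 0
    try:
        return date.fromisoformat(iso).toordinal()
    except ValueError:
        return 0


def rank(
    q: TripletQuery,
    index: Index,
    cfg: Optional[ScoringConfig] = None,
    cds: Optional[str] = None,
    limit: Optional[int] = None,
) -> list[RankedHit]:
    """Retrieve and re-rank documents for a triplet query.

    The candidate set is the union of the full-query and relaxed-query
    results; each candidate's final score is the configured linear
    combination of the five components.  English documents always precede
    non-English ones; within a tier the order is final score descending,
    publication date descending, doc_id ascending.
    """
    cfg = cfg or ScoringConfig()
    full, relaxed = build_queries(q, cds)
    full_res = evaluate_clauses(full, index)
    relaxed_res = {label: evaluate_clauses(t, index) for label, t in relaxed.items()}

    candidates: set[str] = {d for d, _ in full_res}
    for results in relaxed_res.values():
        candidates.update(d for d, _ in results)
    if not candidates:
        return []

    rsv_norm = _minmax(full_res)
    hits: list[RankedHit] = []
    for did in candidates:
        doc = index.docs[did]
        r = rsv_norm.get(did, 0.0)
        x = relax_score(did, relaxed_res, cfg)
        n = ne_density_score(doc, cfg)
        dm = demographic_score(q, doc, cfg)
        kw = keyword_score(doc, cfg)
        final = (cfg.w_rsv * r + cfg.w_relax * x + cfg.w_ne * n
                 + cfg.w_demo * dm + cfg.w_kw * kw)
        tier = "english" if doc.language == "en" else "other"
        hits.append(RankedHit(did, r, x, n, dm, kw, final, tier))

    hits.sort(key=lambda h: (
        0 if h.language_tier == "english" else 1,
        -h.final,
        -_date_ordinal(index.docs[h.doc_id].pub_date),
        h.doc_id,
    ))
    return hits[:limit] if limit is not None else hits
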