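"""Document model, lexicon annotation, and a BM25 inverted index.

The retrieval layer works over two fields per document:

``text``
    the normalized tokens of title + body, with positions (so multi-token
    variant forms such as the spaced ``1799 T > A`` can be matched as
    phrases);
``annotations``
    concept identifiers attached by dictionary-based named-entity annotation
    (gene / disease / drug / variant lexicons).  Searching a concept id
    retrieves every document in which *any* synonym of the concept was
    matched, which is what lifts recall over exact keyword search.

Queries are boolean trees of ``must`` / ``should`` nodes over term, phrase
and concept leaves; matching documents are scored with Okapi BM25
(k1 = 1.2, b = 0.75, idf = ln(1 + (N − df + 0.5)/(df + 0.5))) summed over the
satisfied leaves, and the result list is capped at the top 1000.

Token normalization is deliberately aggressive about intra-word punctuation:
hyphens joining alphanumerics are dropped (``B-RAF`` ≡ ``BRAF``) and periods
are dropped between alphanumerics *except* after a single-letter HGVS level
prefix (``p.Val600Glu`` → ``p.val600glu``), so variant descriptors survive as
single tokens.  Character spans in annotations are 0-based half-open over the
document's combined ``title + "\\n" + body`` text.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence, Union

from lxml import etree

__all__ = [
    "Annotation",
    "ClauseError",
    "Concept",
    "Document",
    "DuplicateDocumentError",
    "Index",
    "Lexicon",
    "Must",
    "Should",
    "Term",
    "Phrase",
    "annotate",
    "evaluate_clauses",
    "index_collection",
    "leaf_for_text",
    "normalize_token",
    "read_jsonl",
    "read_lexicons_tsv",
    "read_medline_xml",
    "tokenize",
    "write_jsonl",
    "write_lexicons_tsv",
]

BM25_K1 = 1.2
BM25_B = 0.75
MAX_RESULTS = 1000

ENTITY_TYPES = ("gene", "disease", "drug", "variant")


class DuplicateDocumentError(ValueError):
    """Two documents in one collection share a doc_id."""


class ClauseError(ValueError):
    """A boolean clause tree is structurally invalid."""


# --------------------------------------------------------------------------
# Documents and annotations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Annotation:
    concept_id: str
    entity_type: str
    start: int
    end: int
    matched_text: str


@dataclass
class Document:
    """One literature record: abstract-level text plus controlled metadata."""

    doc_id: str
    title: str = ""
    body: str = ""
    language: str = "en"
    subject_tags: tuple[str, ...] = ()
    pub_date: str = ""          # ISO date string, "" when unknown
    annotations: tuple[Annotation, ...] = ()

    def __post_init__(self) -> None:
        self.subject_tags = tuple(self.subject_tags)
        self.annotations = tuple(self.annotations)
        if not self.language:
            self.language = "en"

    @property
    def text(self) -> str:
        return f"{self.title}\n{self.body}" if self.title else self.body


@dataclass(frozen=True)
class Lexicon:
    """concept_id → synonyms for one entity type."""

    entity_type: str
    entries: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type: {self.entity_type!r}")
        object.__setattr__(
            self, "entries", {cid: tuple(syns) for cid, syns in self.entries.items()}
        )
        for cid, syns in self.entries.items():
            if not syns:
                raise ValueError(f"concept {cid!r} has no synonyms")


# --------------------------------------------------------------------------
# Tokenization / normalization
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9.\-]*")
_INTERNAL_DOT = re.compile(r"(?<=[a-z0-9])\.(?=[a-z0-9])")
_INTERNAL_HYPHEN = re.compile(r"(?<=[a-z0-9])-(?=[a-z0-9])")


def normalize_token(t: str) -> str:
    """Canonicalize one token: lower-case, collapse whitespace, drop joining
    hyphens and non-prefix periods (see module docstring)."""
    t = re.sub(r"\s+", " ", t.strip()).lower()
    t = _INTERNAL_HYPHEN.sub("", t)
    if len(t) >= 2 and t[1] == "." and t[0].isalpha():
        t = t[:2] + _INTERNAL_DOT.sub("", t[2:])
    else:
        t = _INTERNAL_DOT.sub("", t)
    return t.strip(".-")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Normalized tokens with their (start, end) character spans."""
    out = []
    for m in _TOKEN_RE.finditer(text):
        norm = normalize_token(m.group())
        if norm:
            out.append((norm, m.start(), m.end()))
    return out


def _token_strings(text: str) -> list[str]:
    return [t for t, _, _ in tokenize(text)]


# --------------------------------------------------------------------------
# Dictionary annotation
# --------------------------------------------------------------------------

def annotate(doc: Document, lexicons: Sequence[Lexicon]) -> list[Annotation]:
    """Greedy longest-match dictionary annotation over normalized tokens.

    Overlapping candidates resolve to the longest match; ties go to the
    earliest start (inherent in the left-to-right scan).  The first lexicon
    to claim a synonym keeps it.
    """
    if not lexicons:
        raise ValueError("at least one lexicon is required")
    patterns: dict[tuple[str, ...], tuple[str, str]] = {}
    max_len = 0
    for lex in lexicons:
        for cid, syns in lex.entries.items():
            for syn in syns:
                key = tuple(_token_strings(syn))
                if key and key not in patterns:
                    patterns[key] = (cid, lex.entity_type)
                    max_len = max(max_len, len(key))
    text = doc.text
    toks = tokenize(text)
    out: list[Annotation] = []
    i = 0
    while i < len(toks):
        matched = False
        for L in range(min(max_len, len(toks) - i), 0, -1):
            key = tuple(t for t, _, _ in toks[i:i + L])
            hit = patterns.get(key)
            if hit is not None:
                cid, etype = hit
                start, end = toks[i][1], toks[i + L - 1][2]
                out.append(Annotation(cid, etype, start, end, text[start:end]))
                i += L
                matched = True
                break
        if not matched:
            i += 1
    return out


def annotate_collection(docs: Iterable[Document], lexicons: Sequence[Lexicon]) -> list[Document]:
    return [replace(d, annotations=tuple(annotate(d, lexicons))) for d in docs]


# --------------------------------------------------------------------------
# Inverted index + BM25
# --------------------------------------------------------------------------

class Index:
    """Positional inverted index over the ``text`` field plus a concept
    index over the ``annotations`` field, with BM25 scoring."""

    def __init__(self, docs: Sequence[Document]):
        self.docs: dict[str, Document] = {}
        self.text_postings: dict[str, dict[str, list[int]]] = {}
        self.concept_postings: dict[str, dict[str, int]] = {}
        self.text_len: dict[str, int] = {}
        self.ann_len: dict[str, int] = {}
        for doc in docs:
            if doc.doc_id in self.docs:
                raise DuplicateDocumentError(f"duplicate doc_id: {doc.doc_id!r}")
            self.docs[doc.doc_id] = doc
            toks = _token_strings(doc.text)
            self.text_len[doc.doc_id] = len(toks)
            for pos, tok in enumerate(toks):
                self.text_postings.setdefault(tok, {}).setdefault(doc.doc_id, []).append(pos)
            self.ann_len[doc.doc_id] = len(doc.annotations)
            for ann in doc.annotations:
                bucket = self.concept_postings.setdefault(ann.concept_id, {})
                bucket[doc.doc_id] = bucket.get(doc.doc_id, 0) + 1
        self.n_docs = len(self.docs)
        self.avg_text_len = (
            sum(self.text_len.values()) / self.n_docs if self.n_docs else 0.0
        )
        self.avg_ann_len = (
            sum(self.ann_len.values()) / self.n_docs if self.n_docs else 0.0
        )
        self._phrase_cache: dict[tuple[str, ...], dict[str, int]] = {}

    # -- statistics -------------------------------------------------------

    def df(self, term: str, fld: str = "text") -> int:
        if fld == "text":
            return len(self.text_postings.get(normalize_token(term), {}))
        if fld == "annotations":
            return len(self.concept_postings.get(term, {}))
        raise ValueError(f"unknown field: {fld!r}")

    def idf(self, df: int) -> float:
        return math.log(1.0 + (self.n_docs - df + 0.5) / (df + 0.5))

    # -- phrase support ---------------------------------------------------

    def phrase_occurrences(self, tokens: tuple[str, ...]) -> dict[str, int]:
        """doc_id → number of occurrences of the consecutive token sequence."""
        if tokens in self._phrase_cache:
            return self._phrase_cache[tokens]
        first = self.text_postings.get(tokens[0], {})
        candidates = set(first)
        for tok in tokens[1:]:
            candidates &= set(self.text_postings.get(tok, {}))
            if not candidates:
                break
        occ: dict[str, int] = {}
        for did in candidates:
            positions = set(self.text_postings[tokens[0]][did])
            count = 0
            for p in positions:
                if all(
                    p + k in (self.text_postings[tokens[k]].get(did) or [])
                    for k in range(1, len(tokens))
                ):
                    count += 1
            if count:
                occ[did] = count
        self._phrase_cache[tokens] = occ
        return occ

    # -- BM25 -------------------------------------------------------------

    def _bm25(self, tf: int, df: int, dl: int, avgdl: float) -> float:
        if tf == 0 or df == 0:
            return 0.0
        denom_norm = BM25_K1 * (1.0 - BM25_B + BM25_B * dl / avgdl) if avgdl else BM25_K1
        return self.idf(df) * tf * (BM25_K1 + 1.0) / (tf + denom_norm)

    def score_term(self, term: str, doc_id: str) -> float:
        tok = normalize_token(term)
        tf = len(self.text_postings.get(tok, {}).get(doc_id, []))
        return self._bm25(tf, self.df(tok, "text"), self.text_len.get(doc_id, 0),
                          self.avg_text_len)

    def score_phrase(self, tokens: tuple[str, ...], doc_id: str) -> float:
        occ = self.phrase_occurrences(tokens)
        return self._bm25(occ.get(doc_id, 0), len(occ), self.text_len.get(doc_id, 0),
                          self.avg_text_len)

    def score_concept(self, concept_id: str, doc_id: str) -> float:
        tf = self.concept_postings.get(concept_id, {}).get(doc_id, 0)
        return self._bm25(tf, self.df(concept_id, "annotations"),
                          self.ann_len.get(doc_id, 0), self.avg_ann_len)

    def bm25_rsv(self, query_terms: Sequence[str], doc_id: str) -> float:
        """Okapi BM25 retrieval status value of one document for a bag of terms."""
        return sum(self.score_term(t, doc_id) for t in query_terms)


def index_collection(docs: Sequence[Document]) -> Index:
    """Build the two-field inverted index for a document collection."""
    return Index(docs)


# --------------------------------------------------------------------------
# Boolean clause trees
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """A single normalized token searched in the text field."""
    token: str


@dataclass(frozen=True)
class Phrase:
    """A consecutive normalized token sequence searched in the text field."""
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class Concept:
    """A concept identifier searched in the annotations field."""
    concept_id: str


@dataclass(frozen=True)
class Must:
    children: tuple = ()


@dataclass(frozen=True)
class Should:
    children: tuple = ()


ClauseNode = Union[Term, Phrase, Concept, Must, Should]


def leaf_for_text(surface: str) -> ClauseNode:
    """Build the right leaf for a surface form: a Term if it normalizes to a
    single token, a Phrase otherwise."""
    toks = _token_strings(surface)
    if not toks:
        raise ClauseError(f"surface form {surface!r} normalizes to nothing")
    if len(toks) == 1:
        return Term(toks[0])
    return Phrase(tuple(toks))


def _matching_docs(node: ClauseNode, index: Index) -> set[str]:
    if isinstance(node, Term):
        return set(index.text_postings.get(normalize_token(node.token), {}))
    if isinstance(node, Phrase):
        return set(index.phrase_occurrences(tuple(node.tokens)))
    if isinstance(node, Concept):
        return set(index.concept_postings.get(node.concept_id, {}))
    if isinstance(node, Must):
        if not node.children:
            raise ClauseError("must node with no children")
        sets = [_matching_docs(c, index) for c in node.children]
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out
    if isinstance(node, Should):
        if not node.children:
            raise ClauseError("should node with no children")
        out: set[str] = set()
        for c in node.children:
            out |= _matching_docs(c, index)
        return out
    raise ClauseError(f"unknown clause node: {node!r}")


def _collect_leaves(node: ClauseNode) -> list[ClauseNode]:
    if isinstance(node, (Term, Phrase, Concept)):
        return [node]
    if isinstance(node, (Must, Should)):
        out: list[ClauseNode] = []
        for c in node.children:
            out.extend(_collect_leaves(c))
        return out
    raise ClauseError(f"unknown clause node: {node!r}")


def evaluate_clauses(
    tree: ClauseNode, index: Index, limit: int = MAX_RESULTS
) -> list[tuple[str, float]]:
    """Documents satisfying the boolean tree, scored by the summed BM25
    contributions of the satisfied leaves, top ``limit`` by score (ties by
    doc_id ascending)."""
    matching = _matching_docs(tree, index)
    leaves = _collect_leaves(tree)
    scored: list[tuple[str, float]] = []
    for did in matching:
        rsv = 0.0
        for lf in leaves:
            if isinstance(lf, Term):
                rsv += index.score_term(lf.token, did)
            elif isinstance(lf, Phrase):
                rsv += index.score_phrase(tuple(lf.tokens), did)
            else:
                rsv += index.score_concept(lf.concept_id, did)
        scored.append((did, rsv))
    scored.sort(key=lambda x: (-x[1], x[0]))
    return scored[:limit]


# --------------------------------------------------------------------------
# I/O: JSONL corpus, MEDLINE-like XML, lexicon TSV
# --------------------------------------------------------------------------

def read_jsonl(path: str) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            docs.append(Document(
                doc_id=str(rec["doc_id"]),
                title=rec.get("title", ""),
                body=rec.get("body", ""),
                language=rec.get("language", "en"),
                subject_tags=tuple(rec.get("subject_tags", [])),
                pub_date=rec.get("pub_date", ""),
            ))
    return docs


def write_jsonl(docs: Iterable[Document], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps({
                "doc_id": d.doc_id,
                "title": d.title,
                "body": d.body,
                "language": d.language,
                "subject_tags": list(d.subject_tags),
                "pub_date": d.pub_date,
            }, ensure_ascii=False) + "\n")


def read_medline_xml(path: str) -> list[Document]:
    """Read a MEDLINE-like XML file: PMID, ArticleTitle, AbstractText,
    Language, and MeSH descriptor names as subject tags."""
    tree = etree.parse(path)
    docs = []
    for cit in tree.iter("MedlineCitation"):
        pmid = cit.findtext("PMID", default="").strip()
        title = cit.findtext(".//ArticleTitle", default="") or ""
        abstract = " ".join(
            (el.text or "") for el in cit.findall(".//Abstract/AbstractText")
        ).strip()
        language = (cit.findtext(".//Language", default="en") or "en").strip().lower()
        # MEDLINE uses ISO-639-2 ("eng"); fold to 2-letter for English
        if language == "eng":
            language = "en"
        tags = tuple(
            (el.text or "").strip()
            for el in cit.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
            if (el.text or "").strip()
        )
        year = cit.findtext(".//PubDate/Year", default="") or ""
        docs.append(Document(
            doc_id=pmid, title=title, body=abstract,
            language=language, subject_tags=tags,
            pub_date=f"{year}-01-01" if year else "",
        ))
    return docs


def read_lexicons_tsv(path: str) -> list[Lexicon]:
    """TSV with columns concept_id, entity_type, synonym (one synonym per row)."""
    grouped: dict[str, dict[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            cid, etype, syn = parts
            grouped.setdefault(etype, {}).setdefault(cid, []).append(syn)
    return [
        Lexicon(etype, {cid: tuple(syns) for cid, syns in entries.items()})
        for etype, entries in sorted(grouped.items())
    ]


def write_lexicons_tsv(lexicons: Iterable[Lexicon], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lex in lexicons:
            for cid, syns in lex.entries.items():
                for syn in syns:
                    fh.write(f"{cid}\t{lex.entity_type}\t{syn}\n")
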