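"""IR evaluation: ranked-retrieval metrics and two-system comparisons.

Metrics
-------
* ``precision_at_k`` — fraction of the top-k results that are relevant
  (grade ≥ 1); short rankings count as padded with non-relevant documents.
* ``r_precision`` — precision at rank R, R = number of relevant documents
  for the query; undefined (and excluded from macro averages) when R = 0.
* ``ndcg`` — discounted cumulative gain with gain = grade and discount
  1/log2(rank+1), normalized by the ideal ordering.
* ``top_k_recall`` — percentage of items (e.g. gold variants) whose rank is
  ≤ k, for rank lists that may contain not-retrieved entries.

System comparison
-----------------
``compare_runs`` contrasts two systems' per-query retrieved document sets
with five recall/silence measures: (1) mean documents per query, (2) mean
per-query share of the pooled content (the union of both systems' results),
(3) total documents, (4) queries where one system returns strictly more, and
(5) queries with no result ("silence"), each with the relative gain of A
over B.  Rounding follows reporting convention: means and percentage gains
to one decimal, the common-document share to an integer percent.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ComparisonStats",
    "EvalResult",
    "compare_runs",
    "evaluate_run",
    "ndcg",
    "per_query_breakdown",
    "precision_at_k",
    "r_precision",
    "read_qrels",
    "read_run",
    "read_docsets_json",
    "relative_gain",
    "top_k_recall",
    "write_run",
]

logger = logging.getLogger(__name__)

#: (query_id, doc_id) → graded relevance (grade ≥ 1 means relevant)
Qrels = Mapping[tuple[str, str], int]


def _relevant_docs(qrels: Qrels, qid: str) -> set[str]:
    return {d for (q, d), g in qrels.items() if q == qid and g >= 1}


def precision_at_k(ranked: Sequence[str], qrels: Qrels, qid: str, k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    rel = _relevant_docs(qrels, qid)
    return sum(1 for d in ranked[:k] if d in rel) / k


def r_precision(ranked: Sequence[str], qrels: Qrels, qid: str) -> float:
    rel = _relevant_docs(qrels, qid)
    r = len(rel)
    if r == 0:
        raise ValueError(f"R-Precision undefined for query {qid!r}: no relevant documents")
    return sum(1 for d in ranked[:r] if d in rel) / r


def ndcg(ranked: Sequence[str], qrels: Qrels, qid: str, depth: int = 1000) -> float:
    """Normalized discounted cumulative gain at ``depth`` (gain = grade)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    grades = {d: g for (q, d), g in qrels.items() if q == qid and g > 0}
    dcg = sum(
        grades.get(d, 0) / math.log2(i + 2)
        for i, d in enumerate(ranked[:depth])
    )
    ideal = sorted(grades.values(), reverse=True)[:depth]
    idcg = sum(g / math.log2(i + 2) for i, g in enumerate(ideal))
    return dcg / idcg if idcg > 0 else 0.0


def top_k_recall(variant_ranks: Sequence[Optional[int]], k: int) -> float:
    """Percentage of items with rank ≤ k (``None`` = not retrieved), one decimal."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not variant_ranks:
        raise ValueError("empty rank list")
    hits = sum(1 for r in variant_ranks if r is not None and r <= k)
    return round(100.0 * hits / len(variant_ranks), 1)


# --------------------------------------------------------------------------
# Run-level evaluation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalResult:
    """Per-query and macro-averaged P5 / P10 / R-Prec / NDCG."""

    per_query: dict[str, dict[str, float]]
    macro: dict[str, float]


def evaluate_run(
    run: Mapping[str, Sequence[str]],
    qrels: Qrels,
    ndcg_depth: int = 1000,
) -> EvalResult:
    """Evaluate a run (qid → ranked doc ids) against graded qrels.

    Queries with no relevant documents contribute no R-Precision value and
    are excluded from that macro average (with a logged note)."""
    per_query: dict[str, dict[str, float]] = {}
    skipped_rprec = []
    for qid in sorted(run):
        ranked = run[qid]
        row = {
            "P5": precision_at_k(ranked, qrels, qid, 5),
            "P10": precision_at_k(ranked, qrels, qid, 10),
            "NDCG": ndcg(ranked, qrels, qid, ndcg_depth),
        }
        try:
            row["R-Prec"] = r_precision(ranked, qrels, qid)
        except ValueError:
            skipped_rprec.append(qid)
        per_query[qid] = row
    if skipped_rprec:
        logger.info("R-Precision undefined (no relevant docs) for %d queries: %s",
                    len(skipped_rprec), ", ".join(skipped_rprec))
    macro: dict[str, float] = {}
    for metric in ("P5", "P10", "R-Prec", "NDCG"):
        vals = [row[metric] for row in per_query.values() if metric in row]
        macro[metric] = sum(vals) / len(vals) if vals else 0.0
    return EvalResult(per_query=per_query, macro=macro)


# --------------------------------------------------------------------------
# Two-system comparison
# --------------------------------------------------------------------------

def relative_gain(a: float, b: float) -> float:
    """Relative gain of a over b as a percentage, one decimal.

    A zero baseline yields 0.0 when a is also zero (no change) and +inf
    otherwise."""
    if b == 0:
        return 0.0 if a == 0 else math.inf
    return round(100.0 * (a - b) / b, 1)


def per_query_breakdown(
    a: Iterable[str], b: Iterable[str]
) -> tuple[int, int, int, int, int]:
    """(|A|, |B|, |A∪B|, |A\\B|, |B\\A|) for one query's result sets."""
    sa, sb = set(a), set(b)
    return len(sa), len(sb), len(sa | sb), len(sa - sb), len(sb - sa)


@dataclass(frozen=True)
class ComparisonStats:
    n_queries: int
    mean_docs: dict[str, float]          # keys: A, B, union (1 decimal)
    content_pct: dict[str, float]        # mean per-query share of the union
    totals: dict[str, int]
    more_queries: dict[str, int]         # queries where one side has strictly more
    equal_queries: int
    silence: dict[str, int]              # zero-result queries per side and union
    common_total: int
    common_share_pct: int                # integer percent of the union total
    gains: dict[str, float]              # relative gain of A over B per measure

    def rows(self) -> list[tuple[str, str, str, str, str]]:
        """The five comparison rows (measure, union, B, A, gain), printable."""
        return [
            ("Average number of documents retrieved per query",
             f"{self.mean_docs['union']}", f"{self.mean_docs['B']}",
             f"{self.mean_docs['A']}", f"{self.gains['mean_docs']:+}%"),
            ("Average percentage of the content retrieved per query",
             f"{self.content_pct['union']}%", f"{self.content_pct['B']}%",
             f"{self.content_pct['A']}%", f"{self.gains['content_pct']:+}%"),
            ("Total number of documents retrieved",
             f"{self.totals['union']}", f"{self.totals['B']}",
             f"{self.totals['A']}", f"{self.gains['totals']:+}%"),
            ("Number of queries with more results than the other system",
             "-", f"{self.more_queries['B']}", f"{self.more_queries['A']}",
             f"{self.gains['more_queries']:+}%"),
            ("Number of queries with no result",
             f"{self.silence['union']}", f"{self.silence['B']}",
             f"{self.silence['A']}", f"{self.gains['silence']:+}%"),
        ]

    def to_csv(self, path: str) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["measure", "union", "system_b", "system_a", "relative_gain"])
            w.writerows(self.rows())


def compare_runs(
    a: Mapping[str, Iterable[str]], b: Mapping[str, Iterable[str]]
) -> ComparisonStats:
    """Compare two systems' per-query retrieved document sets (see module
    docstring for the five measures)."""
    if set(a) != set(b):
        raise ValueError("the two runs must cover the same query set")
    qids = sorted(a)
    n = len(qids)
    if n == 0:
        raise ValueError("empty query set")

    total_a = total_b = total_u = common_total = 0
    content_a: list[float] = []
    content_b: list[float] = []
    more_a = more_b = equal = 0
    sil_a = sil_b = sil_u = 0
    for qid in qids:
        na, nb, nu, only_a, only_b = per_query_breakdown(a[qid], b[qid])
        total_a += na
        total_b += nb
        total_u += nu
        common_total += nu - only_a - only_b
        if nu > 0:
            content_a.append(100.0 * na / nu)
            content_b.append(100.0 * nb / nu)
        if na > nb:
            more_a += 1
        elif nb > na:
            more_b += 1
        else:
            equal += 1
        sil_a += na == 0
        sil_b += nb == 0
        sil_u += nu == 0

    mean_a, mean_b, mean_u = total_a / n, total_b / n, total_u / n
    cpa = sum(content_a) / len(content_a) if content_a else 0.0
    cpb = sum(content_b) / len(content_b) if content_b else 0.0
    # gains on the mean rows are computed from the rounded (displayed) means,
    # matching how such comparison tables are read
    gains = {
        "mean_docs": relative_gain(round(mean_a, 1), round(mean_b, 1)),
        "content_pct": relative_gain(round(cpa, 1), round(cpb, 1)),
        "totals": relative_gain(total_a, total_b),
        "more_queries": relative_gain(more_a, more_b),
        "silence": relative_gain(sil_a, sil_b),
    }
    return ComparisonStats(
        n_queries=n,
        mean_docs={"A": round(mean_a, 1), "B": round(mean_b, 1), "union": round(mean_u, 1)},
        content_pct={"A": round(cpa, 1), "B": round(cpb, 1), "union": 100.0},
        totals={"A": total_a, "B": total_b, "union": total_u},
        more_queries={"A": more_a, "B": more_b},
        equal_queries=equal,
        silence={"A": sil_a, "B": sil_b, "union": sil_u},
        common_total=common_total,
        common_share_pct=round(100.0 * common_total / total_u) if total_u else 0,
        gains=gains,
    )


# --------------------------------------------------------------------------
# TREC-format I/O
# --------------------------------------------------------------------------

def read_qrels(path: str) -> dict[tuple[str, str], int]:
    """TREC qrels: ``qid 0 docid grade`` per line."""
    out: dict[tuple[str, str], int] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 'qid 0 docid grade'")
            qid, _, docid, grade = parts
            out[(qid, docid)] = int(grade)
    return out


def read_run(path: str) -> dict[str, list[str]]:
    """TREC run: ``qid Q0 docid rank score tag``; docs ordered by rank."""
    rows: dict[str, list[tuple[int, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 'qid Q0 docid rank score tag'")
            qid, _, docid, rank_, _, _ = parts
            rows.setdefault(qid, []).append((int(rank_), docid))
    return {qid: [d for _, d in sorted(pairs)] for qid, pairs in rows.items()}


def write_run(
    run: Mapping[str, Sequence[tuple[str, float]]], path: str, tag: str = "varlit"
) -> None:
    """Write ``qid → [(docid, score), ...]`` in TREC run format."""
    with open(path, "w", encoding="utf-8") as fh:
        for qid in sorted(run):
            for i, (docid, score) in enumerate(run[qid], 1):
                fh.write(f"{qid} Q0 {docid} {i} {score:.6f} {tag}\n")


def read_docsets_json(path: str) -> dict[str, set[str]]:
    """JSON mapping qid → [doc ids], as used by ``compare_runs``."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return {qid: set(docs) for qid, docs in data.items()}
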