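"""Okapi BM25 retrieval over an in-memory inverted index, plus a Boolean
recency-ranked baseline and axis-specific query expansion.

The ranking model is plain Okapi BM25 with a non-negative idf floor:

    score(q, d) = sum over distinct query terms t of
                  idf(t) * tf * (k1 + 1) / (tf + k1 * (1 - b + b * dl/avgdl))
    idf(t)      = ln(1 + (N - df + 0.5) / (df + 0.5))

with k1 = 1.2 and b = 0.75 by default. The idf floor keeps engine scores
non-negative, which the downstream score-fusion weights rely on.

The Boolean baseline emulates the traditional bibliographic search mode:
documents matching the Boolean condition are ranked by publication date,
most recent first. It stands in for date-driven Boolean engines; a live
proprietary relevance sort is deliberately not reproduced.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

from .annotate import tokenize
from .corpus import DocumentSet

__all__ = [
    "Index",
    "QuerySpec",
    "ScoredDoc",
    "RankedList",
    "AXIS_REFINEMENT_KEYWORDS",
    "build_index",
    "bm25_score",
    "expand_query",
    "search",
    "boolean_search",
    "write_trec_run",
    "read_trec_run",
]

DEFAULT_K1 = 1.2
DEFAULT_B = 0.75

# axis-specific trigger keywords appended under query refinement
AXIS_REFINEMENT_KEYWORDS: dict[str, tuple[str, ...]] = {
    "PPI": ("binds", "interacts", "associates"),
    "PTM": ("phosphorylates",),
}


@dataclass(frozen=True)
class QuerySpec:
    """A triage query: a gene symbol, its synonyms, and the curation axis.

    With ``refinement`` on, axis-specific trigger keywords (or
    ``extra_keywords`` when given) are appended to the engine query; they
    act on the engine score only and are never counted as concept
    descriptors.
    """

    gene: str
    synonyms: tuple[str, ...] = ()
    axis: str = "PPI"
    refinement: bool = False
    extra_keywords: tuple[str, ...] = ()
    top_k: int = 1000

    def __post_init__(self) -> None:
        if not self.gene.strip():
            raise ValueError("gene must be non-empty")
        if self.axis not in AXIS_REFINEMENT_KEYWORDS:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class ScoredDoc:
    pmid: int
    engine_score: float
    rank: int
    fused_score: float | None = None


RankedList = list  # list[ScoredDoc]; ranks 1..n, scores non-increasing


@dataclass
class Index:
    """Inverted index over lowercased title+abstract tokens."""

    n_docs: int
    df: dict[str, int]
    postings: dict[str, dict[int, int]]  # term -> {pmid: tf}
    doc_len: dict[int, int]
    avgdl: float
    dates: dict[int, dt.date | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_docs": self.n_docs,
            "postings": {t: sorted(p.items()) for t, p in self.postings.items()},
            "doc_len": sorted(self.doc_len.items()),
            "dates": {
                str(pmid): (None if d is None else d.isoformat())
                for pmid, d in self.dates.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Index":
        postings = {t: {pmid: tf for pmid, tf in p} for t, p in payload["postings"].items()}
        doc_len = {pmid: n for pmid, n in payload["doc_len"]}
        avgdl = sum(doc_len.values()) / len(doc_len) if doc_len else 0.0
        return cls(
            n_docs=payload["n_docs"],
            df={t: len(p) for t, p in postings.items()},
            postings=postings,
            doc_len=doc_len,
            avgdl=avgdl,
            dates={
                int(pmid): (None if d is None else dt.date.fromisoformat(d))
                for pmid, d in payload["dates"].items()
            },
        )


def build_index(docs: DocumentSet) -> Index:
    """Index a corpus. Raises on an empty corpus (avgdl would be undefined)."""
    if len(docs) == 0:
        raise ValueError("cannot index an empty corpus")
    postings: dict[str, dict[int, int]] = {}
    doc_len: dict[int, int] = {}
    dates: dict[int, dt.date | None] = {}
    for doc in docs:
        tokens = [t.lower for t in tokenize(doc.text)]
        doc_len[doc.pmid] = len(tokens)
        dates[doc.pmid] = doc.pub_date
        for term in tokens:
            bucket = postings.setdefault(term, {})
            bucket[doc.pmid] = bucket.get(doc.pmid, 0) + 1
    avgdl = sum(doc_len.values()) / len(doc_len)
    return Index(
        n_docs=len(docs),
        df={t: len(p) for t, p in postings.items()},
        postings=postings,
        doc_len=doc_len,
        avgdl=avgdl,
        dates=dates,
    )


def _idf(index: Index, term: str) -> float:
    df = index.df.get(term, 0)
    return math.log(1.0 + (index.n_docs - df + 0.5) / (df + 0.5))


def bm25_score(
    index: Index,
    terms: list[str],
    pmid: int,
    k1: float = DEFAULT_K1,
    b: float = DEFAULT_B,
) -> float:
    """BM25 score of one document for a list of query terms.

    Additive over *distinct* terms (repeating a query term does not double
    its contribution); 0 when no query term occurs in the document.
    """
    if pmid not in index.doc_len:
        raise KeyError(f"pmid {pmid} not in index")
    dl = index.doc_len[pmid]
    norm = k1 * (1.0 - b + b * dl / index.avgdl)
    score = 0.0
    for term in dict.fromkeys(t.lower() for t in terms):
        tf = index.postings.get(term, {}).get(pmid, 0)
        if tf == 0:
            continue
        score += _idf(index, term) * tf * (k1 + 1.0) / (tf + norm)
    return score


def expand_query(q: QuerySpec) -> list[str]:
    """The engine term list: gene + synonyms, plus refinement keywords when
    refinement is on; duplicates removed preserving first occurrence."""
    terms = [q.gene, *q.synonyms]
    if q.refinement:
        terms.extend(q.extra_keywords or AXIS_REFINEMENT_KEYWORDS[q.axis])
    return list(dict.fromkeys(t.lower() for t in terms if t.strip()))


def _ranked(scored: list[tuple[int, float]], top_k: int) -> list[ScoredDoc]:
    scored.sort(key=lambda item: (-item[1], -item[0]))
    return [
        ScoredDoc(pmid=pmid, engine_score=score, rank=rank)
        for rank, (pmid, score) in enumerate(scored[:top_k], start=1)
    ]


def search(index: Index, q: QuerySpec, k1: float = DEFAULT_K1, b: float = DEFAULT_B) -> list[ScoredDoc]:
    """BM25 ranking: documents with positive score, best first, truncated to
    ``q.top_k``; ties broken by PMID descending."""
    terms = expand_query(q)
    candidates: set[int] = set()
    for term in terms:
        candidates.update(index.postings.get(term, ()))
    scored = [
        (pmid, s) for pmid in candidates
        if (s := bm25_score(index, terms, pmid, k1=k1, b=b)) > 0.0
    ]
    return _ranked(scored, q.top_k)


def boolean_search(index: Index, q: QuerySpec, mode: str = "OR") -> list[ScoredDoc]:
    """Boolean retrieval ranked by recency (most recent first).

    ``mode`` is AND (all terms present) or OR (any term present). Undated
    documents sort last. The reported ``engine_score`` is the toordinal of
    the publication date so that ranks and scores stay consistent.
    """
    if mode not in ("AND", "OR"):
        raise ValueError(f"mode must be AND or OR, got {mode!r}")
    terms = expand_query(q)
    if not terms:
        return []
    sets = [set(index.postings.get(t, ())) for t in terms]
    matched = set.intersection(*sets) if mode == "AND" else set.union(*sets)

    def recency(pmid: int) -> float:
        date = index.dates.get(pmid)
        return float(date.toordinal()) if date is not None else 0.0

    return _ranked([(pmid, recency(pmid)) for pmid in matched], q.top_k)


# ---------------------------------------------------------------------------
# TREC run serialization: `qid Q0 pmid rank score tag`
# ---------------------------------------------------------------------------

def write_trec_run(run: dict[str, list[ScoredDoc]], stream, tag: str = "litriage") -> None:
    for qid in sorted(run):
        for doc in run[qid]:
            score = doc.fused_score if doc.fused_score is not None else doc.engine_score
            stream.write(f"{qid} Q0 {doc.pmid} {doc.rank} {score:.6f} {tag}\n")


def read_trec_run(stream) -> dict[str, list[ScoredDoc]]:
    run: dict[str, list[ScoredDoc]] = {}
    for lineno, line in enumerate(stream, start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6:
            raise ValueError(f"line {lineno}: expected 6 fields in TREC run format")
        qid, _, pmid, rank, score, _ = parts
        run.setdefault(qid, []).append(
            ScoredDoc(pmid=int(pmid), engine_score=float(score), rank=int(rank))
        )
    for docs in run.values():
        docs.sort(key=lambda d: d.rank)
    return run
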