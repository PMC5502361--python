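"""TREC-style evaluation: qrels IO and ranked-retrieval metrics.

Conventions follow TREC practice. Relevance judgements (*qrels*) are binary.
``P@1`` — here also reported under the historical name ``P0`` — is the mean
over queries of whether the top-ranked document is relevant; MRR is the mean
reciprocal rank of the first relevant document; MAP averages, per query, the
precision at each relevant retrieved document's rank divided by the total
number of relevant documents. Queries judged in the qrels but missing from a
run (or with an empty result list) contribute 0 to every mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .retrieval import ScoredDoc

logger = logging.getLogger(__name__)

__all__ = [
    "QrelSet",
    "MetricReport",
    "read_qrels",
    "write_qrels",
    "precision_at_1",
    "precision_at_k",
    "mean_reciprocal_rank",
    "mean_average_precision",
    "relative_improvement",
    "evaluate_run",
]

Run = dict[str, list[ScoredDoc]]


@dataclass(frozen=True)
class QrelSet:
    """Binary relevance judgements keyed by (query_id, pmid)."""

    judgements: dict[tuple[str, int], int]

    def __post_init__(self) -> None:
        if not self.judgements:
            raise ValueError("a QrelSet must contain at least one judgement")
        for (qid, pmid), rel in self.judgements.items():
            if rel not in (0, 1):
                raise ValueError(f"relevance for ({qid}, {pmid}) must be 0 or 1, got {rel}")

    @property
    def query_ids(self) -> list[str]:
        return sorted({qid for qid, _ in self.judgements})

    def relevant(self, qid: str) -> set[int]:
        return {pmid for (q, pmid), rel in self.judgements.items() if q == qid and rel == 1}

    def n_relevant(self, qid: str) -> int:
        return len(self.relevant(qid))


def read_qrels(stream) -> QrelSet:
    """Read TREC qrels lines ``qid 0 pmid rel`` (whitespace-separated).

    Repeated (qid, pmid) pairs keep the last judgement, with a warning.
    Non-binary relevance values are rejected.
    """
    judgements: dict[tuple[str, int], int] = {}
    for lineno, line in enumerate(stream, start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 4 fields `qid 0 pmid rel`")
        qid, _, pmid_text, rel_text = parts
        try:
            pmid, rel = int(pmid_text), int(rel_text)
        except ValueError:
            raise ValueError(f"line {lineno}: pmid and relevance must be integers") from None
        if rel not in (0, 1):
            raise ValueError(f"line {lineno}: relevance must be binary, got {rel}")
        if (qid, pmid) in judgements:
            logger.warning("duplicate judgement for (%s, %d); keeping the last", qid, pmid)
        judgements[(qid, pmid)] = rel
    if not judgements:
        raise ValueError("empty qrels file")
    return QrelSet(judgements)


def write_qrels(qrels: QrelSet, stream) -> None:
    for (qid, pmid), rel in sorted(qrels.judgements.items()):
        stream.write(f"{qid} 0 {pmid} {rel}\n")


def _per_query(run: Run, qrels: QrelSet, scorer) -> dict[str, float]:
    return {qid: scorer(run.get(qid, []), qrels.relevant(qid), qrels.n_relevant(qid))
            for qid in qrels.query_ids}


def _mean(values: dict[str, float]) -> float:
    return sum(values.values()) / len(values) if values else 0.0


def precision_at_1(run: Run, qrels: QrelSet) -> float:
    """Mean over queries of [top-ranked document is relevant]."""
    return _mean(_per_query(run, qrels, _ap_scorers["p_at_1"]))


def precision_at_k(run: Run, qrels: QrelSet, k: int) -> float:
    """Mean over queries of the fraction of the top k that is relevant."""
    if k < 1:
        raise ValueError("k must be >= 1")

    def scorer(docs, relevant, _n_rel):
        top = docs[:k]
        return sum(1 for d in top if d.pmid in relevant) / k

    return _mean(_per_query(run, qrels, scorer))


def mean_reciprocal_rank(run: Run, qrels: QrelSet) -> float:
    """Mean over queries of 1/rank of the first relevant document retrieved,
    0 when none is."""
    return _mean(_per_query(run, qrels, _ap_scorers["rr"]))


def mean_average_precision(run: Run, qrels: QrelSet) -> float:
    """Mean over queries of average precision (precision at each relevant
    retrieved rank, divided by the total number of relevant documents)."""
    return _mean(_per_query(run, qrels, _ap_scorers["ap"]))


def _score_p_at_1(docs, relevant, _n_rel):
    return 1.0 if docs and docs[0].pmid in relevant else 0.0


def _score_rr(docs, relevant, _n_rel):
    for position, doc in enumerate(docs, start=1):
        if doc.pmid in relevant:
            return 1.0 / position
    return 0.0


def _score_ap(docs, relevant, n_rel):
    if n_rel == 0:
        return 0.0
    hits = 0
    precision_sum = 0.0
    for position, doc in enumerate(docs, start=1):
        if doc.pmid in relevant:
            hits += 1
            precision_sum += hits / position
    return precision_sum / n_rel


_ap_scorers = {"p_at_1": _score_p_at_1, "rr": _score_rr, "ap": _score_ap}


def relative_improvement(value: float, baseline: float) -> float:
    """100 * (value - baseline) / baseline, in percent."""
    if baseline <= 0:
        raise ValueError("baseline must be positive for a relative improvement")
    return 100.0 * (value - baseline) / baseline


@dataclass
class MetricReport:
    """Evaluation summary for one run, with optional per-query breakdown."""

    p_at_1: float
    mrr: float
    map: float
    p_at_k: dict[int, float] = field(default_factory=dict)
    per_query: dict[str, dict[str, float]] = field(default_factory=dict)
    improvement_vs_baseline: float | None = None

    def to_dict(self) -> dict:
        payload = {
            "P@1": self.p_at_1,
            "MRR": self.mrr,
            "MAP": self.map,
            **{f"P@{k}": v for k, v in sorted(self.p_at_k.items())},
        }
        if self.improvement_vs_baseline is not None:
            payload["improvement_vs_baseline_pct"] = self.improvement_vs_baseline
        if self.per_query:
            payload["per_query"] = self.per_query
        return payload

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_run(
    run: Run,
    qrels: QrelSet,
    ks: tuple[int, ...] = (5, 10),
    baseline_p_at_1: float | None = None,
) -> MetricReport:
    """Compute P@1 (P0), MRR, MAP and P@k for a run against qrels."""
    per_query = {
        qid: {
            "P@1": _score_p_at_1(run.get(qid, []), qrels.relevant(qid), qrels.n_relevant(qid)),
            "RR": _score_rr(run.get(qid, []), qrels.relevant(qid), qrels.n_relevant(qid)),
            "AP": _score_ap(run.get(qid, []), qrels.relevant(qid), qrels.n_relevant(qid)),
        }
        for qid in qrels.query_ids
    }
    p1 = _mean({q: v["P@1"] for q, v in per_query.items()})
    report = MetricReport(
        p_at_1=p1,
        mrr=_mean({q: v["RR"] for q, v in per_query.items()}),
        map=_mean({q: v["AP"] for q, v in per_query.items()}),
        p_at_k={k: precision_at_k(run, qrels, k) for k in ks},
        per_query=per_query,
    )
    if baseline_p_at_1 is not None and baseline_p_at_1 > 0:
        report.improvement_vs_baseline = relative_improvement(p1, baseline_p_at_1)
    return report
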