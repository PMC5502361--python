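"""Synthetic MEDLINE-like corpora with planted relevance signal.

The generator emulates the statistical skeleton of a curation benchmark:
for each (gene, axis) query a handful of documents are *relevant*, and in
those documents the gene is mentioned often (1 + Poisson(lambda_rel) times)
and several distinct axis concepts occur (1 + Poisson(mu_concepts) of them,
each rendered as a random morphological variant of one of its stems).
Irrelevant documents mention each gene only at the low background rate
lambda_irr and carry each concept independently with probability p_bg.
Everything else is filler tokens drawn uniformly from a synthetic
vocabulary; publication years are uniform over ``year_range`` so that a
recency-ranked Boolean baseline is well defined (and beatable).

Documents are token soup, not prose: BM25 and stem matching only see
tokens, so grammatical fluency would add nothing testable. A fixed seed
yields byte-identical output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from .annotate import annotate_document, build_profile
from .corpus import Document, DocumentSet
from .evaluation import MetricReport, QrelSet, evaluate_run, precision_at_1
from .fusion import PRESETS, FusionConfig, rerank
from .retrieval import QuerySpec, boolean_search, build_index, search
from .thesaurus import ConceptEntry, Thesaurus, default_thesaurus

__all__ = [
    "SynthParams",
    "SystemSpec",
    "BenchmarkReport",
    "generate_corpus",
    "default_systems",
    "run_benchmark",
]

_SUFFIXES = ("s", "es", "ed", "ing", "ion", "e")


@dataclass(frozen=True)
class SynthParams:
    """Generator knobs. Defaults give a desk-scale benchmark with clearly
    separated relevant/irrelevant classes (see the package methods note)."""

    n_docs: int = 500
    n_queries: int = 20
    relevant_per_query: int = 5
    filler_vocab_size: int = 1000
    gene_rate_relevant: float = 3.0    # lambda_rel: extra gene mentions in relevant docs
    gene_rate_irrelevant: float = 0.3  # lambda_irr: per-gene mention rate elsewhere
    concept_rate_relevant: float = 1.5  # mu_c: extra distinct concepts in relevant docs
    background_concept_prob: float = 0.05  # p_bg
    doc_length: float = 120.0
    year_range: tuple[int, int] = (1990, 2013)
    axis: str = "PPI"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1 or self.n_queries < 1 or self.relevant_per_query < 1:
            raise ValueError("n_docs, n_queries and relevant_per_query must be positive")
        # equality is allowed so a no-signal null corpus can be generated
        if not self.gene_rate_relevant >= self.gene_rate_irrelevant >= 0:
            raise ValueError("require gene_rate_relevant >= gene_rate_irrelevant >= 0")
        if not 0 <= self.background_concept_prob < 1:
            raise ValueError("background_concept_prob must be in [0, 1)")
        if self.n_queries * self.relevant_per_query > self.n_docs:
            raise ValueError("more planted-relevant documents than documents")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("empty year_range")


def _render_concept(entry: ConceptEntry, rng: np.random.Generator) -> str:
    """A random morphological variant of one of the entry's stems (or the
    multi-word label when the entry has no single-token stem)."""
    single = [s for s in entry.stems if " " not in s]
    if not single:
        return entry.label.lower()
    stem = single[int(rng.integers(len(single)))]
    return stem + _SUFFIXES[int(rng.integers(len(_SUFFIXES)))]


def generate_corpus(
    params: SynthParams,
    thesaurus: Thesaurus | None = None,
) -> tuple[DocumentSet, list[QuerySpec], QrelSet]:
    """Generate (documents, queries, qrels) with planted relevance."""
    thes = thesaurus if thesaurus is not None else default_thesaurus(params.axis)
    if len(thes) == 0:
        raise ValueError("cannot plant concepts from an empty thesaurus")
    rng = np.random.default_rng(params.seed)
    genes = [f"gene{i}" for i in range(params.n_queries)]
    filler = [f"w{j}" for j in range(params.filler_vocab_size)]

    # block assignment: doc k is relevant to query k // relevant_per_query
    n_planted = params.n_queries * params.relevant_per_query
    judgements: dict[tuple[str, int], int] = {}
    docs: list[Document] = []
    for k in range(params.n_docs):
        pmid = 100001 + k
        target = k // params.relevant_per_query if k < n_planted else None
        tokens: list[str] = []
        for gi, gene in enumerate(genes):
            if gi == target:
                count = 1 + int(rng.poisson(params.gene_rate_relevant))
            else:
                count = int(rng.poisson(params.gene_rate_irrelevant))
            tokens.extend([gene] * count)
        if target is not None:
            n_concepts = min(1 + int(rng.poisson(params.concept_rate_relevant)), len(thes))
            chosen = rng.choice(len(thes), size=n_concepts, replace=False)
            for ci in chosen:
                tokens.append(_render_concept(thes.entries[int(ci)], rng))
            judgements[(f"q{target}", pmid)] = 1
        else:
            for entry in thes.entries:
                if rng.random() < params.background_concept_prob:
                    tokens.append(_render_concept(entry, rng))
        n_filler = max(0, int(rng.poisson(params.doc_length)) - len(tokens))
        tokens.extend(filler[int(j)] for j in rng.integers(len(filler), size=n_filler))
        order = rng.permutation(len(tokens))
        tokens = [tokens[int(i)] for i in order]
        year = int(rng.integers(params.year_range[0], params.year_range[1] + 1))
        title, body = tokens[:8], tokens[8:]
        docs.append(
            Document(
                pmid=pmid,
                title=" ".join(title),
                abstract=" ".join(body),
                pub_date=dt.date(year, 1, 1),
            )
        )

    queries = [
        QuerySpec(gene=genes[i], axis=params.axis, top_k=1000)
        for i in range(params.n_queries)
    ]
    return DocumentSet(docs), queries, QrelSet(judgements)


# ---------------------------------------------------------------------------
# Benchmark driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemSpec:
    """One ranking system to benchmark: an optional fusion config applied on
    top of the engine run, with or without query refinement."""

    name: str
    fusion: FusionConfig | None = None
    refine: bool = False


def default_systems(axis: str) -> list[SystemSpec]:
    """The benchmark ladder for an axis: fused base formula, then the
    query-refinement variant."""
    return [
        SystemSpec(name=f"fused_{axis}_base", fusion=PRESETS[f"{axis}_base"]),
        SystemSpec(name=f"fused_{axis}_refined", fusion=PRESETS[f"{axis}_refined"], refine=True),
    ]


@dataclass
class BenchmarkReport:
    """Per-system metric rows with relative improvement vs the Boolean
    recency baseline."""

    rows: dict[str, MetricReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            name: {k: v for k, v in report.to_dict().items() if k != "per_query"}
            for name, report in self.rows.items()
        }

    def to_text(self) -> str:
        lines = [f"{'system':<24} {'P@1':>7} {'MRR':>7} {'MAP':>7} {'vs baseline':>12}"]
        for name, report in self.rows.items():
            imp = (
                "-" if report.improvement_vs_baseline is None
                else f"{report.improvement_vs_baseline:+.1f}%"
            )
            lines.append(
                f"{name:<24} {report.p_at_1:7.3f} {report.mrr:7.3f} "
                f"{report.map:7.3f} {imp:>12}"
            )
        return "\n".join(lines)


def run_benchmark(
    docs: DocumentSet,
    queries: list[QuerySpec],
    qrels: QrelSet,
    configs: list[SystemSpec | FusionConfig] | None = None,
    thesaurus: Thesaurus | None = None,
) -> BenchmarkReport:
    """Benchmark the triage ladder on one corpus.

    Always evaluates the Boolean recency baseline (``boolean_recency``) and
    the engine-only BM25 ranking (``engine``); then each fused system in
    ``configs``. Plain :class:`FusionConfig` entries are wrapped as
    non-refined systems. Improvements are relative to the Boolean baseline's
    P@1.
    """
    if not queries:
        raise ValueError("no queries to benchmark")
    axis = queries[0].axis
    systems: list[SystemSpec] = []
    for i, cfg in enumerate(configs if configs is not None else default_systems(axis)):
        if isinstance(cfg, FusionConfig):
            systems.append(SystemSpec(name=f"fused_{i}", fusion=cfg))
        else:
            systems.append(cfg)

    index = build_index(docs)
    thes = thesaurus if thesaurus is not None else default_thesaurus(axis)
    profiles = {
        doc.pmid: build_profile(annotate_document(doc, thes), thes) for doc in docs
    }

    runs: dict[str, dict[str, list]] = {
        "boolean_recency": {
            f"q{i}": boolean_search(index, q, mode="OR") for i, q in enumerate(queries)
        },
        "engine": {f"q{i}": search(index, q) for i, q in enumerate(queries)},
    }
    for system in systems:
        if system.fusion is None:
            base = {
                f"q{i}": search(index, replace(q, refinement=system.refine))
                for i, q in enumerate(queries)
            }
            runs[system.name] = base
            continue
        runs[system.name] = {
            f"q{i}": rerank(
                search(index, replace(q, refinement=system.refine)), profiles, system.fusion
            )
            for i, q in enumerate(queries)
        }

    baseline_p1 = precision_at_1(runs["boolean_recency"], qrels)
    report = BenchmarkReport()
    for name, run in runs.items():
        report.rows[name] = evaluate_run(
            run, qrels,
            baseline_p_at_1=baseline_p1 if name != "boolean_recency" else None,
        )
        report.rows[name].per_query = {}  # keep the report compact
    return report
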