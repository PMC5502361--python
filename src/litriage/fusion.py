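"""Linear score fusion: re-score a ranked list with concept density.

The triage ranking combines the vector-space engine score s with an
axis-specific concept-density term in a weighted sum. Two density variants
exist:

* ``distinct_count``:  alpha * s + beta * D, where D is the number of
  distinct concepts annotated in the document;
* ``log_len_tf``:      alpha * s + beta * sum_c ln(1 + len_c * tf_c), where
  len_c is the concept's canonical-label length in characters (a specificity
  proxy) and tf_c its occurrence count.

Four named presets carry the tuned weights: PPI_base (0.9, 1.5) and
PTM_base (0.9, 1.7) on distinct counts, and the query-refinement variants
PPI_refined (1.0, 0.1 on the log-length-tf term) and PTM_refined (1.4, 1.3
on distinct counts). Logarithms are natural. Engine scores are used raw —
the weights are absolute, with no per-query normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .annotate import ConceptProfile
from .retrieval import ScoredDoc

__all__ = ["FusionConfig", "PRESETS", "fuse_distinct", "fuse_logtf", "fuse", "rerank"]

VARIANTS = ("distinct_count", "log_len_tf")


@dataclass(frozen=True)
class FusionConfig:
    variant: str
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown fusion variant {self.variant!r}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("fusion weights must be non-negative")


PRESETS: dict[str, FusionConfig] = {
    "PPI_base": FusionConfig("distinct_count", alpha=0.9, beta=1.5),
    "PTM_base": FusionConfig("distinct_count", alpha=0.9, beta=1.7),
    "PPI_refined": FusionConfig("log_len_tf", alpha=1.0, beta=0.1),
    "PTM_refined": FusionConfig("distinct_count", alpha=1.4, beta=1.3),
}


def fuse_distinct(s: float, distinct_count: int, cfg: FusionConfig) -> float:
    """alpha * s + beta * D."""
    if cfg.variant != "distinct_count":
        raise ValueError(f"fuse_distinct requires the distinct_count variant, got {cfg.variant}")
    if s < 0:
        raise ValueError("engine score must be non-negative")
    if distinct_count < 0:
        raise ValueError("distinct count must be non-negative")
    return cfg.alpha * s + cfg.beta * distinct_count


def fuse_logtf(s: float, profile: ConceptProfile, cfg: FusionConfig) -> float:
    """alpha * s + beta * sum_c ln(1 + len_c * tf_c)."""
    if cfg.variant != "log_len_tf":
        raise ValueError(f"fuse_logtf requires the log_len_tf variant, got {cfg.variant}")
    if s < 0:
        raise ValueError("engine score must be non-negative")
    density = 0.0
    for concept_id, tf in profile.tf.items():
        length = profile.desc_len.get(concept_id, 0)
        if tf <= 0 or length <= 0:
            raise ValueError(
                f"concept {concept_id!r}: tf and descriptor length must be positive "
                f"(tf={tf}, len={length})"
            )
        density += math.log1p(length * tf)
    return cfg.alpha * s + cfg.beta * density


_EMPTY = ConceptProfile()


def fuse(s: float, profile: ConceptProfile, cfg: FusionConfig) -> float:
    """Dispatch on the configured variant."""
    if cfg.variant == "distinct_count":
        return fuse_distinct(s, profile.distinct_count, cfg)
    return fuse_logtf(s, profile, cfg)


def rerank(
    run: list[ScoredDoc],
    profiles: dict[int, ConceptProfile],
    cfg: FusionConfig,
) -> list[ScoredDoc]:
    """Re-score a ranked list with the configured fusion and re-sort.

    Documents without a profile get an empty one (D = 0): retrieved
    documents bearing no axis concept are kept, not dropped. The output is
    a permutation of the input; ties break by PMID descending.
    """
    fused = [
        (doc.pmid, doc.engine_score, fuse(doc.engine_score, profiles.get(doc.pmid, _EMPTY), cfg))
        for doc in run
    ]
    fused.sort(key=lambda item: (-item[2], -item[0]))
    return [
        ScoredDoc(pmid=pmid, engine_score=s, fused_score=f, rank=rank)
        for rank, (pmid, s, f) in enumerate(fused, start=1)
    ]
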