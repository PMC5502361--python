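"""Axis-specific concept vocabularies (thesauri).

A triage *axis* is a curation data type: protein-protein interactions (PPI)
or post-translational modifications (PTM). Each axis has a small controlled
vocabulary of *concepts* (descriptors): interaction trigger terms and
experimental detection methods for PPI, modification types for PTM. Every
concept carries one or more lowercase *stems* — truncated word forms such as
``phosphorylat`` that match all morphological variants (phosphorylated,
phosphorylates, phosphorylating, phosphorylation) by prefix.

Two defaults ship with the package (see ``litriage/data/``): a PPI
vocabulary of 23 concepts (14 interaction stems + 9 experimental methods;
a reconstruction, see the data-file header) and a PTM vocabulary of the 16
most frequently curated modification types.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from importlib import resources

logger = logging.getLogger(__name__)

__all__ = [
    "Axis",
    "CATEGORIES",
    "ConceptEntry",
    "Thesaurus",
    "ThesaurusError",
    "load_thesaurus",
    "default_thesaurus",
]

CATEGORIES = ("interaction_term", "experimental_method", "ptm_type")
_AXIS_CATEGORIES = {
    "PPI": {"interaction_term", "experimental_method"},
    "PTM": {"ptm_type"},
}
Axis = str  # "PPI" | "PTM"


class ThesaurusError(ValueError):
    """Raised for invalid thesaurus tables."""


@dataclass(frozen=True)
class ConceptEntry:
    """One controlled-vocabulary descriptor.

    ``stems`` are lowercase match patterns: a single-token stem matches any
    word token that starts with it; a multi-token stem (space-separated)
    matches a window of consecutive tokens, each by prefix. The canonical
    ``label`` length in characters serves downstream as a crude specificity
    proxy (longer descriptors tend to be more specific).
    """

    concept_id: str
    label: str
    stems: tuple[str, ...]
    category: str

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ThesaurusError("empty concept_id")
        if not self.label.strip():
            raise ThesaurusError(f"{self.concept_id}: empty label")
        if not self.stems:
            raise ThesaurusError(f"{self.concept_id}: at least one stem required")
        for stem in self.stems:
            if not stem or stem != stem.strip() or stem != stem.lower():
                raise ThesaurusError(
                    f"{self.concept_id}: stems must be non-empty, lowercase, "
                    f"trimmed; got {stem!r}"
                )
        if self.category not in CATEGORIES:
            raise ThesaurusError(f"{self.concept_id}: unknown category {self.category!r}")

    @property
    def desc_len(self) -> int:
        """Canonical-label length in characters, surrounding whitespace excluded."""
        return len(self.label.strip())


@dataclass(frozen=True)
class Thesaurus:
    axis: Axis
    entries: tuple[ConceptEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.axis not in _AXIS_CATEGORIES:
            raise ThesaurusError(f"unknown axis {self.axis!r}; expected PPI or PTM")
        seen: set[str] = set()
        for e in self.entries:
            if e.concept_id in seen:
                raise ThesaurusError(f"duplicate concept_id {e.concept_id!r}")
            seen.add(e.concept_id)
            if e.category not in _AXIS_CATEGORIES[self.axis]:
                raise ThesaurusError(
                    f"{e.concept_id}: category {e.category!r} not allowed on axis {self.axis}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, concept_id: str) -> ConceptEntry | None:
        for e in self.entries:
            if e.concept_id == concept_id:
                return e
        return None


def load_thesaurus(table, axis: Axis) -> Thesaurus:
    """Load a thesaurus from a TSV table.

    Columns: ``concept_id``, ``label``, ``stems`` (pipe-separated; spaces
    inside a stem make it a multi-token stem), ``category``. Lines starting
    with ``#`` are comments. An empty table yields a valid empty thesaurus
    with a warning.
    """
    if isinstance(table, str):
        table = io.StringIO(table)
    rows = [
        row for row in csv.reader(table, delimiter="\t")
        if row and not row[0].lstrip().startswith("#")
    ]
    if not rows:
        logger.warning("empty thesaurus table for axis %s", axis)
        return Thesaurus(axis=axis)
    header, *body = rows
    if header != ["concept_id", "label", "stems", "category"]:
        raise ThesaurusError(f"bad thesaurus header {header!r}")
    entries = []
    for row in body:
        if len(row) != 4:
            raise ThesaurusError(f"expected 4 columns, got {row!r}")
        concept_id, label, stems_text, category = row
        stems = tuple(s.strip().lower() for s in stems_text.split("|") if s.strip())
        entries.append(ConceptEntry(concept_id, label, stems, category))
    if not entries:
        logger.warning("thesaurus table for axis %s has no entries", axis)
    return Thesaurus(axis=axis, entries=tuple(entries))


def default_thesaurus(axis: Axis) -> Thesaurus:
    """The bundled default vocabulary for an axis (PPI: 23 concepts,
    PTM: 16 modification types)."""
    filename = {"PPI": "ppi_thesaurus.tsv", "PTM": "ptm_thesaurus.tsv"}.get(axis)
    if filename is None:
        raise ThesaurusError(f"unknown axis {axis!r}; expected PPI or PTM")
    text = resources.files("litriage.data").joinpath(filename).read_text(encoding="utf-8")
    return load_thesaurus(text, axis)
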