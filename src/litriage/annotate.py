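"""Dictionary-based concept mark-up of abstracts.

Concept occurrences are found by stem matching over word tokens: a token
matches a single-token stem when it *starts with* the stem (so the stem
``phosphorylat`` covers phosphorylated, phosphorylates, phosphorylating and
phosphorylation), and a window of consecutive tokens matches a multi-token
stem when each token starts with the corresponding stem component. Multi-word
canonical labels additionally match by exact lowercase phrase equality over
token windows. Matching is case-insensitive; hyphens and slashes separate
tokens (so "ubiquitin-mediated" exposes "ubiquitin"), digits stay inside
tokens.

All offsets are 0-based half-open character positions into the document's
``title + " " + abstract`` text; the sentence index of each match is recorded
alongside.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .corpus import Document
from .thesaurus import ConceptEntry, Thesaurus

__all__ = [
    "Token",
    "Annotation",
    "ConceptProfile",
    "tokenize",
    "split_sentences",
    "annotate_document",
    "annotate_text",
    "build_profile",
    "write_annotations_jsonl",
]

# word tokens: runs of letters/digits; underscore, hyphen, slash etc. separate
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)
# sentence boundary: terminal punctuation, whitespace, then uppercase or digit
_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[A-Z0-9])")


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    lower: str


def tokenize(text: str) -> list[Token]:
    """Word tokens with character offsets, lowercased."""
    return [Token(m.start(), m.end(), m.group().lower()) for m in _TOKEN_RE.finditer(text)]


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans ``(start, end)``.

    Boundaries fall after sentence-final punctuation followed by whitespace
    and an uppercase letter or digit. Spans are ordered, non-overlapping and
    trimmed so they cover exactly the non-whitespace text. Note the rule is
    deliberately simple: "Fig. 2" splits after "Fig." because a digit follows.
    """
    spans: list[tuple[int, int]] = []
    cursor = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        spans.append((cursor, m.end()))
        cursor = m.end()
    spans.append((cursor, len(text)))

    trimmed = []
    for start, end in spans:
        chunk = text[start:end]
        lstrip = len(chunk) - len(chunk.lstrip())
        rstrip = len(chunk) - len(chunk.rstrip())
        if start + lstrip < end - rstrip:
            trimmed.append((start + lstrip, end - rstrip))
    return trimmed


@dataclass(frozen=True)
class Annotation:
    """One concept occurrence: where it is and what it says."""

    concept_id: str
    sentence_index: int
    char_start: int
    char_end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.char_start < self.char_end):
            raise ValueError(f"bad annotation offsets [{self.char_start}, {self.char_end})")


@dataclass(frozen=True)
class ConceptProfile:
    """Per-document concept-density statistics.

    ``tf`` maps each annotated concept to its occurrence count; ``desc_len``
    to its canonical-label length in characters. ``distinct_count`` (the
    number of different concepts present) is the density statistic the base
    fusion formulas use.
    """

    tf: dict[str, int] = field(default_factory=dict)
    desc_len: dict[str, int] = field(default_factory=dict)

    @property
    def distinct_count(self) -> int:
        return len(self.tf)


def _entry_patterns(entry: ConceptEntry) -> list[tuple[tuple[str, ...], bool]]:
    """Match patterns for an entry: (token components, exact?) pairs."""
    patterns: list[tuple[tuple[str, ...], bool]] = []
    for stem in entry.stems:
        patterns.append((tuple(stem.split()), False))
    label_tokens = tuple(t.lower for t in tokenize(entry.label))
    if len(label_tokens) > 1:
        patterns.append((label_tokens, True))
    return patterns


def _match_at(tokens: list[Token], i: int, parts: tuple[str, ...], exact: bool) -> bool:
    if i + len(parts) > len(tokens):
        return False
    for part, token in zip(parts, tokens[i:i + len(parts)]):
        if exact:
            if token.lower != part:
                return False
        elif not token.lower.startswith(part):
            return False
    return True


def annotate_text(text: str, thes: Thesaurus) -> list[Annotation]:
    """All non-overlapping concept matches in ``text``, longest match first,
    sorted by start offset."""
    tokens = tokenize(text)
    sentences = split_sentences(text)
    compiled = [(entry, _entry_patterns(entry)) for entry in thes.entries]

    def sentence_of(pos: int) -> int:
        for idx, (start, end) in enumerate(sentences):
            if start <= pos < end:
                return idx
        return max(0, len(sentences) - 1)

    annotations: list[Annotation] = []
    i = 0
    while i < len(tokens):
        best: tuple[int, ConceptEntry] | None = None
        for entry, patterns in compiled:
            for parts, exact in patterns:
                if _match_at(tokens, i, parts, exact):
                    if best is None or len(parts) > best[0]:
                        best = (len(parts), entry)
        if best is None:
            i += 1
            continue
        n_tokens, entry = best
        start = tokens[i].start
        end = tokens[i + n_tokens - 1].end
        annotations.append(
            Annotation(
                concept_id=entry.concept_id,
                sentence_index=sentence_of(start),
                char_start=start,
                char_end=end,
                surface=text[start:end],
            )
        )
        i += n_tokens
    return annotations


def annotate_document(doc: Document, thes: Thesaurus) -> list[Annotation]:
    """Concept annotations over the document's title+abstract text."""
    return annotate_text(doc.text, thes)


def build_profile(annotations: list[Annotation], thes: Thesaurus) -> ConceptProfile:
    """Aggregate annotations into a :class:`ConceptProfile`."""
    tf: dict[str, int] = {}
    desc_len: dict[str, int] = {}
    for ann in annotations:
        entry = thes.get(ann.concept_id)
        if entry is None:
            raise ValueError(f"annotation references unknown concept {ann.concept_id!r}")
        tf[ann.concept_id] = tf.get(ann.concept_id, 0) + 1
        desc_len[ann.concept_id] = entry.desc_len
    return ConceptProfile(tf=tf, desc_len=desc_len)


def write_annotations_jsonl(pmid: int, annotations: list[Annotation], stream) -> None:
    """Serialize annotations as JSON-lines, one record per occurrence."""
    for ann in annotations:
        stream.write(json.dumps({
            "pmid": pmid,
            "concept_id": ann.concept_id,
            "sentence_index": ann.sentence_index,
            "char_start": ann.char_start,
            "char_end": ann.char_end,
            "surface": ann.surface,
        }) + "\n")
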