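"""Mapping annotator-reported surface strings back to character spans.

Annotators report only surface strings per class, never offsets, so training
data is built by searching the source text for each reported surface at
whole-token boundaries and labeling every occurrence (the standard
distant-supervision choice: a class->strings mapping carries no
per-occurrence information).  Surfaces absent from the text — hallucinated
or reformatted by the annotator — are dropped and logged, never invented.
Overlapping candidate spans are resolved greedily (longer span wins, then
earlier start, then class priority DRUG > PROCEDURE > DISEASE > SMOKING)
before emission as IOB2 tags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation import AnnotationResponse
from .corpus_io import ENTITY_CLASSES, Document, TaggedSequence, TokenizedText, tokenize

_CLASS_PRIORITY = {cls: i for i, cls in enumerate(ENTITY_CLASSES)}


@dataclass(frozen=True)
class EntityMention:
    """A labeled span: class, surface, character span and token span (both
    0-based half-open)."""

    doc_id: str
    label: str
    surface: str
    char_span: tuple[int, int]
    token_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.char_span[1] <= self.char_span[0]:
            raise ValueError(f"empty char span {self.char_span} for {self.surface!r}")
        if self.token_span[1] <= self.token_span[0]:
            raise ValueError(f"empty token span {self.token_span} for {self.surface!r}")


@dataclass(frozen=True)
class AlignPolicy:
    case_insensitive: bool = True
    all_occurrences: bool = True  # False: annotate only the first occurrence
    collapse_whitespace: bool = True


@dataclass
class AlignmentLog:
    """Bookkeeping for one corpus alignment pass."""

    skipped_unparsed: int = 0
    dropped: list[tuple[str, str, str, str]] = field(default_factory=list)  # doc, class, surface, reason

    def dropped_by_reason(self) -> Counter:
        return Counter(reason for *_, reason in self.dropped)


def _norm(token: str, policy: AlignPolicy) -> str:
    return token.lower() if policy.case_insensitive else token


def map_entities_to_spans(
    doc: Document,
    response: AnnotationResponse,
    policy: AlignPolicy = AlignPolicy(),
) -> tuple[list[EntityMention], list[tuple[str, str, str]]]:
    """Locate every whole-token-boundary occurrence of each reported surface.

    Returns mentions sorted by (start, end) plus dropped (class, surface,
    reason) records.  Whitespace inside surfaces is normalized by matching at
    the token level, so "a  b" matches "a b".
    """
    if not response.parsed:
        raise ValueError(f"document {doc.id!r}: response is unparsed; filter first")
    tokenized = tokenize(doc.text, doc.id)
    doc_norm = [_norm(t.surface, policy) for t in tokenized.tokens]
    mentions: list[EntityMention] = []
    dropped: list[tuple[str, str, str]] = []
    for cls, surfaces in response.entities.items():
        for surface in surfaces:
            surf_toks = [_norm(t, policy) for t in tokenize(surface).surfaces()]
            if not surf_toks:
                dropped.append((cls, surface, "empty_surface"))
                continue
            hits = [
                i
                for i in range(len(doc_norm) - len(surf_toks) + 1)
                if doc_norm[i : i + len(surf_toks)] == surf_toks
            ]
            if not hits:
                dropped.append((cls, surface, "not_found"))
                continue
            if not policy.all_occurrences:
                hits = hits[:1]
            for i in hits:
                first, last = tokenized.tokens[i], tokenized.tokens[i + len(surf_toks) - 1]
                mentions.append(
                    EntityMention(
                        doc_id=doc.id,
                        label=cls,
                        surface=doc.text[first.start : last.end],
                        char_span=(first.start, last.end),
                        token_span=(i, i + len(surf_toks)),
                    )
                )
    # distinct classes may report the same span; dedupe exact duplicates only
    mentions = sorted(
        set(mentions), key=lambda m: (m.char_span, _CLASS_PRIORITY[m.label])
    )
    return mentions, dropped


def resolve_overlaps(mentions: Sequence[EntityMention]) -> list[EntityMention]:
    """Greedy selection among overlapping mentions: longer span wins, ties by
    earlier start, then class priority.  Output is pairwise non-overlapping,
    sorted by start."""
    ranked = sorted(
        mentions,
        key=lambda m: (
            -(m.char_span[1] - m.char_span[0]),
            m.char_span[0],
            _CLASS_PRIORITY[m.label],
        ),
    )
    kept: list[EntityMention] = []
    for m in ranked:
        if all(
            m.char_span[1] <= o.char_span[0] or m.char_span[0] >= o.char_span[1]
            for o in kept
        ):
            kept.append(m)
    return sorted(kept, key=lambda m: m.char_span)


def spans_to_tags(tokenized: TokenizedText, mentions: Sequence[EntityMention]) -> TaggedSequence:
    """Emit IOB2 tags: tokens overlapping a mention's char span get B-/I-.

    A mention whose span ends mid-token claims the whole token.  Mentions must
    be non-overlapping (resolve first)."""
    ordered = sorted(mentions, key=lambda m: m.char_span)
    for a, b in zip(ordered, ordered[1:]):
        if b.char_span[0] < a.char_span[1]:
            raise ValueError(
                f"overlapping mentions {a.char_span} and {b.char_span}; resolve first"
            )
    tags = ["O"] * len(tokenized.tokens)
    for m in ordered:
        start, end = m.char_span
        covered = [
            i
            for i, t in enumerate(tokenized.tokens)
            if t.start < end and t.end > start
        ]
        for pos, i in enumerate(covered):
            tags[i] = ("B-" if pos == 0 else "I-") + m.label
    return TaggedSequence(doc_id=tokenized.doc_id, tokens=list(tokenized.tokens), tags=tags)


def build_training_set(
    corpus: Sequence[Document],
    responses: Sequence[AnnotationResponse],
    policy: AlignPolicy = AlignPolicy(),
) -> tuple[list[TaggedSequence], AlignmentLog]:
    """Compose map -> resolve -> tag per parsed document.

    Corpus and responses must be aligned by document id; unparsed responses
    are skipped and counted in the log."""
    if len(corpus) != len(responses):
        raise ValueError(
            f"corpus ({len(corpus)}) and responses ({len(responses)}) differ in length"
        )
    log = AlignmentLog()
    tagged: list[TaggedSequence] = []
    for doc, resp in zip(corpus, responses):
        if doc.id != resp.doc_id:
            raise ValueError(f"id mismatch: document {doc.id!r} vs response {resp.doc_id!r}")
        if not resp.parsed:
            log.skipped_unparsed += 1
            continue
        mentions, dropped = map_entities_to_spans(doc, resp, policy)
        log.dropped.extend((doc.id, cls, surf, reason) for cls, surf, reason in dropped)
        resolved = resolve_overlaps(mentions)
        tagged.append(spans_to_tags(tokenize(doc.text, doc.id), resolved))
    return tagged, log
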