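"""Document model, tokenization, and JSONL / CoNLL-style TSV readers and writers.

Documents are short clinical-style free texts carrying the metadata header
fields used to condition synthetic generation: document type (medical history
or procedure note), patient age band, gender, and an ICD-10 diagnosis code.
Tokenization is deliberately simple — whitespace split plus peeling of
leading/trailing punctuation — because every downstream step (LCS scoring,
span alignment, IOB2 tagging, entity-level evaluation) operates at the word
level and only needs deterministic, offset-preserving tokens.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

#: the four entity classes, in priority order (used for tie-breaking)
ENTITY_CLASSES: tuple[str, ...] = ("DRUG", "PROCEDURE", "DISEASE", "SMOKING")

DOC_TYPES: tuple[str, ...] = ("medical_history", "procedure")

UNKNOWN = "unknown"


@dataclass(frozen=True)
class Document:
    """One free-text document with its generation-time metadata header."""

    id: str
    text: str
    doc_type: str = UNKNOWN
    age_group: str = UNKNOWN
    gender: str = UNKNOWN
    diagnosis_code: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"document {self.id!r}: text must be non-empty")
        if self.doc_type not in DOC_TYPES and self.doc_type != UNKNOWN:
            raise ValueError(
                f"document {self.id!r}: doc_type {self.doc_type!r} not in {DOC_TYPES}"
            )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "doc_type": self.doc_type,
            "age_group": self.age_group,
            "gender": self.gender,
            "diagnosis_code": self.diagnosis_code,
            "text": self.text,
        }


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int  # half-open


@dataclass
class TokenizedText:
    """Ordered tokens with 0-based half-open character offsets into one text."""

    doc_id: str
    tokens: list[Token]

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


_WS_CHUNK = re.compile(r"\S+")


def tokenize(text: str, doc_id: str = "") -> TokenizedText:
    """Split ``text`` on whitespace, then peel leading/trailing punctuation
    characters into their own tokens.  Offsets index into ``text`` and satisfy
    ``text[start:end] == surface`` for every token.
    """
    tokens: list[Token] = []
    for m in _WS_CHUNK.finditer(text):
        start, end = m.start(), m.end()
        # peel leading punctuation
        while start < end and _is_punct(text[start]):
            tokens.append(Token(text[start], start, start + 1))
            start += 1
        # find trailing punctuation run (emitted after the core token)
        trail = end
        while trail > start and _is_punct(text[trail - 1]):
            trail -= 1
        if trail > start:
            tokens.append(Token(text[start:trail], start, trail))
        for i in range(trail, end):
            tokens.append(Token(text[i], i, i + 1))
    return TokenizedText(doc_id=doc_id, tokens=tokens)


def _validate_iob2(tags: Sequence[str], classes: Sequence[str]) -> None:
    valid = {"O"} | {f"{p}-{c}" for p in "BI" for c in classes}
    prev = "O"
    for i, tag in enumerate(tags):
        if tag not in valid:
            raise ValueError(f"unknown tag {tag!r} at position {i}")
        if tag.startswith("I-"):
            cls = tag[2:]
            if prev not in (f"B-{cls}", f"I-{cls}"):
                raise ValueError(
                    f"IOB2 violation at position {i}: {tag} after {prev}"
                )
        prev = tag


@dataclass
class TaggedSequence:
    """Tokens plus one IOB2 label per token."""

    doc_id: str
    tokens: list[Token]
    tags: list[str]
    classes: tuple[str, ...] = ENTITY_CLASSES

    def __post_init__(self) -> None:
        if len(self.tags) != len(self.tokens):
            raise ValueError(
                f"doc {self.doc_id!r}: {len(self.tags)} tags for {len(self.tokens)} tokens"
            )
        _validate_iob2(self.tags, self.classes)


def read_jsonl_corpus(path: str | Path) -> list[Document]:
    """Read one Document per line; missing metadata fields become "unknown"."""
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            if not isinstance(obj, dict) or "id" not in obj or "text" not in obj:
                raise ValueError(f"{path}: line {lineno} lacks required fields 'id'/'text'")
            docs.append(
                Document(
                    id=str(obj["id"]),
                    text=obj["text"],
                    doc_type=obj.get("doc_type", UNKNOWN),
                    age_group=obj.get("age_group", UNKNOWN),
                    gender=obj.get("gender", UNKNOWN),
                    diagnosis_code=obj.get("diagnosis_code", UNKNOWN),
                )
            )
    ids = [d.id for d in docs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate document ids")
    return docs


def write_jsonl_corpus(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.to_dict(), ensure_ascii=False) + "\n")


def write_conll(tagged: Iterable[TaggedSequence], path: str | Path) -> None:
    """Two-column ``token<TAB>tag`` TSV, blank line between documents."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in tagged:
            for tok, tag in zip(seq.tokens, seq.tags):
                fh.write(f"{tok.surface}\t{tag}\n")
            fh.write("\n")


def read_conll(
    path: str | Path, classes: Sequence[str] = ENTITY_CLASSES
) -> list[TaggedSequence]:
    """Inverse of :func:`write_conll`.

    Character offsets are not serialized; they are re-derived by joining token
    surfaces with single spaces, which preserves (surface, tag) pairs exactly.
    """
    valid = {"O"} | {f"{p}-{c}" for p in "BI" for c in classes}
    sequences: list[TaggedSequence] = []
    surfaces: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        if not surfaces:
            return
        tokens: list[Token] = []
        pos = 0
        for s in surfaces:
            tokens.append(Token(s, pos, pos + len(s)))
            pos += len(s) + 1
        sequences.append(
            TaggedSequence(
                doc_id=f"doc-{len(sequences):05d}",
                tokens=tokens,
                tags=list(tags),
                classes=tuple(classes),
            )
        )
        surfaces.clear()
        tags.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                flush()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno} is not 'token<TAB>tag'")
            surface, tag = parts
            if tag not in valid:
                raise ValueError(f"{path}: line {lineno}: unknown tag {tag!r}")
            surfaces.append(surface)
            tags.append(tag)
    flush()
    return sequences
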