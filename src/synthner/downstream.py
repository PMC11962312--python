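"""Desk-scale downstream tagger learned from weakly labeled sequences.

A dictionary (gazetteer) tagger stands in for the fine-tuned multilingual
transformer of the full pipeline: it memorizes the surface token sequences
observed as chunks in the weak training data, assigns each surface its
majority class, and tags unseen text by leftmost-longest dictionary matching.
This captures the part of the learning problem the weak labels actually
determine — which surfaces belong to which class — while remaining fully
deterministic and CPU-cheap; contextual generalization to unseen surfaces is
deliberately out of scope (the CoNLL export keeps external fine-tuning open).
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus_io import ENTITY_CLASSES, TaggedSequence, Token
from .evaluation import extract_chunks

_CLASS_PRIORITY = {cls: i for i, cls in enumerate(ENTITY_CLASSES)}


def split_train_validation(
    corpus: Sequence[TaggedSequence],
    validation_fraction: float = 0.15,
    seed: int = 0,
) -> tuple[list[TaggedSequence], list[TaggedSequence]]:
    """Seeded shuffle-then-split; validation gets round(n * fraction) items."""
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in (0, 1)")
    if len(corpus) < 2:
        raise ValueError("corpus must contain at least 2 documents to split")
    indices = list(range(len(corpus)))
    random.Random(seed).shuffle(indices)
    n_val = max(1, round(len(corpus) * validation_fraction))
    val_idx = set(indices[:n_val])
    train = [corpus[i] for i in indices[n_val:]]
    validation = [corpus[i] for i in sorted(val_idx)]
    return train, validation


@dataclass
class SurfaceModel:
    """Learned surface -> class mapping with observation counts."""

    surfaces: dict[tuple[str, ...], str] = field(default_factory=dict)
    counts: dict[tuple[str, ...], Counter] = field(default_factory=dict)
    min_frequency: int = 1

    @property
    def max_len(self) -> int:
        return max((len(s) for s in self.surfaces), default=0)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for surface, cls in sorted(self.surfaces.items()):
                total = sum(self.counts[surface].values())
                fh.write(f"{cls}\t{' '.join(surface)}\t{total}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SurfaceModel":
        model = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                label, surface, count = line.rstrip("\n").split("\t")
                key = tuple(surface.split(" "))
                model.surfaces[key] = label
                model.counts[key] = Counter({label: int(count)})
        return model


def train_surface_tagger(
    train: Sequence[TaggedSequence], min_frequency: int = 1
) -> SurfaceModel:
    """Count (surface token sequence, class) chunk observations; keep surfaces
    seen at least ``min_frequency`` times, each mapped to its majority class
    (ties broken by class priority order)."""
    if not train:
        raise ValueError("training data must be non-empty")
    counts: dict[tuple[str, ...], Counter] = {}
    for seq in train:
        for cls, start, end in extract_chunks(seq.tags):
            surface = tuple(t.surface for t in seq.tokens[start:end])
            counts.setdefault(surface, Counter())[cls] += 1
    model = SurfaceModel(min_frequency=min_frequency)
    for surface, ctr in counts.items():
        total = sum(ctr.values())
        if total < min_frequency:
            continue
        best = max(ctr.items(), key=lambda kv: (kv[1], -_CLASS_PRIORITY[kv[0]]))
        model.surfaces[surface] = best[0]
        model.counts[surface] = ctr
    return model


def tag(tokens: Sequence[Token], model: SurfaceModel, doc_id: str = "") -> TaggedSequence:
    """Leftmost-longest dictionary matching over the token sequence."""
    surfaces = [t.surface for t in tokens]
    tags = ["O"] * len(tokens)
    i = 0
    max_len = model.max_len
    while i < len(tokens):
        matched = 0
        for width in range(min(max_len, len(tokens) - i), 0, -1):
            key = tuple(surfaces[i : i + width])
            cls = model.surfaces.get(key)
            if cls is not None:
                tags[i] = f"B-{cls}"
                for j in range(i + 1, i + width):
                    tags[j] = f"I-{cls}"
                matched = width
                break
        i += matched or 1
    return TaggedSequence(doc_id=doc_id, tokens=list(tokens), tags=tags)
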