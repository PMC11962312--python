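"""Entity-level precision/recall/F1 with Wilson confidence intervals.

Metrics follow the default conventions of standard sequence-labeling
evaluation: predictions count as true positives only on exact span-and-class
match of whole chunks; chunk boundaries are read leniently, so an ``I-X``
following ``O`` (or a different class) opens a new chunk even though strict
IOB2 would forbid it.  Undefined ratios (0/0) are reported as 0.  95%
confidence intervals for precision and recall use the Wilson score method,
which behaves well for proportions near 0 and 1 — relevant here because
rare classes (e.g. smoking status) have small support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .corpus_io import ENTITY_CLASSES, TaggedSequence

Chunk = tuple[str, int, int]  # (class, start token, end token), half-open


def _split_tag(tag: str) -> tuple[str, str]:
    if tag == "O":
        return "O", ""
    prefix, _, cls = tag.partition("-")
    if prefix not in ("B", "I") or not cls:
        raise ValueError(f"unknown tag label {tag!r}")
    return prefix, cls


def extract_chunks(tags: Sequence[str]) -> set[Chunk]:
    """Chunks under lenient (default-mode) boundary reading.

    A chunk starts at ``B-X``, or at ``I-X`` when the previous token was
    ``O`` or a different class; it ends before ``O``, ``B-``, or a class
    change."""
    chunks: set[Chunk] = set()
    start = -1
    prev_prefix, prev_cls = "O", ""
    for i, tag in enumerate(tags):
        prefix, cls = _split_tag(tag)
        starts = prefix == "B" or (prefix == "I" and (prev_prefix == "O" or prev_cls != cls))
        ends = prev_prefix != "O" and (prefix == "O" or starts)
        if ends:
            chunks.add((prev_cls, start, i))
        if starts:
            start = i
        prev_prefix, prev_cls = prefix, cls
    if prev_prefix != "O":
        chunks.add((prev_cls, start, len(tags)))
    return chunks


def f1_harmonic(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R), 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def wilson_interval(successes: int, trials: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError(f"need 0 <= successes <= trials, got {successes}/{trials}")
    p = successes / trials
    z2 = z * z
    denom = 1 + z2 / trials
    center = (p + z2 / (2 * trials)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / trials + z2 / (4 * trials * trials))
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass(frozen=True)
class ClassMetrics:
    label: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_ci: tuple[float, float]
    recall_ci: tuple[float, float]
    support: int


@dataclass
class EvalReport:
    per_class: dict[str, ClassMetrics]
    micro: ClassMetrics
    parsed_responses: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cm in [*self.per_class.values(), self.micro]:
            rows.append(
                {
                    "class": cm.label,
                    "precision": cm.precision,
                    "precision_ci_low": cm.precision_ci[0],
                    "precision_ci_high": cm.precision_ci[1],
                    "recall": cm.recall,
                    "recall_ci_low": cm.recall_ci[0],
                    "recall_ci_high": cm.recall_ci[1],
                    "f1": cm.f1,
                    "support": cm.support,
                }
            )
        df = pd.DataFrame(rows)
        if self.parsed_responses is not None:
            df["parsed_responses"] = self.parsed_responses
        return df


def _safe_div(num: int, den: int) -> float:
    return num / den if den else 0.0


def _metrics(label: str, tp: int, fp: int, fn: int, z: float) -> ClassMetrics:
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    p_ci = wilson_interval(tp, tp + fp, z) if tp + fp else (0.0, 0.0)
    r_ci = wilson_interval(tp, tp + fn, z) if tp + fn else (0.0, 0.0)
    return ClassMetrics(
        label=label,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1_harmonic(precision, recall),
        precision_ci=p_ci,
        recall_ci=r_ci,
        support=tp + fn,
    )


def evaluate_tag_lists(
    pred: Sequence[Sequence[str]],
    gold: Sequence[Sequence[str]],
    classes: Sequence[str] = ENTITY_CLASSES,
    z: float = 1.96,
    parsed_responses: int | None = None,
) -> EvalReport:
    """Entity-level evaluation over parallel lists of tag sequences."""
    if len(pred) != len(gold):
        raise ValueError(f"{len(pred)} predicted vs {len(gold)} gold sequences")
    tp: dict[str, int] = {c: 0 for c in classes}
    fp: dict[str, int] = {c: 0 for c in classes}
    fn: dict[str, int] = {c: 0 for c in classes}
    for idx, (p_tags, g_tags) in enumerate(zip(pred, gold)):
        if len(p_tags) != len(g_tags):
            raise ValueError(f"token-count mismatch in sequence {idx}")
        p_chunks = extract_chunks(p_tags)
        g_chunks = extract_chunks(g_tags)
        for cls in classes:
            pc = {c for c in p_chunks if c[0] == cls}
            gc = {c for c in g_chunks if c[0] == cls}
            tp[cls] += len(pc & gc)
            fp[cls] += len(pc - gc)
            fn[cls] += len(gc - pc)
    per_class = {c: _metrics(c, tp[c], fp[c], fn[c], z) for c in classes}
    micro = _metrics(
        "micro", sum(tp.values()), sum(fp.values()), sum(fn.values()), z
    )
    return EvalReport(per_class=per_class, micro=micro, parsed_responses=parsed_responses)


def evaluate(
    pred: Sequence[TaggedSequence],
    gold: Sequence[TaggedSequence],
    classes: Sequence[str] = ENTITY_CLASSES,
    z: float = 1.96,
    parsed_responses: int | None = None,
) -> EvalReport:
    """Evaluate predicted against gold tagged sequences, paired by document id."""
    gold_by_id = {g.doc_id: g for g in gold}
    if len(gold_by_id) != len(gold):
        raise ValueError("duplicate document ids in gold")
    pred_tags, gold_tags = [], []
    for p in pred:
        g = gold_by_id.get(p.doc_id)
        if g is None:
            raise ValueError(f"no gold sequence for document {p.doc_id!r}")
        if len(p.tags) != len(g.tags):
            raise ValueError(f"token-count mismatch in document {p.doc_id!r}")
        pred_tags.append(p.tags)
        gold_tags.append(g.tags)
    return evaluate_tag_lists(pred_tags, gold_tags, classes, z, parsed_responses)


def interannotator_agreement(
    a: Sequence[TaggedSequence],
    b: Sequence[TaggedSequence],
    classes: Sequence[str] = ENTITY_CLASSES,
) -> dict[str, float]:
    """Pairwise agreement: per-class F1 of one annotator taking the other as
    reference.  Symmetric, since F1 is invariant under swapping FP and FN."""
    report = evaluate(a, b, classes)
    return {cls: cm.f1 for cls, cm in report.per_class.items()}
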