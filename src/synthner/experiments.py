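"""End-to-end experiment harnesses: learning curves and prompt comparison.

A learning curve draws weakly annotated training batches of increasing size
(at a fixed 2:1 medical-history:procedure mix), trains the downstream tagger
on each batch after holding out a 15% validation split, and evaluates on a
fixed held-out gold evaluation corpus (default 300 documents, half per
document type).  "Model comparison" across annotators of different quality is
realized with named noise profiles — seeded error-mode configurations whose
drop/spurious/garble rates emulate stronger and weaker annotators — since the
hosted models themselves are outside the toolkit.  Every harness is a pure
function of (config, seed): identical inputs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .alignment import AlignPolicy, build_training_set
from .annotation import (
    ENTITY_CLASSES,
    Annotator,
    NoiseConfig,
    NoisyGoldAnnotator,
    PromptSpec,
    batch_annotate,
)
from .corpus_io import tokenize
from .downstream import split_train_validation, tag, train_surface_tagger
from .evaluation import EvalReport, evaluate
from .synthgen import (
    GeneratorConfig,
    GoldDocument,
    generate_gold_corpus,
    gold_tagged_sequences,
)

#: noise presets emulating annotators of decreasing quality: a strong
#: fourth-generation-style annotator, a weaker chat annotator, and a small
#: local model that often fails to produce parseable output
DEFAULT_NOISE_PROFILES: dict[str, NoiseConfig] = {
    "strong": NoiseConfig(drop_prob=0.20, spurious_prob=0.5, boundary_shift_prob=0.05, garble_prob=0.0),
    "medium": NoiseConfig(drop_prob=0.40, spurious_prob=0.9, boundary_shift_prob=0.10, garble_prob=0.01),
    "weak_local": NoiseConfig(drop_prob=0.65, spurious_prob=1.2, boundary_shift_prob=0.15, garble_prob=0.09),
}

DEFAULT_SIZES: tuple[int, ...] = (250, 500, 750, 1000, 2000, 4000)


@dataclass(frozen=True)
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(n_documents=4100))
    noise_profiles: Mapping[str, NoiseConfig] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_PROFILES)
    )
    sizes: tuple[int, ...] = DEFAULT_SIZES
    batch_ratio: tuple[int, int] = (2, 1)  # history : procedure
    eval_n: int = 300  # evaluation corpus, half per doc type
    validation_fraction: float = 0.15
    min_frequency: int = 2  # dictionary denoising: prune surfaces seen fewer times
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        if min(self.batch_ratio) <= 0:
            raise ValueError("batch ratio components must be positive")


def _make_eval_corpus(cfg: ExperimentConfig) -> list[GoldDocument]:
    gen_cfg = replace(
        cfg.generator,
        n_documents=cfg.eval_n,
        history_fraction=0.5,
        seed=(cfg.seed * 7919 + 17) % 2**31,
        id_prefix="eval",
    )
    return generate_gold_corpus(gen_cfg)


def _draw_batch(
    corpus: Sequence[GoldDocument], size: int, ratio: tuple[int, int]
) -> list[GoldDocument]:
    """First ``size`` documents at the configured history:procedure mix,
    taken in corpus order (deterministic)."""
    n_hist = round(size * ratio[0] / (ratio[0] + ratio[1]))
    n_proc = size - n_hist
    hist = [gd for gd in corpus if gd.document.doc_type == "medical_history"]
    proc = [gd for gd in corpus if gd.document.doc_type == "procedure"]
    if n_hist > len(hist) or n_proc > len(proc):
        raise ValueError(
            f"batch of {size} at ratio {ratio} exceeds corpus "
            f"({len(hist)} history, {len(proc)} procedure)"
        )
    return hist[:n_hist] + proc[:n_proc]


def _annotate_and_train(
    batch: Sequence[GoldDocument],
    noise: NoiseConfig,
    validation_fraction: float,
    seed: int,
    min_frequency: int = 1,
):
    gold_by_doc = {gd.document.id: gd.mentions for gd in batch}
    annotator = NoisyGoldAnnotator(gold_by_doc, replace(noise, seed=seed))
    docs = [gd.document for gd in batch]
    responses, parsed = batch_annotate(docs, annotator, PromptSpec(style="zero_shot"))
    tagged, log = build_training_set(docs, responses, AlignPolicy())
    train, _validation = split_train_validation(tagged, validation_fraction, seed=seed)
    model = train_surface_tagger(train, min_frequency)
    return model, parsed, log


def run_learning_curve(
    cfg: ExperimentConfig,
    profile: str = "strong",
    classes: Sequence[str] = ENTITY_CLASSES,
) -> pd.DataFrame:
    """One row per (training size, class): precision/recall/F1 with Wilson CIs
    on the held-out gold evaluation corpus."""
    noise = cfg.noise_profiles[profile]
    corpus = generate_gold_corpus(cfg.generator)
    eval_corpus = _make_eval_corpus(cfg)
    eval_gold = gold_tagged_sequences(eval_corpus)
    eval_ids = {gd.document.id for gd in eval_corpus}

    rows = []
    for size in cfg.sizes:
        batch = _draw_batch(corpus, size, cfg.batch_ratio)
        assert not eval_ids & {gd.document.id for gd in batch}, "eval/train leakage"
        model, parsed, _log = _annotate_and_train(
            batch, noise, cfg.validation_fraction, seed=cfg.seed + size,
            min_frequency=cfg.min_frequency,
        )
        predicted = [
            tag(tokenize(gd.document.text, gd.document.id).tokens, model, gd.document.id)
            for gd in eval_corpus
        ]
        report = evaluate(predicted, eval_gold, classes, parsed_responses=parsed)
        for cls in classes:
            cm = report.per_class[cls]
            rows.append(
                {
                    "size": size,
                    "class": cls,
                    "precision": cm.precision,
                    "precision_ci_low": cm.precision_ci[0],
                    "precision_ci_high": cm.precision_ci[1],
                    "recall": cm.recall,
                    "recall_ci_low": cm.recall_ci[0],
                    "recall_ci_high": cm.recall_ci[1],
                    "f1": cm.f1,
                    "support": cm.support,
                    "parsed_responses": parsed,
                }
            )
    return pd.DataFrame(rows)


def run_prompt_comparison(
    corpus: Sequence[GoldDocument],
    specs: Mapping[str, PromptSpec],
    annotators: Mapping[str, Annotator],
    classes: Sequence[str] = ENTITY_CLASSES,
) -> tuple[pd.DataFrame, dict[str, EvalReport]]:
    """Annotate the gold corpus once per prompt style and score each against
    the gold annotations; one table block per style (class rows with
    precision/recall CIs, F1, and parsed-response counts)."""
    docs = [gd.document for gd in corpus]
    gold = gold_tagged_sequences(corpus)
    reports: dict[str, EvalReport] = {}
    rows = []
    for name, spec in specs.items():
        responses, parsed = batch_annotate(docs, annotators[name], spec)
        kept_docs = [d for d, r in zip(docs, responses) if r.parsed]
        kept_resps = [r for r in responses if r.parsed]
        tagged, _log = build_training_set(kept_docs, kept_resps)
        kept_ids = {t.doc_id for t in tagged}
        gold_kept = [g for g in gold if g.doc_id in kept_ids]
        report = evaluate(tagged, gold_kept, classes, parsed_responses=parsed)
        reports[name] = report
        for cls in classes:
            cm = report.per_class[cls]
            rows.append(
                {
                    "class": cls,
                    "prompt": name,
                    "precision": cm.precision,
                    "precision_ci_low": cm.precision_ci[0],
                    "precision_ci_high": cm.precision_ci[1],
                    "recall": cm.recall,
                    "recall_ci_low": cm.recall_ci[0],
                    "recall_ci_high": cm.recall_ci[1],
                    "f1": cm.f1,
                    "parsed_responses": parsed,
                }
            )
    return pd.DataFrame(rows), reports
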