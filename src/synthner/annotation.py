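"""Prompt rendering, the annotator contract, and annotation-response parsing.

The annotation contract mirrors how hosted chat models are used for weak
labeling: a prompt carries the task instructions and the document text, and
the model is asked to return a JSON object whose keys are the entity classes
(DRUG, PROCEDURE, DISEASE, SMOKING) and whose values are the surface strings
found in the text.  Span indices are never requested — chat models are
unreliable at producing them — so surfaces are mapped back to character spans
downstream (see :mod:`synthner.alignment`).

Four prompt styles are supported: a plain zero-shot instruction, the same
instruction translated to Estonian (with Estonian class keys RAVIM /
PROTSEDUUR / HAIGUS / SUITS), a variant carrying annotation-guideline
definitions per class, and a few-shot variant carrying five worked
input/output example pairs.

No live HTTP client lives here.  An annotator is any callable taking the
rendered prompt (and the document, for bookkeeping) and returning a raw
response string; the two shipped annotators are a deterministic gazetteer
lookup and a seeded noise model that corrupts gold annotations with the
error modes real models exhibit: dropped mentions, spurious mentions,
boundary shifts, and wholly unparseable responses.
"""

from __future__ import annotations

import json
import logging
import math
import random
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .corpus_io import ENTITY_CLASSES, Document, tokenize

logger = logging.getLogger(__name__)

PROMPT_STYLES = ("zero_shot", "estonian", "definitions", "few_shot")

#: Estonian-prompt class keys, in the same order as ENTITY_CLASSES
ESTONIAN_CLASS_NAMES: Mapping[str, str] = {
    "DRUG": "RAVIM",
    "PROCEDURE": "PROTSEDUUR",
    "DISEASE": "HAIGUS",
    "SMOKING": "SUITS",
}

_ZERO_SHOT = (
    "In the text below, give the list of:\n"
    "drug named entity, procedure named entity, disease named entity, "
    "smoking named entity.\n"
    "Words need to be in exactly the same format as in input text.\n"
    "Format the output in JSON with the following keys:\n"
    "DRUG for drug named entity,\n"
    "PROCEDURE for procedure named entity,\n"
    "DISEASE for disease named entity,\n"
    "SMOKING for smoking named entity.\n"
    "Text below:\n"
)

_ESTONIAN = (
    "Loetle järgnevas tekstis järgmiseid nimeolemeid:\n"
    "ravimite nimeolemid, protseduuride nimeolemid, haiguste nimeolemid, "
    "suitsetamiste nimeolemid.\n"
    "Sõnad päevad olema täpselt samal kujul kui sisendtekstis.\n"
    "Vorminda väljund JSON kujul järgnevate võtmetega:\n"
    "RAVIM ravimite nimeolemite jaoks,\n"
    "PROTSEDUUR protseduuride nimeolemite jaoks,\n"
    "HAIGUS haiguste nimeolemite jaoks,\n"
    "SUITS suitsetamiste nimeolemite jaoks.\n"
    "Tekst on järgmine:\n"
)

_DEFINITIONS_HEAD = (
    "In the text below, give the list of:\n"
    "drug named entity, procedure named entity, disease named entity, "
    "smoking named entity.\n"
    "Words need to be in exactly the same format as in input text.\n"
    "The annotation guidelines are the following:\n"
)

_DEFINITIONS_TAIL = (
    "Format the output in JSON with the following keys:\n"
    "DRUG for drug named entity,\n"
    "PROCEDURE for procedure named entity,\n"
    "DISEASE for disease named entity,\n"
    "SMOKING for smoking named entity.\n"
    "Text below:\n"
)

_FEW_SHOT_HEAD = (
    "In the text below, give the list of:\n"
    "drug named entity, procedure named entity, disease named entity, "
    "smoking named entity.\n"
    "Words need to be in exactly the same format as in input text.\n"
    "Format the output in JSON with the following keys:\n"
    "DRUG for drug named entity,\n"
    "PROCEDURE for procedure named entity,\n"
    "DISEASE for disease named entity,\n"
    "SMOKING for smoking named entity.\n"
    "Here are a few examples:\n"
)

DEFAULT_FEW_SHOT_N = 5


@dataclass(frozen=True)
class PromptSpec:
    """One of the four prompt styles plus its style-specific payload."""

    style: str = "zero_shot"
    class_names: tuple[str, ...] = ENTITY_CLASSES
    definitions: Mapping[str, str] | None = None
    examples: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.style not in PROMPT_STYLES:
            raise ValueError(f"unknown prompt style {self.style!r}")
        if self.style == "definitions" and not self.definitions:
            raise ValueError("definitions style requires per-class definitions")
        if self.style == "few_shot":
            if not self.examples:
                raise ValueError("few_shot style requires example pairs")
            if len(self.examples) != DEFAULT_FEW_SHOT_N:
                raise ValueError(
                    f"few_shot style expects {DEFAULT_FEW_SHOT_N} example pairs, "
                    f"got {len(self.examples)}"
                )

    @property
    def response_keys(self) -> tuple[str, ...]:
        if self.style == "estonian":
            return tuple(ESTONIAN_CLASS_NAMES[c] for c in self.class_names)
        return self.class_names


def render_prompt(spec: PromptSpec, text: str) -> str:
    """Render the prompt for ``spec`` with the payload text appended after the
    "Text below:" (or "Tekst on järgmine:") marker.  Pure function."""
    if spec.style == "zero_shot":
        return _ZERO_SHOT + text
    if spec.style == "estonian":
        return _ESTONIAN + text
    if spec.style == "definitions":
        assert spec.definitions is not None
        guidelines = "".join(
            f"{cls} - {spec.definitions[cls]}\n"
            for cls in spec.class_names
            if cls in spec.definitions
        )
        return _DEFINITIONS_HEAD + guidelines + _DEFINITIONS_TAIL + text
    assert spec.style == "few_shot" and spec.examples is not None
    shots = "".join(f"{inp}\n{out}\n" for inp, out in spec.examples)
    return _FEW_SHOT_HEAD + shots + "Text below:\n" + text


@dataclass
class AnnotationResponse:
    """Parsed annotator output: class -> reported surface strings."""

    doc_id: str
    entities: dict[str, list[str]]
    parsed: bool
    raw: str

    def __post_init__(self) -> None:
        if not self.parsed and self.entities:
            raise ValueError("unparsed response must carry no entities")


def _first_json_object(raw: str) -> dict | None:
    """First balanced-brace candidate scanned left to right that parses as a
    JSON object; None if there is none."""
    depth = 0
    start = -1
    in_str = False
    escape = False
    for i, ch in enumerate(raw):
        if in_str:
            if escape:
                escape = False
            elif ch == "\\":
                escape = True
            elif ch == '"':
                in_str = False
            continue
        if ch == '"':
            in_str = True
        elif ch == "{":
            if depth == 0:
                start = i
            depth += 1
        elif ch == "}":
            if depth > 0:
                depth -= 1
                if depth == 0:
                    try:
                        obj = json.loads(raw[start : i + 1])
                    except json.JSONDecodeError:
                        continue
                    if isinstance(obj, dict):
                        return obj
    return None


def parse_response(
    raw: str,
    class_set: Sequence[str] = ENTITY_CLASSES,
    doc_id: str = "",
    key_aliases: Mapping[str, str] | None = None,
) -> AnnotationResponse:
    """Extract the first well-formed JSON object from ``raw``.

    ``parsed`` is true iff extraction succeeds and at least one configured
    class key (or alias, e.g. the Estonian key set) is present.  Unknown keys
    are ignored with a warning; scalar string values become one-element lists.
    Parsing never raises — failure is encoded as ``parsed=False``.
    """
    aliases = dict(key_aliases or {})
    obj = _first_json_object(raw)
    if obj is None:
        return AnnotationResponse(doc_id=doc_id, entities={}, parsed=False, raw=raw)
    entities: dict[str, list[str]] = {cls: [] for cls in class_set}
    hit = False
    for key, value in obj.items():
        cls = key if key in class_set else aliases.get(key)
        if cls is None:
            logger.warning("ignoring unknown annotation key %r (doc %s)", key, doc_id)
            continue
        hit = True
        if isinstance(value, str):
            entities[cls].extend([value])
        elif isinstance(value, list):
            entities[cls].extend(str(v) for v in value)
        elif value is not None:
            entities[cls].append(str(value))
    if not hit:
        return AnnotationResponse(doc_id=doc_id, entities={}, parsed=False, raw=raw)
    return AnnotationResponse(doc_id=doc_id, entities=entities, parsed=True, raw=raw)


@dataclass(frozen=True)
class NoiseConfig:
    """Error-mode rates for the simulated annotator.

    drop_prob: probability each gold mention is omitted;
    spurious_prob: expected spurious mentions per document (Poisson rate);
    boundary_shift_prob: probability a reported surface is truncated or
    extended by one token; garble_prob: probability the whole response is
    unparseable.
    """

    drop_prob: float = 0.0
    spurious_prob: float = 0.0
    boundary_shift_prob: float = 0.0
    garble_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drop_prob", "boundary_shift_prob", "garble_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spurious_prob < 0:
            raise ValueError(f"spurious_prob must be >= 0, got {self.spurious_prob}")


def _doc_rng(cfg_seed: int, doc_id: str) -> random.Random:
    # stable per-document stream independent of corpus order
    return random.Random((cfg_seed << 32) ^ zlib.crc32(doc_id.encode("utf-8")))


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    # Knuth's method; rates here are O(1) per document
    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def gazetteer_annotate(
    doc: Document, gazetteer: Mapping[str, set[str] | frozenset[str] | list[str]]
) -> AnnotationResponse:
    """Deterministic lookup annotator: report every gazetteer surface whose
    token sequence occurs (whole-token match) in the document, once per class."""
    if not gazetteer:
        raise ValueError("gazetteer must be non-empty")
    doc_toks = tokenize(doc.text, doc.id).surfaces()
    joined = "\x00".join(doc_toks)
    entities: dict[str, list[str]] = {}
    for cls in ENTITY_CLASSES:
        found: list[str] = []
        for surface in sorted(gazetteer.get(cls, ())):
            surf_toks = tokenize(surface).surfaces()
            if not surf_toks:
                continue
            needle = "\x00".join(surf_toks)
            if needle == joined or f"\x00{needle}\x00" in f"\x00{joined}\x00":
                found.append(surface)
        entities[cls] = found
    raw = json.dumps(entities, ensure_ascii=False)
    return AnnotationResponse(doc_id=doc.id, entities=entities, parsed=True, raw=raw)


def perturb_annotations(
    gold: Sequence["EntityMention"],  # noqa: F821 - alignment imports this module
    cfg: NoiseConfig,
    doc: Document,
) -> AnnotationResponse:
    """Corrupt gold mentions per ``cfg``; seeded and reproducible per document."""
    rng = _doc_rng(cfg.seed, doc.id)
    if rng.random() < cfg.garble_prob:
        return AnnotationResponse(
            doc_id=doc.id,
            entities={},
            parsed=False,
            raw="I'm sorry, I cannot annotate this text.",
        )
    doc_toks = tokenize(doc.text, doc.id).tokens
    entities: dict[str, list[str]] = {cls: [] for cls in ENTITY_CLASSES}
    for mention in gold:
        if rng.random() < cfg.drop_prob:
            continue
        surface = mention.surface
        if rng.random() < cfg.boundary_shift_prob:
            first, last = mention.token_span[0], mention.token_span[1] - 1
            if rng.random() < 0.5 and last > first:  # truncate one token
                surface = doc.text[doc_toks[first].start : doc_toks[last - 1].end]
            elif last + 1 < len(doc_toks):  # extend one token
                surface = doc.text[doc_toks[first].start : doc_toks[last + 1].end]
        entities[mention.label].append(surface)
    n_spurious = _poisson(rng, cfg.spurious_prob)
    for _ in range(n_spurious):
        if not doc_toks:
            break
        width = rng.randint(1, min(3, len(doc_toks)))
        start = rng.randrange(0, len(doc_toks) - width + 1)
        surface = doc.text[doc_toks[start].start : doc_toks[start + width - 1].end]
        entities[rng.choice(ENTITY_CLASSES)].append(surface)
    raw = json.dumps(entities, ensure_ascii=False)
    return AnnotationResponse(doc_id=doc.id, entities=entities, parsed=True, raw=raw)


class GazetteerAnnotator:
    """Annotator wrapping :func:`gazetteer_annotate`."""

    def __init__(self, gazetteer: Mapping[str, set[str] | list[str]]):
        self.gazetteer = gazetteer

    def __call__(self, prompt: str, doc: Document) -> str:
        return gazetteer_annotate(doc, self.gazetteer).raw


class NoisyGoldAnnotator:
    """Annotator that perturbs known gold mentions with a noise profile."""

    def __init__(self, gold_by_doc: Mapping[str, Sequence["EntityMention"]], cfg: NoiseConfig):  # noqa: F821
        self.gold_by_doc = gold_by_doc
        self.cfg = cfg

    def __call__(self, prompt: str, doc: Document) -> str:
        resp = perturb_annotations(self.gold_by_doc.get(doc.id, ()), self.cfg, doc)
        return resp.raw


Annotator = Callable[[str, Document], str]


def batch_annotate(
    corpus: Sequence[Document],
    annotator: Annotator,
    spec: PromptSpec,
) -> tuple[list[AnnotationResponse], int]:
    """Annotate every document; a failing annotator yields parsed=False for
    that document and processing continues.  Returns responses in corpus
    order plus the parsed count."""
    aliases = (
        {v: k for k, v in ESTONIAN_CLASS_NAMES.items()}
        if spec.style == "estonian"
        else None
    )
    responses: list[AnnotationResponse] = []
    for doc in corpus:
        prompt = render_prompt(spec, doc.text)
        try:
            raw = annotator(prompt, doc)
        except Exception:  # annotator failure is data, not a crash
            logger.exception("annotator failed on document %s", doc.id)
            raw = ""
        responses.append(
            parse_response(raw, spec.class_names, doc_id=doc.id, key_aliases=aliases)
        )
    parsed_count = sum(r.parsed for r in responses)
    return responses, parsed_count
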