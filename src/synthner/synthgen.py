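"""Synthetic clinical-style corpora with generation-time gold annotations.

The generator stands in for a language model fine-tuned on private Estonian
health records: it emits short documents of two types (medical histories and
procedure notes), each carrying the metadata header used to condition
generation — document type, one of 13 age bands spanning 15–80, gender, and
an ICD-10 diagnosis code (default C50, breast cancer).  Texts are assembled
from sentence templates with typed slots filled from small invented
pseudo-Estonian vocabularies for the four entity classes.  Gold mentions are
recorded at insertion time with their exact character offsets, never
recovered by string search afterwards, so alignment code can be tested
against ground truth that is independent of it.

Default per-document mention rates mirror the class mix of an expert-
annotated 500-document evaluation set (procedures most frequent at ~1.29 per
document, then diseases ~0.64, drugs ~0.44, smoking rarest at ~0.12), with
per-class counts Poisson-distributed around those means.

Two disjoint template banks ("primary" and "alternate", sharing no
non-punctuation tokens) support leakage experiments in which genuinely fresh
documents must not collide with a training pool.  :func:`make_training_pool`
builds such pools: verbatim and token-mutated copies of a corpus subset,
plus optional fresh filler documents, with provenance records for
ground-truth evaluation of the originality filter.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .alignment import EntityMention
from .corpus_io import ENTITY_CLASSES, Document, tokenize

# ---------------------------------------------------------------------------
# default vocabularies: invented surface forms; every non-punctuation token
# occurs in exactly one surface of exactly one class, and in no template.

DEFAULT_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "DRUG": (
        "Metforaliin",
        "Kardipress",
        "Venlaxor",
        "Dolpasan",
        "Tromboveen",
        "Letrosan",
        "Oxaliplat",
        "Femarex",
        "Zoledriin",
        "Paclitaxan",
        "Doxorubal",
        "Tamoxifeen",
        "Anastrosool",
        "Kapetsitab",
        "Epirubitsiin",
        "Trastuzumax forte",
        "Fulvestrant depoo",
        "Ondansetroon",
    ),
    "PROCEDURE": (
        "mammograafia",
        "ehhokardiograafia",
        "kompuutertomograafia",
        "magnetresonantstomograafia",
        "stsintigraafia",
        "gastroskoopia",
        "koloskoopia",
        "spiromeetria",
        "densitomeetria",
        "rindkere röntgenogramm",
        "lümfisõlmede eemaldusoperatsioon",
        "kiiritusravi kuur",
        "punktsioonibiopsia",
        "sentinel-uuring",
        "vaagnapiirkonna ultraheliuuring",
    ),
    "DISEASE": (
        "rinnakartsinoom",
        "hüpertooniatõbi",
        "osteoporoos",
        "kilpnäärmepuudulikkus",
        "metastaasikolle",
        "südamepuudulikkus",
        "aneemiasündroom",
        "refluksitõbi",
        "artroosivaevused",
        "lümfödeem",
        "polüneuropaatia",
        "depressioonihäire",
    ),
    "SMOKING": (
        "suitsetab",
        "mittesuitsetaja",
        "endine suitsetaja",
        "igapäevasuitsetaja",
        "juhusuitsetaja",
        "tubakatarvitaja",
    ),
}

#: mean gold mentions per document per class (class mix: procedures most
#: frequent, smoking rarest)
DEFAULT_MENTION_MEANS: dict[str, float] = {
    "DRUG": 0.44,
    "PROCEDURE": 1.29,
    "DISEASE": 0.64,
    "SMOKING": 0.12,
}

#: 13 five-year age bands spanning 15–80
DEFAULT_AGE_BANDS: tuple[str, ...] = tuple(f"{lo}-{lo + 5}" for lo in range(15, 80, 5))

DEFAULT_GENDERS: tuple[str, ...] = ("F", "M")

DEFAULT_DIAGNOSIS_CODES: tuple[str, ...] = ("C50",)


@dataclass(frozen=True)
class TemplateBank:
    """Per-doc-type sentence templates: slot-free fillers and one-slot
    sentences per entity class (slot marked ``{}``)."""

    fillers: Mapping[str, tuple[str, ...]]  # doc_type -> sentences
    slotted: Mapping[str, Mapping[str, tuple[str, ...]]]  # doc_type -> class -> templates


PRIMARY_TEMPLATES = TemplateBank(
    fillers={
        "medical_history": (
            "Üldseisund püsib stabiilne.",
            "Kaebusi hetkel olulisel määral pole.",
            "Kontroll kolme kuu pärast.",
        ),
        "procedure": (
            "Protseduur kulges tüsistusteta.",
            "Patsient talus sekkumist rahuldavalt.",
            "Järelkontroll lepiti kokku.",
        ),
    },
    slotted={
        "medical_history": {
            "DRUG": (
                "Raviskeemis jätkub {} tavaannuses.",
                "Alustatud {} manustamist väikeses doosis.",
            ),
            "PROCEDURE": (
                "Anamneesis teostatud {} plaanilises korras.",
                "Varem tehtud {} tulemus korrektne.",
            ),
            "DISEASE": (
                "Anamneesis esineb {} pikema aja vältel.",
                "Kaasuvaks diagnoosiks on {}.",
            ),
            "SMOKING": (
                "Elustiili osas dokumenteeritud {} varasemalt.",
                "Harjumuste kohta märgitud: {}.",
            ),
        },
        "procedure": {
            "DRUG": (
                "Premedikatsiooniks manustati {} vahetult enne sekkumist.",
                "Lokaalselt kasutati {} vajadusel.",
            ),
            "PROCEDURE": (
                "Teostati {} vastavalt saatekirjale.",
                "Planeeriti täiendav {} lähinädalatel.",
            ),
            "DISEASE": (
                "Näidustuseks oli {} progresseerumine.",
                "Leid sobib diagnoosiga {}.",
            ),
            "SMOKING": (
                "Riskiteguriks märgitud {} küsitlusel.",
                "Registreeritud staatus: {}.",
            ),
        },
    },
)

#: disjoint from PRIMARY_TEMPLATES in every non-punctuation token; used to
#: build documents guaranteed to share no templates with a training pool
ALTERNATE_TEMPLATES = TemplateBank(
    fillers={
        "medical_history": (
            "Laboratoorsed näitajad referentsvahemikus.",
            "Enesetunne kirjeldatud heana.",
            "Perearstile saadetud epikriis.",
        ),
        "procedure": (
            "Sekkumisjärgne periood möödus probleemideta.",
            "Koju lubatud samal õhtul.",
        ),
    },
    slotted={
        "medical_history": {
            "DRUG": (
                "Igapäevaselt tarvitab {} hommikuti.",
                "Retseptile lisatud {} pikaajaliselt.",
            ),
            "PROCEDURE": (
                "Saatekiri väljastatud uuringu {} teostamiseks.",
                "Eelnevalt läbitud {} näitas normleidu.",
            ),
            "DISEASE": (
                "Põhiprobleemiks kujunes {} viimastel kuudel.",
                "Varasemalt diagnoositud {} ravil.",
            ),
            "SMOKING": (
                "Küsitluses selgus {} aastaid.",
                "Tervisekäitumises fikseeritud: {}.",
            ),
        },
        "procedure": {
            "DRUG": ("Valutustamiseks kasutatud {} ühekordselt.",),
            "PROCEDURE": ("Läbi viidud {} üldnarkoosis.",),
            "DISEASE": ("Sekkumise aluseks {} kahtlus.",),
            "SMOKING": ("Ankeedis toodud {} teave.",),
        },
    },
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_documents: int = 500
    history_fraction: float = 2 / 3
    vocabularies: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_VOCABULARIES)
    )
    mention_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MENTION_MEANS)
    )
    templates: TemplateBank = PRIMARY_TEMPLATES
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS
    genders: tuple[str, ...] = DEFAULT_GENDERS
    diagnosis_codes: tuple[str, ...] = DEFAULT_DIAGNOSIS_CODES
    seed: int = 0
    id_prefix: str = "synth"

    def __post_init__(self) -> None:
        if not 0.0 <= self.history_fraction <= 1.0:
            raise ValueError("history_fraction must be in [0, 1]")
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        for cls, mean in self.mention_means.items():
            if mean > 0 and not self.vocabularies.get(cls):
                raise ValueError(f"class {cls} has positive mention rate but empty vocabulary")


@dataclass
class GoldDocument:
    """A document paired with its generation-time gold mentions."""

    document: Document
    mentions: list[EntityMention]

    def __post_init__(self) -> None:
        text = self.document.text
        for m in self.mentions:
            if text[m.char_span[0] : m.char_span[1]] != m.surface:
                raise ValueError(
                    f"gold mention {m.surface!r} does not match text at {m.char_span}"
                )
        spans = sorted(m.char_span for m in self.mentions)
        for a, b in zip(spans, spans[1:]):
            if b[0] < a[1]:
                raise ValueError(f"overlapping gold mentions at {a} and {b}")


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    import math

    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _token_span(text: str, char_span: tuple[int, int]) -> tuple[int, int]:
    toks = tokenize(text).tokens
    covered = [i for i, t in enumerate(toks) if t.start < char_span[1] and t.end > char_span[0]]
    return (covered[0], covered[-1] + 1)


def generate_gold_corpus(cfg: GeneratorConfig) -> list[GoldDocument]:
    """Seeded, reproducible generation of ``cfg.n_documents`` gold-annotated
    documents; the first ``round(n * history_fraction)`` are medical
    histories, the rest procedure notes."""
    rng = random.Random(cfg.seed)
    n_history = round(cfg.n_documents * cfg.history_fraction)
    docs: list[GoldDocument] = []
    for idx in range(cfg.n_documents):
        doc_type = "medical_history" if idx < n_history else "procedure"
        doc_id = f"{cfg.id_prefix}-{idx:05d}"
        # sampled mentions: per-class Poisson counts, surfaces drawn without
        # replacement within the document
        planned: list[tuple[str, str]] = []
        for cls in ENTITY_CLASSES:
            mean = cfg.mention_means.get(cls, 0.0)
            vocab = list(cfg.vocabularies.get(cls, ()))
            count = min(_poisson(rng, mean), len(vocab))
            planned.extend((cls, surface) for surface in rng.sample(vocab, count))
        rng.shuffle(planned)

        fillers = cfg.templates.fillers[doc_type]
        sentences: list[tuple[str, str | None, str | None]] = []  # (template, class, surface)
        sentences.append((rng.choice(fillers), None, None))
        for cls, surface in planned:
            tpl = rng.choice(cfg.templates.slotted[doc_type][cls])
            sentences.append((tpl, cls, surface))
        sentences.append((rng.choice(fillers), None, None))

        parts: list[str] = []
        cursor = 0
        raw_mentions: list[tuple[str, str, int]] = []  # (class, surface, char start)
        for tpl, cls, surface in sentences:
            if cls is None:
                rendered = tpl
            else:
                assert surface is not None
                prefix, _, _suffix = tpl.partition("{}")
                raw_mentions.append((cls, surface, cursor + len(prefix)))
                rendered = tpl.replace("{}", surface)
            parts.append(rendered)
            cursor += len(rendered) + 1  # +1 for the joining space
        text = " ".join(parts)

        document = Document(
            id=doc_id,
            text=text,
            doc_type=doc_type,
            age_group=rng.choice(cfg.age_bands),
            gender=rng.choice(cfg.genders),
            diagnosis_code=rng.choice(cfg.diagnosis_codes),
        )
        mentions = [
            EntityMention(
                doc_id=doc_id,
                label=cls,
                surface=surface,
                char_span=(start, start + len(surface)),
                token_span=_token_span(text, (start, start + len(surface))),
            )
            for cls, surface, start in raw_mentions
        ]
        docs.append(GoldDocument(document=document, mentions=sorted(mentions, key=lambda m: m.char_span)))
    return docs


@dataclass(frozen=True)
class PoolProvenance:
    pool_id: str
    source_id: str | None  # None for fresh documents
    mutation_rate: float


def make_training_pool(
    corpus: Sequence[GoldDocument],
    copy_fraction: float,
    mutation_rate: float,
    seed: int,
    n_fresh: int = 0,
    fresh_cfg: GeneratorConfig | None = None,
) -> tuple[list[Document], list[PoolProvenance]]:
    """Build a training pool: token-mutated copies of ``copy_fraction`` of the
    corpus, plus ``n_fresh`` fresh documents (generated from ``fresh_cfg``,
    default the alternate template bank so they share no templates).

    Mutated tokens are replaced with substitution tokens disjoint from every
    vocabulary and template, so ``mutation_rate=1`` destroys all overlap.
    Provenance records map each pool document to its source (or None)."""
    if not 0.0 <= copy_fraction <= 1.0:
        raise ValueError("copy_fraction must be in [0, 1]")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = random.Random(seed)
    pool: list[Document] = []
    provenance: list[PoolProvenance] = []

    n_copies = round(copy_fraction * len(corpus))
    chosen = rng.sample(range(len(corpus)), n_copies)
    sub_counter = 0
    for idx in sorted(chosen):
        src = corpus[idx].document
        toks = tokenize(src.text).surfaces()
        mutated: list[str] = []
        for t in toks:
            if rng.random() < mutation_rate:
                mutated.append(f"qsub{seed % 1000}x{sub_counter}")
                sub_counter += 1
            else:
                mutated.append(t)
        pool_id = f"pool-copy-{src.id}"
        pool.append(replace(src, id=pool_id, text=" ".join(mutated)))
        provenance.append(PoolProvenance(pool_id, src.id, mutation_rate))

    if n_fresh > 0:
        cfg = fresh_cfg or GeneratorConfig(
            n_documents=n_fresh,
            templates=ALTERNATE_TEMPLATES,
            seed=rng.randrange(2**31),
            id_prefix="pool-fresh",
        )
        for gd in generate_gold_corpus(cfg):
            pool.append(gd.document)
            provenance.append(PoolProvenance(gd.document.id, None, 0.0))

    return pool, provenance


def gold_tagged_sequences(corpus: Sequence[GoldDocument]):
    """Gold IOB2 sequences for a generated corpus (convenience for
    evaluation against ground truth)."""
    from .alignment import spans_to_tags

    return [
        spans_to_tags(tokenize(gd.document.text, gd.document.id), gd.mentions)
        for gd in corpus
    ]


def gold_gazetteer(cfg: GeneratorConfig) -> dict[str, list[str]]:
    """The generator's own vocabularies as a gazetteer (a perfect-knowledge
    annotator for end-to-end tests)."""
    return {cls: list(v) for cls, v in cfg.vocabularies.items()}
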