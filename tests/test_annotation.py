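import json

import pytest

from synthner.alignment import EntityMention
from synthner.annotation import (
    AnnotationResponse,
    GazetteerAnnotator,
    NoiseConfig,
    NoisyGoldAnnotator,
    PromptSpec,
    batch_annotate,
    gazetteer_annotate,
    parse_response,
    perturb_annotations,
    render_prompt,
)
from synthner.cli import DEFAULT_DEFINITIONS, DEFAULT_FEW_SHOT_EXAMPLES
from synthner.corpus_io import Document


def test_zero_shot_prompt_anchors():
    out = render_prompt(PromptSpec(style="zero_shot"), "payload")
    assert out.startswith("In the text below, give the list of:")
    assert "DRUG for drug named entity" in out
    assert "Words need to be in exactly the same format as in input text." in out
    assert out.endswith("Text below:\npayload")


def test_estonian_prompt_anchors():
    out = render_prompt(PromptSpec(style="estonian"), "payload")
    assert out.startswith("Loetle järgnevas tekstis")
    assert "RAVIM ravimite nimeolemite jaoks" in out
    assert out.endswith("Tekst on järgmine:\npayload")


def test_definitions_prompt_contains_guidelines():
    spec = PromptSpec(style="definitions", definitions=DEFAULT_DEFINITIONS)
    out = render_prompt(spec, "payload")
    assert "The annotation guidelines are the following:" in out
    assert "DRUG - any names or active ingredients" in out
    assert out.endswith("Text below:\npayload")


def test_few_shot_prompt_contains_all_examples_in_order():
    spec = PromptSpec(style="few_shot", examples=DEFAULT_FEW_SHOT_EXAMPLES)
    out = render_prompt(spec, "payload")
    pos = -1
    for inp, expected in DEFAULT_FEW_SHOT_EXAMPLES:
        assert out.index(inp) > pos
        pos = out.index(inp)
        assert out.index(expected) > pos
        pos = out.index(expected)
    assert pos < out.rindex("Text below:")


def test_render_prompt_is_pure():
    spec = PromptSpec(style="zero_shot")
    assert render_prompt(spec, "x") == render_prompt(spec, "x")


def test_prompt_spec_requires_style_payloads():
    with pytest.raises(ValueError):
        PromptSpec(style="definitions")
    with pytest.raises(ValueError):
        PromptSpec(style="few_shot", examples=(("a", "b"),))


@pytest.mark.parametrize(
    "raw,parsed,n_drugs",
    [
        ('{"DRUG":["Metforal"],"PROCEDURE":[],"DISEASE":[],"SMOKING":[]}', True, 1),
        ('Here you go: {"DRUG": ["Metforal"]} hope it helps', True, 1),
        ("I cannot help with that request.", False, 0),
        ("", False, 0),
        ('{"DRUG": "Metforal"}', True, 1),  # scalar coerced to list
        ('{"unrelated": 1} then {"DRUG": ["Metforal"]}', False, 0),  # first object wins
    ],
)
def test_parse_response_cases(raw, parsed, n_drugs):
    resp = parse_response(raw, doc_id="d")
    assert resp.parsed is parsed
    assert len(resp.entities.get("DRUG", [])) == n_drugs
    if not parsed:
        assert resp.entities == {}


def test_parse_response_round_trips_entity_mapping():
    entities = {"DRUG": ["Metforal"], "PROCEDURE": ["mammograafia", "biopsia"],
                "DISEASE": [], "SMOKING": []}
    resp = parse_response(json.dumps(entities))
    assert resp.entities == entities


def test_parse_response_accepts_estonian_aliases():
    aliases = {"RAVIM": "DRUG", "SUITS": "SMOKING"}
    resp = parse_response('{"RAVIM": ["Metforal"]}', key_aliases=aliases)
    assert resp.parsed and resp.entities["DRUG"] == ["Metforal"]


def test_unparsed_response_must_be_empty():
    with pytest.raises(ValueError):
        AnnotationResponse(doc_id="d", entities={"DRUG": ["x"]}, parsed=False, raw="")


DOC = Document(id="d1", text="Patsient võttis Metforal õhtuti .")


def test_gazetteer_annotate_finds_whole_token_matches():
    resp = gazetteer_annotate(DOC, {"DRUG": {"Metforal"}, "DISEASE": {"Metfo"}})
    assert resp.parsed
    assert resp.entities["DRUG"] == ["Metforal"]
    assert resp.entities["DISEASE"] == []  # substring of a token is not a match


def test_gazetteer_surface_in_two_classes_reported_under_both():
    resp = gazetteer_annotate(DOC, {"DRUG": {"Metforal"}, "DISEASE": {"Metforal"}})
    assert resp.entities["DRUG"] == ["Metforal"]
    assert resp.entities["DISEASE"] == ["Metforal"]


def test_gazetteer_requires_entries():
    with pytest.raises(ValueError):
        gazetteer_annotate(DOC, {})


def _gold_mention(surface="Metforal", label="DRUG", doc=DOC):
    start = doc.text.index(surface)
    return EntityMention(
        doc_id=doc.id, label=label, surface=surface,
        char_span=(start, start + len(surface)), token_span=(2, 3),
    )


def test_perturb_zero_noise_is_identity():
    gold = [_gold_mention()]
    resp = perturb_annotations(gold, NoiseConfig(seed=4), DOC)
    assert resp.parsed
    assert resp.entities["DRUG"] == ["Metforal"]
    assert all(resp.entities[c] == [] for c in ("PROCEDURE", "DISEASE", "SMOKING"))


def test_perturb_drop_one_empties_everything():
    resp = perturb_annotations([_gold_mention()], NoiseConfig(drop_prob=1.0, seed=4), DOC)
    assert resp.parsed and all(v == [] for v in resp.entities.values())


def test_perturb_garble_one_is_unparseable():
    resp = perturb_annotations([_gold_mention()], NoiseConfig(garble_prob=1.0, seed=4), DOC)
    assert not resp.parsed and resp.entities == {}


def test_perturb_is_reproducible_and_order_independent():
    gold = [_gold_mention()]
    cfg = NoiseConfig(drop_prob=0.5, spurious_prob=0.7, seed=9)
    a = perturb_annotations(gold, cfg, DOC)
    b = perturb_annotations(gold, cfg, DOC)
    assert a.entities == b.entities and a.raw == b.raw


def test_perturb_drop_rate_recovered():
    """Over many mentions, the retained fraction concentrates at 1 - drop_prob."""
    docs = [Document(id=f"d{i}", text="Patsient võttis Metforal õhtuti .") for i in range(1200)]
    cfg = NoiseConfig(drop_prob=0.3, seed=11)
    kept = sum(
        len(perturb_annotations([_gold_mention(doc=d)], cfg, d).entities["DRUG"])
        for d in docs
    )
    n, p = 1200, 0.7
    sd = (n * p * (1 - p)) ** 0.5
    assert abs(kept - n * p) <= 3 * sd


def test_noise_config_validation():
    with pytest.raises(ValueError):
        NoiseConfig(drop_prob=1.5)
    with pytest.raises(ValueError):
        NoiseConfig(spurious_prob=-0.1)


def test_batch_annotate_counts_and_continues_on_failure():
    docs = [Document(id=f"d{i}", text="Metforal siin .") for i in range(4)]

    calls = {"n": 0}

    def flaky(prompt, doc):
        calls["n"] += 1
        if doc.id == "d2":
            raise RuntimeError("boom")
        return '{"DRUG": ["Metforal"]}'

    responses, parsed = batch_annotate(docs, flaky, PromptSpec())
    assert [r.doc_id for r in responses] == ["d0", "d1", "d2", "d3"]
    assert parsed == 3
    assert not responses[2].parsed
    assert calls["n"] == 4


def test_batch_annotate_gazetteer_parses_everything():
    docs = [Document(id=f"d{i}", text="Metforal siin .") for i in range(10)]
    annot = GazetteerAnnotator({"DRUG": {"Metforal"}})
    _responses, parsed = batch_annotate(docs, annot, PromptSpec())
    assert parsed == 10


def test_batch_annotate_garble_count_is_reproducible():
    docs = [Document(id=f"d{i}", text="Metforal siin .") for i in range(300)]
    gold = {d.id: [_gold_mention(doc=d)] for d in docs}
    annot = NoisyGoldAnnotator(gold, NoiseConfig(garble_prob=0.1, seed=21))
    _r1, parsed1 = batch_annotate(docs, annot, PromptSpec())
    _r2, parsed2 = batch_annotate(docs, annot, PromptSpec())
    assert parsed1 == parsed2
    assert 0 < parsed1 < 300
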