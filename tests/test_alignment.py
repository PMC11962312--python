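import random

import pytest
from hypothesis import given, settings, strategies as st

from synthner.alignment import (
    AlignPolicy,
    EntityMention,
    build_training_set,
    map_entities_to_spans,
    resolve_overlaps,
    spans_to_tags,
)
from synthner.annotation import AnnotationResponse
from synthner.corpus_io import Document, tokenize
from synthner.evaluation import extract_chunks


def _resp(doc_id, entities, parsed=True):
    return AnnotationResponse(doc_id=doc_id, entities=entities if parsed else {}, parsed=parsed, raw="")


def test_map_single_surface_to_span():
    doc = Document(id="d", text="võttis Metforal 500mg")
    mentions, dropped = map_entities_to_spans(doc, _resp("d", {"DRUG": ["Metforal"]}))
    assert dropped == []
    (m,) = mentions
    assert m.char_span == (7, 15)
    assert doc.text[7:15] == "Metforal"
    assert m.token_span == (1, 2)


def test_map_missing_surface_dropped_with_reason():
    doc = Document(id="d", text="võttis Metforal")
    mentions, dropped = map_entities_to_spans(doc, _resp("d", {"DRUG": ["Aspirin"]}))
    assert mentions == []
    assert dropped == [("DRUG", "Aspirin", "not_found")]


def test_map_annotates_every_occurrence():
    doc = Document(id="d", text="Metforal enne , Metforal hiljem")
    mentions, _ = map_entities_to_spans(doc, _resp("d", {"DRUG": ["Metforal"]}))
    assert [m.char_span for m in mentions] == [(0, 8), (16, 24)]


def test_map_first_occurrence_only_policy():
    doc = Document(id="d", text="Metforal enne , Metforal hiljem")
    mentions, _ = map_entities_to_spans(
        doc, _resp("d", {"DRUG": ["Metforal"]}), AlignPolicy(all_occurrences=False)
    )
    assert [m.char_span for m in mentions] == [(0, 8)]


def test_map_is_case_insensitive_by_default_and_switchable():
    doc = Document(id="d", text="võttis METFORAL õhtul")
    mentions, _ = map_entities_to_spans(doc, _resp("d", {"DRUG": ["Metforal"]}))
    assert [m.surface for m in mentions] == ["METFORAL"]  # text form, never invented
    _, dropped = map_entities_to_spans(
        doc, _resp("d", {"DRUG": ["Metforal"]}), AlignPolicy(case_insensitive=False)
    )
    assert dropped == [("DRUG", "Metforal", "not_found")]


def test_map_normalizes_whitespace_in_surfaces():
    doc = Document(id="d", text="tehti rindkere röntgen täna")
    mentions, _ = map_entities_to_spans(doc, _resp("d", {"PROCEDURE": ["rindkere  röntgen"]}))
    assert [m.surface for m in mentions] == ["rindkere röntgen"]


def test_map_requires_whole_token_boundaries():
    doc = Document(id="d", text="Metforaliga ravi")  # inflected form, not a token match
    _, dropped = map_entities_to_spans(doc, _resp("d", {"DRUG": ["Metforal"]}))
    assert dropped == [("DRUG", "Metforal", "not_found")]


def test_map_rejects_unparsed_response():
    doc = Document(id="d", text="tekst")
    with pytest.raises(ValueError):
        map_entities_to_spans(doc, _resp("d", {}, parsed=False))


def _mention(label, start, end, doc_id="d"):
    return EntityMention(doc_id=doc_id, label=label, surface="x" * (end - start),
                         char_span=(start, end), token_span=(start, end))


def test_resolve_containment_keeps_longer():
    kept = resolve_overlaps([_mention("DRUG", 0, 10), _mention("DRUG", 3, 6)])
    assert [m.char_span for m in kept] == [(0, 10)]


def test_resolve_identical_span_uses_class_priority():
    kept = resolve_overlaps([_mention("DISEASE", 2, 5), _mention("DRUG", 2, 5)])
    assert [m.label for m in kept] == ["DRUG"]


def test_resolve_disjoint_keeps_both():
    kept = resolve_overlaps([_mention("DRUG", 0, 3), _mention("DISEASE", 5, 8)])
    assert len(kept) == 2


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["DRUG", "PROCEDURE", "DISEASE", "SMOKING"]),
            st.integers(0, 30),
            st.integers(1, 8),
        ),
        max_size=15,
    )
)
@settings(max_examples=200, derandomize=True)
def test_resolve_output_pairwise_non_overlapping(raw):
    mentions = [_mention(lbl, s, s + w) for lbl, s, w in raw]
    kept = resolve_overlaps(mentions)
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            assert a.char_span[1] <= b.char_span[0] or b.char_span[1] <= a.char_span[0]


def test_spans_to_tags_basic():
    doc = Document(id="d", text="enne rindkere röntgen hiljem")
    tt = tokenize(doc.text, "d")
    m = EntityMention("d", "PROCEDURE", "rindkere röntgen", (5, 21), (1, 3))
    seq = spans_to_tags(tt, [m])
    assert seq.tags == ["O", "B-PROCEDURE", "I-PROCEDURE", "O"]


def test_spans_to_tags_no_mentions_all_outside():
    tt = tokenize("lihtsalt tavaline tekst", "d")
    assert spans_to_tags(tt, []).tags == ["O", "O", "O"]


def test_spans_to_tags_partial_token_claims_whole_token():
    tt = tokenize("enne Metforal hiljem", "d")
    m = EntityMention("d", "DRUG", "Metfo", (5, 10), (1, 2))  # span ends mid-token
    assert spans_to_tags(tt, [m]).tags == ["O", "B-DRUG", "O"]


def test_spans_to_tags_rejects_overlaps():
    tt = tokenize("a b c d", "d")
    with pytest.raises(ValueError):
        spans_to_tags(tt, [_mention("DRUG", 0, 3), _mention("DISEASE", 2, 5)])


def test_build_training_set_round_trips_mention_token_spans():
    doc = Document(id="d", text="võttis Metforal , tehti mammograafia")
    resp = _resp("d", {"DRUG": ["Metforal"], "PROCEDURE": ["mammograafia"]})
    tagged, log = build_training_set([doc], [resp])
    assert log.skipped_unparsed == 0 and log.dropped == []
    chunks = extract_chunks(tagged[0].tags)
    assert chunks == {("DRUG", 1, 2), ("PROCEDURE", 4, 5)}


def test_build_training_set_skips_unparsed_and_logs():
    docs = [Document(id="a", text="tekst üks"), Document(id="b", text="tekst kaks")]
    resps = [_resp("a", {}, parsed=False), _resp("b", {}, parsed=False)]
    tagged, log = build_training_set(docs, resps)
    assert tagged == [] and log.skipped_unparsed == 2


def test_build_training_set_logs_not_found():
    docs = [Document(id="a", text="tekst üks")]
    resps = [_resp("a", {"DRUG": ["Puudub"]})]
    tagged, log = build_training_set(docs, resps)
    assert len(tagged) == 1
    assert log.dropped_by_reason()["not_found"] == 1


def test_build_training_set_rejects_id_mismatch():
    docs = [Document(id="a", text="tekst")]
    with pytest.raises(ValueError, match="mismatch"):
        build_training_set(docs, [_resp("b", {"DRUG": []})])
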