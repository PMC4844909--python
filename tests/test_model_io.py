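"""Data-model invariants and Open-Annotation-style JSON round-tripping."""

from __future__ import annotations

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pddikit import (
    AnnotationSet,
    DrugMention,
    DrugReference,
    PDDIMention,
    ValidationError,
    load_corpus,
    read_annotations,
    write_annotations,
    write_corpus,
)
from pddikit.io import annotation_set_from_json, annotation_set_to_json

from .conftest import make_section


def drug(sid, start, end, surface, etype="active_ingredient", cid="ING01", nid=None):
    return DrugMention(
        section_id=sid,
        char_start=start,
        char_end=end,
        surface=surface,
        entity_type=etype,
        concept_id=cid,
        normalized_ingredient_id=nid or cid,
    )


def pddi(sid, sentences, precip="ING01", obj="ING02", statement="qualitative",
         modality="positive"):
    return PDDIMention(
        section_id=sid,
        sentence_indices=frozenset(sentences),
        precipitant=DrugReference(precip, "active_ingredient"),
        object=DrugReference(obj, "active_ingredient"),
        statement=statement,
        modality=modality,
    )


class TestInvariants:
    def test_precipitant_object_must_differ(self):
        with pytest.raises(ValidationError, match="share normalized id"):
            pddi("s1", {0}, precip="ING01", obj="ING01").validate()

    def test_surface_must_equal_text_slice(self, tiny_corpus):
        bad = drug("s1", 0, 4, "XXXX")
        with pytest.raises(ValidationError, match="surface"):
            bad.validate(tiny_corpus.sections["s1"])

    def test_duplicate_pddi_mentions_rejected(self, tiny_corpus):
        aset = AnnotationSet("x", "human", pddi_mentions=[pddi("s1", {0}), pddi("s1", {0})])
        with pytest.raises(ValidationError, match="duplicate"):
            aset.validate(tiny_corpus)

    def test_sentence_indices_validated_against_section(self, tiny_corpus):
        aset = AnnotationSet("x", "human", pddi_mentions=[pddi("s1", {7})])
        with pytest.raises(ValidationError, match="out of range"):
            aset.validate(tiny_corpus)

    def test_noncontiguous_multi_sentence_selection_allowed(self, tiny_corpus):
        AnnotationSet("x", "human", pddi_mentions=[pddi("s1", {0, 1})]).validate(
            tiny_corpus
        )


class TestCorpusLoading:
    def _write(self, tmp_path, records, texts):
        for name, text in texts.items():
            (tmp_path / name).write_text(text)
        manifest = tmp_path / "manifest.json"
        manifest.write_text(json.dumps({"sections": records}))
        return manifest

    def test_loads_sections_with_scenarios(self, tmp_path):
        records = [
            {"section_id": f"s{i}", "label_id": f"l{i}", "path": f"s{i}.txt",
             "scenario": "1"}
            for i in range(3)
        ]
        texts = {f"s{i}.txt": f"Section {i} text. More text." for i in range(3)}
        corpus = load_corpus(self._write(tmp_path, records, texts))
        assert len(corpus) == 3
        assert corpus.sections["s1"].sentence_spans
        assert corpus.scenario_counts() == {"1": 3}

    def test_duplicate_section_id_names_offender(self, tmp_path):
        records = [
            {"section_id": "s1", "path": "a.txt", "scenario": "1"},
            {"section_id": "s1", "path": "b.txt", "scenario": "2"},
        ]
        texts = {"a.txt": "A.", "b.txt": "B."}
        with pytest.raises(ValidationError, match="s1"):
            load_corpus(self._write(tmp_path, records, texts))

    def test_missing_file_names_section(self, tmp_path):
        records = [{"section_id": "s9", "path": "gone.txt", "scenario": "1"}]
        with pytest.raises(ValidationError, match="s9"):
            load_corpus(self._write(tmp_path, records, {}))

    def test_corpus_roundtrip_preserves_segmentation(self, tmp_path, small_study):
        manifest = write_corpus(small_study.corpus, tmp_path / "c")
        reloaded = load_corpus(manifest)
        assert len(reloaded) == len(small_study.corpus)
        for sid, sec in small_study.corpus.sections.items():
            assert reloaded.sections[sid].sentence_spans == sec.sentence_spans
        assert sum(reloaded.scenario_counts().values()) == len(reloaded)


class TestAnnotationJSON:
    def test_empty_set_serializes_with_zero_annotations(self, tmp_path, tiny_corpus):
        path = tmp_path / "empty.json"
        write_annotations(AnnotationSet("empty", "human"), path, tiny_corpus)
        doc = json.loads(path.read_text())
        assert doc["annotations"] == []
        assert read_annotations(path, tiny_corpus) == AnnotationSet("empty", "human")

    def test_pddi_body_carries_model_fields(self, tiny_corpus):
        aset = AnnotationSet("x", "human", pddi_mentions=[pddi("s1", {0})])
        doc = annotation_set_to_json(aset, tiny_corpus)
        body = doc["annotations"][0]["body"]
        assert set(body) >= {"precipitant", "object", "statement", "modality"}

    def test_quote_mismatch_error_names_annotation(self, tiny_corpus):
        aset = AnnotationSet("x", "human", pddi_mentions=[pddi("s1", {0})])
        doc = annotation_set_to_json(aset, tiny_corpus)
        doc["annotations"][0]["target"]["selectors"][0]["exact"] = "WRONG QUOTE"
        with pytest.raises(ValidationError, match="x-1"):
            annotation_set_from_json(doc, tiny_corpus)

    def test_unknown_body_keys_pass_through(self, tiny_corpus):
        aset = AnnotationSet("x", "human", pddi_mentions=[pddi("s1", {0})])
        doc = annotation_set_to_json(aset, tiny_corpus)
        doc["annotations"][0]["body"]["curator_note"] = "check me"
        back = annotation_set_from_json(doc, tiny_corpus)
        assert back.pddi_mentions[0].extra == {"curator_note": "check me"}
        # and survives a further round trip
        again = annotation_set_from_json(
            annotation_set_to_json(back, tiny_corpus), tiny_corpus
        )
        assert again == back

    def test_minimal_handwritten_document(self, tiny_corpus):
        doc = {
            "source_id": "manual",
            "source_kind": "human",
            "annotations": [
                {
                    "id": "m1",
                    "type": "drug_mention",
                    "target": {
                        "section_id": "s1",
                        "selector": {"char_start": 0, "char_end": 12},
                    },
                    "body": {
                        "entity_type": "active_ingredient",
                        "concept_id": "ING01",
                        "normalized_ingredient_id": "ING01",
                    },
                }
            ],
        }
        aset = annotation_set_from_json(doc, tiny_corpus)
        assert len(aset.drug_mentions) == 1
        assert aset.drug_mentions[0].surface == "Ketoconazole"

    def test_50_mention_roundtrip(self, tmp_path, small_study):
        ref = small_study.reference
        subset = AnnotationSet(
            "ref50",
            "reference",
            drug_mentions=ref.drug_mentions[:25],
            pddi_mentions=ref.pddi_mentions[:25],
        )
        path = tmp_path / "ref50.json"
        write_annotations(subset, path, small_study.corpus)
        assert read_annotations(path, small_study.corpus) == subset


# -- property: read(write(x)) == x over generated sets ----------------------

_SECTION = make_section(
    "p1",
    "Alpha interacts with beta. Gamma is excreted renally. Delta was studied.",
)
_CORPUS_SECTIONS = {"p1": _SECTION}

_ids = st.sampled_from(["ING01", "ING02", "ING03", "ING04"])


@st.composite
def _pddi_mentions(draw):
    n_sent = len(_SECTION.sentence_spans)
    precip = draw(_ids)
    obj = draw(_ids.filter(lambda x: True))
    if obj == precip:
        obj = "ING99"
    return PDDIMention(
        section_id="p1",
        sentence_indices=frozenset(
            draw(st.sets(st.integers(0, n_sent - 1), min_size=1, max_size=n_sent))
        ),
        precipitant=DrugReference(precip, "active_ingredient"),
        object=DrugReference(obj, "active_ingredient"),
        statement=draw(st.sampled_from(["quantitative", "qualitative"])),
        modality=draw(st.sampled_from(["positive", "negative"])),
    )


@given(st.lists(_pddi_mentions(), max_size=8))
@settings(max_examples=80, deadline=None)
def test_roundtrip_identity_property(mentions):
    from pddikit.model import Corpus

    corpus = Corpus(sections=_CORPUS_SECTIONS, scenario_assignment={"p1": "1"})
    unique = {m.key(): m for m in mentions}
    aset = AnnotationSet("prop", "human", pddi_mentions=list(unique.values()))
    doc = annotation_set_to_json(aset, corpus)
    assert annotation_set_from_json(doc, corpus) == aset
    # every serialized quote equals the corpus slice at its sentence
    for ann in doc["annotations"]:
        for sel in ann["target"]["selectors"]:
            assert sel["exact"] == _SECTION.sentence_text(sel["sentence_index"])
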