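"""Rule-based PDDI extraction: cue gating, modality, statement, role frames."""

from __future__ import annotations

import json

import pytest

from pddikit import (
    GeneratorConfig,
    RuleConfig,
    annotate_drug_mentions,
    extract_pddi_mentions,
    generate_corpus,
    match_sets,
    run_pipeline,
)
from pddikit.io import annotation_set_to_json
from pddikit.synth import with_overrides

from .conftest import make_section


def extract(text, lexicon, config=None):
    sec = make_section("s1", text)
    drugs = annotate_drug_mentions(sec, lexicon)
    return extract_pddi_mentions(sec, drugs, config)


class TestSingleSentenceRules:
    def test_quantitative_positive_active_frame(self, tiny_lexicon):
        _, mentions = extract(
            "Ketoconazole increased midazolam AUC by 5-fold.", tiny_lexicon
        )
        (m,) = mentions
        assert m.precipitant.normalized_ingredient_id == "ING01"
        assert m.object.normalized_ingredient_id == "ING02"
        assert m.statement == "quantitative"
        assert m.modality == "positive"
        assert m.sentence_indices == {0}

    def test_no_effect_is_negative_qualitative(self, tiny_lexicon):
        _, mentions = extract(
            "Coadministration of ketoconazole had no effect on the "
            "pharmacokinetics of midazolam.",
            tiny_lexicon,
        )
        (m,) = mentions
        assert m.modality == "negative"
        assert m.statement == "qualitative"
        # no causative frame: fallback makes the first drug the precipitant
        assert m.precipitant.normalized_ingredient_id == "ING01"

    def test_passive_frame_flips_roles(self, tiny_lexicon):
        _, mentions = extract(
            "The AUC of midazolam was increased by ketoconazole.", tiny_lexicon
        )
        (m,) = mentions
        assert m.precipitant.normalized_ingredient_id == "ING01"
        assert m.object.normalized_ingredient_id == "ING02"

    def test_single_drug_sentence_emits_nothing(self, tiny_lexicon):
        cls, mentions = extract(
            "Ketoconazole increased the AUC substantially.", tiny_lexicon
        )
        assert mentions == []
        assert not cls[0].is_pddi

    def test_two_drugs_without_cue_emit_nothing(self, tiny_lexicon):
        _, mentions = extract(
            "Both ketoconazole and midazolam are widely prescribed.",
            tiny_lexicon,
        )
        assert mentions == []

    def test_modality_present_iff_pddi(self, tiny_lexicon):
        cls, _ = extract(
            "Warfarin is taken daily. Ketoconazole increased midazolam AUC.",
            tiny_lexicon,
        )
        assert [c.is_pddi for c in cls] == [False, True]
        assert cls[0].modality is None
        assert cls[1].modality == "positive"

    def test_product_mention_normalizes_for_pairing(self, tiny_lexicon):
        # warfarin sodium (product) normalizes to warfarin's ingredient id,
        # so the pair is (ketoconazole, warfarin-ingredient)
        _, mentions = extract(
            "Ketoconazole increased warfarin sodium exposure and AUC.",
            tiny_lexicon,
        )
        (m,) = mentions
        assert {
            m.precipitant.normalized_ingredient_id,
            m.object.normalized_ingredient_id,
        } == {"ING01", "ING03"}


def test_two_sentence_window_joins_cross_sentence_pairs(tiny_lexicon):
    text = (
        "Ketoconazole inhibits hepatic metabolism. "
        "Midazolam AUC was higher in the interaction study."
    )
    _, narrow = extract(text, tiny_lexicon, RuleConfig(window_size=1))
    assert narrow == []
    _, wide = extract(text, tiny_lexicon, RuleConfig(window_size=2))
    (m,) = wide
    assert m.sentence_indices == {0, 1}


def test_every_mention_window_contains_both_drugs(small_study):
    nlp = run_pipeline(small_study.corpus, small_study.lexicon)
    by_section = {}
    for d in nlp.drug_mentions:
        by_section.setdefault(d.section_id, []).append(d)
    for m in nlp.pddi_mentions:
        sec = small_study.corpus.sections[m.section_id]
        ids_in_window = {
            d.normalized_ingredient_id
            for d in by_section[m.section_id]
            if sec.sentence_of_offset(d.char_start) in m.sentence_indices
        }
        assert {
            m.precipitant.normalized_ingredient_id,
            m.object.normalized_ingredient_id,
        } <= ids_in_window


def test_pipeline_deterministic_byte_identical(small_study):
    a = run_pipeline(small_study.corpus, small_study.lexicon)
    b = run_pipeline(small_study.corpus, small_study.lexicon)
    ja = json.dumps(annotation_set_to_json(a, small_study.corpus), sort_keys=True)
    jb = json.dumps(annotation_set_to_json(b, small_study.corpus), sort_keys=True)
    assert ja == jb


def test_empty_corpus_yields_empty_set(tiny_lexicon):
    from pddikit.model import Corpus

    out = run_pipeline(Corpus(sections={}), tiny_lexicon)
    assert out.drug_mentions == [] and out.pddi_mentions == []


class TestPipelineOnSyntheticCorpus:
    def test_rule_perfect_corpus_recall_and_precision_one(self, small_study):
        nlp = run_pipeline(small_study.corpus, small_study.lexicon)
        res = match_sets(nlp, small_study.reference)
        assert res.candidate_fp == []
        assert res.reference_fn == []
        assert res.tp == len(small_study.reference.pddi_mentions) > 0

    def test_negative_modality_statements_extracted_as_negative(self):
        study = generate_corpus(
            GeneratorConfig(n_sections=12, p_negative_modality=0.5, seed=9)
        )
        planted_neg = [
            m for m in study.reference.pddi_mentions if m.modality == "negative"
        ]
        assert planted_neg
        nlp = run_pipeline(study.corpus, study.lexicon)
        extracted = {m.key() for m in nlp.pddi_mentions}
        assert all(m.key() in extracted for m in planted_neg)

    def test_recall_and_precision_degrade_monotonically_with_noise(self):
        base = GeneratorConfig(n_sections=40, seed=17)
        recalls, precisions = [], []
        for noise in (0.0, 0.25, 0.5):
            cfg = with_overrides(
                base, paraphrase_noise=noise, cue_distractor_noise=noise
            )
            study = generate_corpus(cfg)
            nlp = run_pipeline(study.corpus, study.lexicon)
            res = match_sets(nlp, study.reference)
            n_ref = len(study.reference.pddi_mentions)
            n_cand = res.tp + len(res.candidate_fp)
            recalls.append(res.tp / n_ref)
            precisions.append(res.tp / n_cand)
        assert recalls[0] == 1.0 and precisions[0] == 1.0
        assert recalls[0] > recalls[1] > recalls[2]
        assert precisions[0] > precisions[1] > precisions[2]


def test_rule_config_yaml_roundtrip(tmp_path):
    path = tmp_path / "rules.yaml"
    path.write_text(
        "window_size: 2\ncue_stems: [auc, clearance]\n"
    )
    cfg = RuleConfig.from_yaml(path)
    assert cfg.window_size == 2
    assert cfg.cue_stems == ("auc", "clearance")
    with pytest.raises(ValueError):
        RuleConfig(window_size=3)
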