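"""Shared fixtures: a tiny hand-built lexicon/corpus and small synthetic studies."""

from __future__ import annotations

import pytest

from pddikit import (
    Corpus,
    GeneratorConfig,
    LabelSection,
    Lexicon,
    LexiconEntry,
    generate_corpus,
    segment_sentences,
)


def make_section(section_id: str, text: str, length_class: str = "short") -> LabelSection:
    return LabelSection(
        section_id=section_id,
        label_id=f"label-{section_id}",
        text=text,
        sentence_spans=tuple(segment_sentences(text)),
        length_class=length_class,
    )


@pytest.fixture
def tiny_lexicon() -> Lexicon:
    lex = Lexicon(
        entries=[
            LexiconEntry("ING01", "ketoconazole", "active_ingredient"),
            LexiconEntry("ING02", "midazolam", "active_ingredient", ("versed base",)),
            LexiconEntry("ING03", "warfarin", "active_ingredient"),
            LexiconEntry("PRD01", "warfarin sodium", "drug_product"),
            LexiconEntry("PRD02", "Zentrex", "drug_product"),
            LexiconEntry("MET01", "norketoconazole", "metabolite"),
            LexiconEntry("NON01", "aspirin", "non_drug"),
        ],
        product_to_ingredient={"PRD01": "ING03"},
    )
    lex.validate()
    return lex


@pytest.fixture
def tiny_corpus() -> Corpus:
    sections = {
        "s1": make_section(
            "s1",
            "Ketoconazole increased midazolam AUC by 5-fold. "
            "Warfarin is excreted in urine.",
        ),
        "s2": make_section(
            "s2",
            "Coadministration of ketoconazole had no effect on the "
            "pharmacokinetics of warfarin. Aspirin was given daily.",
        ),
    }
    corpus = Corpus(
        sections=sections, scenario_assignment={"s1": "1", "s2": "3"}
    )
    corpus.validate()
    return corpus


@pytest.fixture(scope="session")
def small_study():
    """Rule-perfect synthetic study: 30 sections, default composition."""
    return generate_corpus(GeneratorConfig(n_sections=30, seed=42))
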