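"""Rule-based sentence-level pharmacokinetic PDDI extraction.

This is a transparent, auditable stand-in for a learned PDDI classifier: a
sentence window is flagged as containing a pharmacokinetic PDDI iff at least
two distinct normalized drug ingredients co-occur with at least one
pharmacokinetic cue term.  Modality, statement type, and precipitant/object
roles are then assigned by small surface-pattern rules:

* modality is ``negative`` iff a negation cue ("no effect", "did not", ...)
  occurs in the window, else ``positive``;
* statement is ``quantitative`` iff the window carries a numeric magnitude
  (percent, fold-change, multiplier), else ``qualitative``;
* the precipitant is the drug before a causative verb in an active frame
  ("X increased ... Y"), the drug after "by" in a passive frame
  ("Y ... was increased by X"), and otherwise — logged fallback — the drug
  mentioned first in the window.

Cue, negation and causative-verb lists ship as editable TSV data files and
can be overridden through :class:`RuleConfig`.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path

import yaml

from .lexicon import Lexicon
from .model import (
    AnnotationSet,
    Corpus,
    DrugMention,
    LabelSection,
    PDDIMention,
)
from .ner import DictionaryMatcher

log = logging.getLogger(__name__)

_TOKEN_CHAR = r"[0-9A-Za-z-]"

#: numeric magnitudes: "45%", "30 percent", "5-fold", "2.5 fold", "3 times"
_QUANTITATIVE_RE = re.compile(
    r"\d+(?:\.\d+)?\s*(?:%|percent\b|times\b)|\d+(?:\.\d+)?[\s-]*fold\b",
    re.IGNORECASE,
)


def _read_term_tsv(name: str) -> tuple[str, ...]:
    text = resources.files("pddikit.data").joinpath(name).read_text()
    rows = [
        line.split("\t")[0].strip()
        for line in text.splitlines()[1:]
        if line.strip() and not line.startswith("#")
    ]
    return tuple(rows)


@dataclass(frozen=True)
class SentenceClassification:
    """Per-window verdict of the extractor (the table-of-sentence-spans view)."""

    section_id: str
    sentence_span: frozenset[int]
    is_pddi: bool
    modality: str | None = None


@dataclass(frozen=True)
class RuleConfig:
    """Tunable surface of the rule-based extractor.

    ``window_size`` is the number of consecutive sentences examined jointly
    (1 or 2); cue/negation/verb lists default to the packaged TSV files.
    ``fallback_policy`` currently supports only ``"first_drug"``.
    """

    window_size: int = 1
    cue_stems: tuple[str, ...] = field(
        default_factory=lambda: _read_term_tsv("pk_cues.tsv")
    )
    negation_phrases: tuple[str, ...] = field(
        default_factory=lambda: _read_term_tsv("negation_cues.tsv")
    )
    causative_stems: tuple[str, ...] = field(
        default_factory=lambda: _read_term_tsv("causative_verbs.tsv")
    )
    fallback_policy: str = "first_drug"

    def __post_init__(self) -> None:
        if self.window_size not in (1, 2):
            raise ValueError("window_size must be 1 or 2")
        if self.fallback_policy != "first_drug":
            raise ValueError(f"unknown fallback_policy {self.fallback_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = {}
        for key in ("window_size", "fallback_policy"):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("cue_stems", "negation_phrases", "causative_stems"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        return cls(**kwargs)

    def provenance(self) -> dict:
        return {
            "window_size": self.window_size,
            "cue_stems": list(self.cue_stems),
            "negation_phrases": list(self.negation_phrases),
            "causative_stems": list(self.causative_stems),
            "fallback_policy": self.fallback_policy,
        }

    @cached_property
    def _cue_re(self) -> re.Pattern:
        alts = "|".join(re.escape(s) for s in self.cue_stems)
        return re.compile(rf"(?<!{_TOKEN_CHAR})(?:{alts})[a-z]*", re.IGNORECASE)

    @cached_property
    def _negation_res(self) -> tuple[re.Pattern, ...]:
        return tuple(
            re.compile(rf"\b{re.escape(p)}\b", re.IGNORECASE)
            for p in self.negation_phrases
        )

    @cached_property
    def _verb_re(self) -> re.Pattern:
        alts = "|".join(re.escape(s) for s in self.causative_stems)
        return re.compile(rf"(?<!{_TOKEN_CHAR})(?:{alts})[a-z]*", re.IGNORECASE)

    @cached_property
    def _passive_re(self) -> re.Pattern:
        alts = "|".join(re.escape(s) for s in self.causative_stems)
        return re.compile(
            rf"\b(?:was|were|is|are)\b[^.;]*?(?:{alts})[a-z]*[^.;]*?\bby\b",
            re.IGNORECASE,
        )


def _assign_roles(
    window_text: str,
    window_offset: int,
    first_a: DrugMention,
    first_b: DrugMention,
    config: RuleConfig,
) -> tuple[DrugMention, DrugMention]:
    """Return (precipitant mention, object mention) for one drug pair.

    Offsets of the mentions are absolute; ``window_offset`` is the absolute
    offset of ``window_text``.
    """
    # passive frame: "<object> ... was <verb> ... by <precipitant>"
    m = config._passive_re.search(window_text)
    if m is not None:
        by_end = window_offset + m.end()
        a_after = first_a.char_start >= by_end
        b_after = first_b.char_start >= by_end
        if a_after != b_after:
            return (first_a, first_b) if a_after else (first_b, first_a)
    # active frame: "<precipitant> <verb> ... <object>"
    early, late = sorted((first_a, first_b), key=lambda d: d.char_start)
    for v in config._verb_re.finditer(window_text):
        v_start = window_offset + v.start()
        v_end = window_offset + v.end()
        if early.char_end <= v_start and late.char_start >= v_end:
            return early, late
    log.debug(
        "role fallback (first drug = precipitant) for pair %s/%s in window %r",
        first_a.normalized_ingredient_id,
        first_b.normalized_ingredient_id,
        window_text[:60],
    )
    return early, late


def extract_pddi_mentions(
    section: LabelSection,
    drugs: list[DrugMention],
    config: RuleConfig | None = None,
) -> tuple[list[SentenceClassification], list[PDDIMention]]:
    """Classify sentence windows and emit one PDDI mention per drug pair.

    A window is PDDI-positive iff it contains mentions of at least two
    distinct normalized ingredients and at least one pharmacokinetic cue.
    Emitted mentions anchor to the sentences actually containing the pair's
    first mentions (so single-sentence windows anchor to that sentence).
    """
    if config is None:
        config = RuleConfig()
    n_sent = len(section.sentence_spans)
    by_sentence: dict[int, list[DrugMention]] = {i: [] for i in range(n_sent)}
    for d in drugs:
        idx = section.sentence_of_offset(d.char_start)
        if idx is not None:
            by_sentence[idx].append(d)

    if n_sent == 0:
        return [], []
    w = min(config.window_size, n_sent)
    windows = [tuple(range(i, i + w)) for i in range(n_sent - w + 1)]

    classifications: list[SentenceClassification] = []
    mentions: list[PDDIMention] = []
    seen_keys: set[tuple] = set()
    for window in windows:
        start = section.sentence_spans[window[0]][0]
        end = section.sentence_spans[window[-1]][1]
        window_text = section.text[start:end]
        window_drugs = [d for i in window for d in by_sentence[i]]
        first_by_id: dict[str, DrugMention] = {}
        for d in window_drugs:
            first_by_id.setdefault(d.normalized_ingredient_id, d)
        has_pair = len(first_by_id) >= 2
        has_cue = config._cue_re.search(window_text) is not None
        is_pddi = has_pair and has_cue
        modality = None
        if is_pddi:
            negated = any(p.search(window_text) for p in config._negation_res)
            modality = "negative" if negated else "positive"
            statement = (
                "quantitative"
                if _QUANTITATIVE_RE.search(window_text)
                else "qualitative"
            )
            ids = sorted(first_by_id)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    a, b = first_by_id[ids[i]], first_by_id[ids[j]]
                    precip, obj = _assign_roles(
                        window_text, start, a, b, config
                    )
                    anchor = frozenset(
                        idx
                        for idx in (
                            section.sentence_of_offset(precip.char_start),
                            section.sentence_of_offset(obj.char_start),
                        )
                        if idx is not None
                    )
                    mention = PDDIMention(
                        section_id=section.section_id,
                        sentence_indices=anchor,
                        precipitant=precip.reference(),
                        object=obj.reference(),
                        statement=statement,
                        modality=modality,
                    )
                    if mention.key() not in seen_keys:
                        seen_keys.add(mention.key())
                        mentions.append(mention)
        classifications.append(
            SentenceClassification(
                section_id=section.section_id,
                sentence_span=frozenset(window),
                is_pddi=is_pddi,
                modality=modality,
            )
        )
    return classifications, mentions


def run_pipeline(
    corpus: Corpus,
    lexicon: Lexicon,
    config: RuleConfig | None = None,
    mode: str = "ner+pddi",
) -> AnnotationSet:
    """NER + PDDI extraction over every section; deterministic given inputs.

    ``mode`` mirrors the two assistance levels of a preannotation study:
    ``"ner"`` emits drug mentions only, ``"ner+pddi"`` adds PDDI mentions.
    """
    if mode not in ("ner", "ner+pddi"):
        raise ValueError(f"unknown mode {mode!r}")
    if config is None:
        config = RuleConfig()
    matcher = DictionaryMatcher(lexicon)
    out = AnnotationSet(
        source_id="nlp",
        source_kind="nlp",
        provenance={"mode": mode, "rules": config.provenance()},
    )
    for sid in sorted(corpus.sections):
        section = corpus.sections[sid]
        drugs = matcher.annotate(section)
        out.drug_mentions.extend(drugs)
        if mode == "ner+pddi":
            _, pddis = extract_pddi_mentions(section, drugs, config)
            out.pddi_mentions.extend(pddis)
    return out
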