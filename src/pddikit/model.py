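"""Core data model for pharmacokinetic drug-drug interaction (PDDI) annotation.

A corpus is a set of drug product label *sections*; every annotation source
(the reference standard, an NLP pipeline, or a human annotator) produces an
:class:`AnnotationSet` of typed drug mentions and PDDI mentions over those
sections.  A PDDI mention links a *precipitant* drug (the one perturbing an
enzyme or transporter) to an *object* drug (the one whose exposure changes),
and carries a statement type (quantitative vs qualitative) and a modality
(positive claim vs explicit denial of an interaction).

Character offsets are 0-based and half-open throughout.  PDDI mentions are
anchored to sentences by index into the section's canonical segmentation,
which is computed once when the corpus is loaded, so that sentence-overlap
comparisons between sources are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

ENTITY_TYPES = ("active_ingredient", "metabolite", "drug_product")
SOURCE_KINDS = ("reference", "nlp", "human")
STATEMENTS = ("quantitative", "qualitative")
MODALITIES = ("positive", "negative")
SCENARIOS = ("training", "1", "2", "3", "4")


class ValidationError(ValueError):
    """Raised when a model object violates one of its invariants."""


@dataclass(frozen=True)
class LabelSection:
    """One text section of a drug product label; the unit of annotation.

    ``sentence_spans`` are sorted, non-overlapping ``[start, end)`` character
    intervals; every non-whitespace character belongs to exactly one span
    (inter-sentence whitespace may be unassigned).  ``length_class`` is
    ``"short"`` or ``"long"`` relative to a corpus-level length threshold.
    """

    section_id: str
    label_id: str
    text: str
    sentence_spans: tuple[tuple[int, int], ...]
    length_class: str = "short"

    def validate(self) -> None:
        if self.length_class not in ("short", "long"):
            raise ValidationError(
                f"section {self.section_id}: bad length_class {self.length_class!r}"
            )
        prev_end = 0
        for start, end in self.sentence_spans:
            if not (0 <= start < end <= len(self.text)):
                raise ValidationError(
                    f"section {self.section_id}: sentence span ({start}, {end}) "
                    f"outside text of length {len(self.text)}"
                )
            if start < prev_end:
                raise ValidationError(
                    f"section {self.section_id}: overlapping/unsorted sentence "
                    f"span ({start}, {end})"
                )
            prev_end = end
        covered = [False] * len(self.text)
        for start, end in self.sentence_spans:
            for i in range(start, end):
                covered[i] = True
        for i, ch in enumerate(self.text):
            if not ch.isspace() and not covered[i]:
                raise ValidationError(
                    f"section {self.section_id}: character {i} ({ch!r}) not "
                    "covered by any sentence span"
                )

    def sentence_text(self, index: int) -> str:
        start, end = self.sentence_spans[index]
        return self.text[start:end]

    def sentence_of_offset(self, offset: int) -> int | None:
        """Index of the sentence containing character ``offset``, if any."""
        for i, (start, end) in enumerate(self.sentence_spans):
            if start <= offset < end:
                return i
        return None


@dataclass(frozen=True)
class DrugReference:
    """A normalized drug identity used inside a PDDI mention."""

    normalized_ingredient_id: str
    entity_type: str

    def validate(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValidationError(f"bad entity_type {self.entity_type!r}")


@dataclass(frozen=True)
class DrugMention:
    """A typed drug span inside a section.

    ``normalized_ingredient_id`` equals ``concept_id`` except for drug
    products with a known sole-active-ingredient mapping, where it is the
    ingredient's concept id.  ``unmapped_product`` flags products for which
    no such mapping exists.
    """

    section_id: str
    char_start: int
    char_end: int
    surface: str
    entity_type: str
    concept_id: str
    normalized_ingredient_id: str
    unmapped_product: bool = False
    extra: Mapping[str, Any] = field(default_factory=dict)

    def validate(self, section: LabelSection | None = None) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValidationError(
                f"drug mention {self.section_id}@{self.char_start}: "
                f"bad entity_type {self.entity_type!r}"
            )
        if not 0 <= self.char_start < self.char_end:
            raise ValidationError(
                f"drug mention {self.section_id}@{self.char_start}: bad offsets"
            )
        if section is not None:
            if self.char_end > len(section.text):
                raise ValidationError(
                    f"drug mention {self.section_id}@{self.char_start}: "
                    "offsets beyond section text"
                )
            slice_ = section.text[self.char_start : self.char_end]
            if slice_ != self.surface:
                raise ValidationError(
                    f"drug mention {self.section_id}@{self.char_start}: surface "
                    f"{self.surface!r} != text slice {slice_!r}"
                )

    def reference(self) -> DrugReference:
        return DrugReference(self.normalized_ingredient_id, self.entity_type)


@dataclass(frozen=True)
class PDDIMention:
    """A sentence-anchored claim that one drug alters the exposure of another.

    ``sentence_indices`` is a non-empty set of indices into the section's
    sentence segmentation; multi-sentence selections need not be contiguous.
    """

    section_id: str
    sentence_indices: frozenset[int]
    precipitant: DrugReference
    object: DrugReference
    statement: str
    modality: str
    extra: Mapping[str, Any] = field(default_factory=dict)

    def validate(self, section: LabelSection | None = None) -> None:
        if not self.sentence_indices:
            raise ValidationError(
                f"PDDI mention in {self.section_id}: empty sentence_indices"
            )
        if self.statement not in STATEMENTS:
            raise ValidationError(
                f"PDDI mention in {self.section_id}: bad statement "
                f"{self.statement!r}"
            )
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"PDDI mention in {self.section_id}: bad modality "
                f"{self.modality!r}"
            )
        self.precipitant.validate()
        self.object.validate()
        if (
            self.precipitant.normalized_ingredient_id
            == self.object.normalized_ingredient_id
        ):
            raise ValidationError(
                f"PDDI mention in {self.section_id}: precipitant and object "
                f"share normalized id {self.precipitant.normalized_ingredient_id!r}"
            )
        if section is not None:
            n = len(section.sentence_spans)
            bad = [i for i in self.sentence_indices if not 0 <= i < n]
            if bad:
                raise ValidationError(
                    f"PDDI mention in {self.section_id}: sentence indices "
                    f"{sorted(bad)} out of range (section has {n} sentences)"
                )

    def key(self) -> tuple:
        """Identity key used for the per-set uniqueness invariant."""
        return (
            self.section_id,
            self.precipitant.normalized_ingredient_id,
            self.object.normalized_ingredient_id,
            self.modality,
            self.statement,
            tuple(sorted(self.sentence_indices)),
        )

    def sort_key(self) -> tuple:
        """Deterministic processing order: first sentence, then precipitant."""
        return (
            self.section_id,
            min(self.sentence_indices),
            self.precipitant.normalized_ingredient_id,
            self.object.normalized_ingredient_id,
            self.modality,
            self.statement,
            tuple(sorted(self.sentence_indices)),
        )


@dataclass
class AnnotationSet:
    """All mentions produced by one source over a corpus."""

    source_id: str
    source_kind: str
    drug_mentions: list[DrugMention] = field(default_factory=list)
    pddi_mentions: list[PDDIMention] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def validate(self, corpus: "Corpus | None" = None) -> None:
        if self.source_kind not in SOURCE_KINDS:
            raise ValidationError(f"bad source_kind {self.source_kind!r}")
        seen: set[tuple] = set()
        for m in self.pddi_mentions:
            section = corpus.sections.get(m.section_id) if corpus else None
            if corpus is not None and section is None:
                raise ValidationError(
                    f"PDDI mention references unknown section {m.section_id!r}"
                )
            m.validate(section)
            k = m.key()
            if k in seen:
                raise ValidationError(f"duplicate PDDI mention {k}")
            seen.add(k)
        for d in self.drug_mentions:
            section = corpus.sections.get(d.section_id) if corpus else None
            if corpus is not None and section is None:
                raise ValidationError(
                    f"drug mention references unknown section {d.section_id!r}"
                )
            d.validate(section)

    def in_sections(self, section_ids: Iterable[str]) -> "AnnotationSet":
        """Restriction of this set to the given sections."""
        keep = set(section_ids)
        return AnnotationSet(
            source_id=self.source_id,
            source_kind=self.source_kind,
            drug_mentions=[d for d in self.drug_mentions if d.section_id in keep],
            pddi_mentions=[m for m in self.pddi_mentions if m.section_id in keep],
            provenance=dict(self.provenance),
        )


@dataclass
class Corpus:
    """A collection of label sections plus their scenario assignment."""

    sections: dict[str, LabelSection]
    scenario_assignment: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.scenario_assignment:
            if set(self.scenario_assignment) != set(self.sections):
                raise ValidationError(
                    "scenario_assignment keys do not match section ids"
                )
            bad = {
                s
                for s in self.scenario_assignment.values()
                if s not in SCENARIOS
            }
            if bad:
                raise ValidationError(f"unknown scenarios {sorted(bad)}")
        for sec in self.sections.values():
            sec.validate()

    def __len__(self) -> int:
        return len(self.sections)

    def scenario_sections(self, scenario: str) -> list[str]:
        return sorted(
            sid
            for sid, sc in self.scenario_assignment.items()
            if sc == str(scenario)
        )

    def scenario_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sc in self.scenario_assignment.values():
            counts[sc] = counts.get(sc, 0) + 1
        return counts


def length_threshold(lengths: Iterable[int]) -> float:
    """Default short/long cut: the median section length."""
    import statistics

    vals = list(lengths)
    if not vals:
        return 0.0
    return float(statistics.median(vals))


def classify_length(text_len: int, threshold: float) -> str:
    return "long" if text_len > threshold else "short"
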