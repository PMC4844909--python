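"""Dictionary-based drug named-entity recognition.

Case-insensitive, token-boundary-anchored, longest-leftmost matching of
lexicon surface forms (preferred names and synonyms) over section text,
followed by the two postprocessing steps the preannotation pipeline needs:
discarding matches typed ``non_drug`` (the entity-type filter) and mapping
sole-active-ingredient drug products to their ingredient's identifier.

Token characters are word characters plus internal hyphens, so "warfarin"
does not match inside "warfarin-treated" and hyphenated drug names match
whole.  After a match, scanning resumes at the match end, so output spans
never overlap and longest-leftmost resolution is total.
"""

from __future__ import annotations

import re

from .lexicon import Lexicon
from .model import DrugMention, LabelSection

_TOKEN_CHAR = r"[0-9A-Za-z-]"


def _compile_matcher(lexicon: Lexicon) -> tuple[re.Pattern, dict[str, object]]:
    """Alternation of all surface forms, longest first, with boundary guards."""
    surface_to_entry: dict[str, object] = {}
    for surface, entry in lexicon.surface_forms():
        key = surface.lower()
        # lexicon order wins on ambiguous surfaces
        surface_to_entry.setdefault(key, entry)
    ordered = sorted(surface_to_entry, key=lambda s: (-len(s), s))
    if not ordered:
        pattern = re.compile(r"(?!x)x")  # matches nothing
    else:
        alternation = "|".join(re.escape(s) for s in ordered)
        pattern = re.compile(
            rf"(?<!{_TOKEN_CHAR})(?:{alternation})(?!{_TOKEN_CHAR})",
            re.IGNORECASE,
        )
    return pattern, surface_to_entry


class DictionaryMatcher:
    """Reusable compiled matcher for one lexicon."""

    def __init__(self, lexicon: Lexicon):
        lexicon.validate()
        self.lexicon = lexicon
        self._pattern, self._surface_to_entry = _compile_matcher(lexicon)

    def annotate(self, section: LabelSection) -> list[DrugMention]:
        mentions: list[DrugMention] = []
        pos = 0
        text = section.text
        while True:
            m = self._pattern.search(text, pos)
            if m is None:
                break
            pos = m.end()
            entry = self._surface_to_entry[m.group(0).lower()]
            if entry.entity_type == "non_drug":
                continue  # the filter step: matched, then discarded
            normalized = entry.concept_id
            unmapped = False
            if entry.entity_type == "drug_product":
                mapped = self.lexicon.product_to_ingredient.get(entry.concept_id)
                if mapped is not None:
                    normalized = mapped
                else:
                    unmapped = True
            mentions.append(
                DrugMention(
                    section_id=section.section_id,
                    char_start=m.start(),
                    char_end=m.end(),
                    surface=m.group(0),
                    entity_type=entry.entity_type,
                    concept_id=entry.concept_id,
                    normalized_ingredient_id=normalized,
                    unmapped_product=unmapped,
                )
            )
        mentions.sort(key=lambda d: d.char_start)
        return mentions


def annotate_drug_mentions(section: LabelSection, lexicon: Lexicon) -> list[DrugMention]:
    """One-shot convenience wrapper around :class:`DictionaryMatcher`."""
    return DictionaryMatcher(lexicon).annotate(section)
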