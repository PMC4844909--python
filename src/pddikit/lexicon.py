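"""Drug lexicon: concepts, synonyms, and product-to-ingredient relations.

Emulates the terminology backbone of a dictionary NER step: a flat table of
concepts (active ingredients, metabolites, drug products, plus ``non_drug``
entries that the postprocessing filter discards) and a relation table mapping
sole-active-ingredient drug products to their ingredient, mirroring how
RxNorm-style relations are used to normalize product mentions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .model import ValidationError

LEXICON_TYPES = ("active_ingredient", "metabolite", "drug_product", "non_drug")


@dataclass(frozen=True)
class LexiconEntry:
    concept_id: str
    name: str
    entity_type: str
    synonyms: tuple[str, ...] = ()


@dataclass
class Lexicon:
    entries: list[LexiconEntry] = field(default_factory=list)
    product_to_ingredient: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        by_id: dict[str, LexiconEntry] = {}
        for e in self.entries:
            if e.entity_type not in LEXICON_TYPES:
                raise ValidationError(
                    f"lexicon entry {e.concept_id}: bad type {e.entity_type!r}"
                )
            if e.concept_id in by_id:
                raise ValidationError(f"duplicate concept_id {e.concept_id!r}")
            by_id[e.concept_id] = e
        for prod, ingr in self.product_to_ingredient.items():
            if prod not in by_id or by_id[prod].entity_type != "drug_product":
                raise ValidationError(
                    f"relation key {prod!r} is not a drug_product concept"
                )
            if ingr not in by_id or by_id[ingr].entity_type != "active_ingredient":
                raise ValidationError(
                    f"relation value {ingr!r} is not an active_ingredient concept"
                )

    def by_id(self) -> dict[str, LexiconEntry]:
        return {e.concept_id: e for e in self.entries}

    def surface_forms(self) -> list[tuple[str, LexiconEntry]]:
        """(surface, entry) pairs for preferred names and synonyms.

        Lexicon order breaks ties when two entries share a surface form.
        """
        pairs: list[tuple[str, LexiconEntry]] = []
        for e in self.entries:
            pairs.append((e.name, e))
            for s in e.synonyms:
                pairs.append((s, e))
        return pairs


def read_lexicon(lexicon_tsv: str | Path, relations_tsv: str | Path | None = None) -> Lexicon:
    """Load a lexicon from TSV (columns: concept_id, name, type, synonyms).

    Synonyms are pipe-separated.  ``relations_tsv`` (columns: product_id,
    ingredient_id) populates the sole-active-ingredient map.
    """
    entries: list[LexiconEntry] = []
    with open(lexicon_tsv, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        required = {"concept_id", "name", "type", "synonyms"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(
                f"lexicon TSV must have columns {sorted(required)}"
            )
        for row in reader:
            syns = tuple(s for s in (row["synonyms"] or "").split("|") if s)
            entries.append(
                LexiconEntry(
                    concept_id=row["concept_id"],
                    name=row["name"],
                    entity_type=row["type"],
                    synonyms=syns,
                )
            )
    relations: dict[str, str] = {}
    if relations_tsv is not None:
        with open(relations_tsv, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(
                (line for line in fh if not line.startswith("#")), delimiter="\t"
            )
            for row in reader:
                relations[row["product_id"]] = row["ingredient_id"]
    lex = Lexicon(entries=entries, product_to_ingredient=relations)
    lex.validate()
    return lex


def write_lexicon(lex: Lexicon, lexicon_tsv: str | Path, relations_tsv: str | Path) -> None:
    with open(lexicon_tsv, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["concept_id", "name", "type", "synonyms"])
        for e in lex.entries:
            w.writerow([e.concept_id, e.name, e.entity_type, "|".join(e.synonyms)])
    with open(relations_tsv, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["product_id", "ingredient_id"])
        for prod, ingr in sorted(lex.product_to_ingredient.items()):
            w.writerow([prod, ingr])
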