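"""Corpus and annotation I/O.

Corpora are stored as a JSON manifest plus one UTF-8 text file per section;
annotation sets as Open-Annotation-inspired JSON documents (target with
section id and position selectors carrying the exact quoted text; typed
body).  The schema ships at ``pddikit/data/annotation_schema.json``.

Sentence segmentation happens exactly once, here, at corpus load; every
downstream consumer shares the resulting sentence indices.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

from .model import (
    AnnotationSet,
    Corpus,
    DrugMention,
    DrugReference,
    LabelSection,
    PDDIMention,
    ValidationError,
    classify_length,
    length_threshold,
)
from .segment import segment_sentences

_DRUG_BODY_KEYS = {
    "entity_type",
    "concept_id",
    "normalized_ingredient_id",
    "unmapped_product",
}
_PDDI_BODY_KEYS = {"precipitant", "object", "statement", "modality"}


def load_corpus(manifest_path: str | Path) -> Corpus:
    """Load a corpus from a JSON manifest; fails atomically.

    The manifest lists sections as objects with ``section_id``, ``label_id``,
    ``path`` (relative to the manifest) and ``scenario``.  Sentence spans and
    the short/long length class (threshold: median length) are computed here.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed manifest JSON {manifest_path}: {exc}") from exc
    if not isinstance(manifest, dict) or "sections" not in manifest:
        raise ValidationError(f"manifest {manifest_path} lacks a 'sections' list")

    raw: list[tuple[str, str, str, str]] = []
    seen: set[str] = set()
    for rec in manifest["sections"]:
        try:
            sid = rec["section_id"]
            path = rec["path"]
        except (TypeError, KeyError) as exc:
            raise ValidationError(f"malformed section record {rec!r}") from exc
        if sid in seen:
            raise ValidationError(f"duplicate section_id {sid!r} in manifest")
        seen.add(sid)
        file_path = manifest_path.parent / path
        if not file_path.exists():
            raise ValidationError(f"section {sid!r}: missing file {file_path}")
        text = file_path.read_text(encoding="utf-8")
        raw.append((sid, rec.get("label_id", sid), text, str(rec.get("scenario", "1"))))

    threshold = length_threshold(len(t) for _, _, t, _ in raw)
    sections: dict[str, LabelSection] = {}
    assignment: dict[str, str] = {}
    for sid, label_id, text, scenario in raw:
        sections[sid] = LabelSection(
            section_id=sid,
            label_id=label_id,
            text=text,
            sentence_spans=tuple(segment_sentences(text)),
            length_class=classify_length(len(text), threshold),
        )
        assignment[sid] = scenario
    corpus = Corpus(sections=sections, scenario_assignment=assignment)
    corpus.validate()
    return corpus


def write_corpus(corpus: Corpus, out_dir: str | Path) -> Path:
    """Write section texts and a manifest under ``out_dir``; returns manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "sections").mkdir(parents=True, exist_ok=True)
    records = []
    for sid in sorted(corpus.sections):
        sec = corpus.sections[sid]
        rel = f"sections/{sid}.txt"
        (out_dir / rel).write_text(sec.text, encoding="utf-8")
        records.append(
            {
                "section_id": sid,
                "label_id": sec.label_id,
                "path": rel,
                "scenario": corpus.scenario_assignment.get(sid, "1"),
            }
        )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps({"sections": records}, indent=1) + "\n", encoding="utf-8"
    )
    return manifest_path


def _drug_reference_to_json(ref: DrugReference) -> dict[str, str]:
    return {
        "normalized_ingredient_id": ref.normalized_ingredient_id,
        "entity_type": ref.entity_type,
    }


def _drug_reference_from_json(obj: dict[str, Any]) -> DrugReference:
    return DrugReference(
        normalized_ingredient_id=obj["normalized_ingredient_id"],
        entity_type=obj["entity_type"],
    )


def annotation_set_to_json(aset: AnnotationSet, corpus: Corpus | None = None) -> dict:
    """Serialize an annotation set; validates first.

    With a corpus, sentence selectors carry the exact quoted sentence text.
    """
    aset.validate(corpus)
    annotations: list[dict] = []
    counter = 0
    for d in aset.drug_mentions:
        counter += 1
        body = {
            "entity_type": d.entity_type,
            "concept_id": d.concept_id,
            "normalized_ingredient_id": d.normalized_ingredient_id,
            "unmapped_product": d.unmapped_product,
        }
        body.update(d.extra)
        annotations.append(
            {
                "id": f"{aset.source_id}-{counter}",
                "type": "drug_mention",
                "target": {
                    "section_id": d.section_id,
                    "selector": {
                        "char_start": d.char_start,
                        "char_end": d.char_end,
                        "exact": d.surface,
                    },
                },
                "body": body,
            }
        )
    for m in aset.pddi_mentions:
        counter += 1
        selectors = []
        for idx in sorted(m.sentence_indices):
            sel: dict[str, Any] = {"sentence_index": idx}
            if corpus is not None:
                sel["exact"] = corpus.sections[m.section_id].sentence_text(idx)
            selectors.append(sel)
        body = {
            "precipitant": _drug_reference_to_json(m.precipitant),
            "object": _drug_reference_to_json(m.object),
            "statement": m.statement,
            "modality": m.modality,
        }
        body.update(m.extra)
        annotations.append(
            {
                "id": f"{aset.source_id}-{counter}",
                "type": "pddi_mention",
                "target": {"section_id": m.section_id, "selectors": selectors},
                "body": body,
            }
        )
    doc = {
        "source_id": aset.source_id,
        "source_kind": aset.source_kind,
        "annotations": annotations,
    }
    if aset.provenance:
        doc["provenance"] = aset.provenance
    return doc


def write_annotations(
    aset: AnnotationSet, path: str | Path, corpus: Corpus | None = None
) -> None:
    doc = annotation_set_to_json(aset, corpus)
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def annotation_set_from_json(doc: dict, corpus: Corpus | None = None) -> AnnotationSet:
    """Inverse of :func:`annotation_set_to_json`.

    Unknown body keys land in the mention's ``extra`` pass-through mapping.
    With a corpus, exact quotes are checked against the section text and a
    mismatch is reported with the offending annotation id.
    """
    try:
        aset = AnnotationSet(
            source_id=doc["source_id"], source_kind=doc["source_kind"]
        )
    except KeyError as exc:
        raise ValidationError(f"annotation document lacks key {exc}") from exc
    aset.provenance = dict(doc.get("provenance", {}))
    for ann in doc.get("annotations", []):
        ann_id = ann.get("id", "<missing id>")
        try:
            target = ann["target"]
            body = ann["body"]
            sid = target["section_id"]
            kind = ann["type"]
        except KeyError as exc:
            raise ValidationError(f"annotation {ann_id}: missing key {exc}") from exc
        if kind == "drug_mention":
            sel = target["selector"]
            extra = {k: v for k, v in body.items() if k not in _DRUG_BODY_KEYS}
            mention = DrugMention(
                section_id=sid,
                char_start=sel["char_start"],
                char_end=sel["char_end"],
                surface=sel.get("exact", ""),
                entity_type=body["entity_type"],
                concept_id=body["concept_id"],
                normalized_ingredient_id=body["normalized_ingredient_id"],
                unmapped_product=bool(body.get("unmapped_product", False)),
                extra=extra,
            )
            if corpus is not None:
                if sid not in corpus.sections:
                    raise ValidationError(
                        f"annotation {ann_id}: unknown section {sid!r}"
                    )
                slice_ = corpus.sections[sid].text[
                    mention.char_start : mention.char_end
                ]
                if "exact" in sel and sel["exact"] != slice_:
                    raise ValidationError(
                        f"annotation {ann_id}: quoted text {sel['exact']!r} "
                        f"does not match section text {slice_!r}"
                    )
                if "exact" not in sel:
                    mention = dataclasses.replace(mention, surface=slice_)
            aset.drug_mentions.append(mention)
        elif kind == "pddi_mention":
            selectors = target["selectors"]
            indices = frozenset(s["sentence_index"] for s in selectors)
            if corpus is not None:
                if sid not in corpus.sections:
                    raise ValidationError(
                        f"annotation {ann_id}: unknown section {sid!r}"
                    )
                section = corpus.sections[sid]
                for s in selectors:
                    idx = s["sentence_index"]
                    if not 0 <= idx < len(section.sentence_spans):
                        raise ValidationError(
                            f"annotation {ann_id}: sentence index {idx} out of "
                            f"range for section {sid!r}"
                        )
                    if "exact" in s and s["exact"] != section.sentence_text(idx):
                        raise ValidationError(
                            f"annotation {ann_id}: quoted sentence does not "
                            f"match section text for sentence {idx}"
                        )
            extra = {k: v for k, v in body.items() if k not in _PDDI_BODY_KEYS}
            aset.pddi_mentions.append(
                PDDIMention(
                    section_id=sid,
                    sentence_indices=indices,
                    precipitant=_drug_reference_from_json(body["precipitant"]),
                    object=_drug_reference_from_json(body["object"]),
                    statement=body["statement"],
                    modality=body["modality"],
                    extra=extra,
                )
            )
        else:
            raise ValidationError(f"annotation {ann_id}: unknown type {kind!r}")
    aset.validate(corpus)
    return aset


def read_annotations(path: str | Path, corpus: Corpus | None = None) -> AnnotationSet:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed annotation JSON {path}: {exc}") from exc
    return annotation_set_from_json(doc, corpus)
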