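"""Synthetic annotation-study generator.

Builds everything a preannotation study assumes, so the rest of the package
is testable without any terminology download or human participants:

* a synthetic drug lexicon (pronounceable generated ingredient, product and
  metabolite names, plus a few ``non_drug`` distractor concepts) with a
  sole-active-ingredient product relation table;
* label sections of templated prose mixing planted PDDI statements
  (rendered from the same rule grammar the extractor parses, or — at a
  configurable noise rate — from paraphrases outside that grammar) with
  distractor sentences;
* a reference annotation set recording every planted mention;
* a simulated NLP output with a planted sentence-level operating point
  (recall/precision defaults 0.81/0.86);
* simulated annotators with a four-rate behavioral model (fix an NLP miss,
  drop an NLP hit, accept an NLP false positive, invent a spontaneous false
  positive);
* a ground-truth ledger recording the planted outcome of every mention, so
  downstream agreement tables can be checked cell-for-cell.

Default composition is calibrated to a reference standard of 205 annotated
sections carrying roughly 607 PDDI mentions and a 3351:234:201 mix of
active-ingredient : drug-product : metabolite mentions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .lexicon import Lexicon, LexiconEntry
from .model import (
    AnnotationSet,
    Corpus,
    DrugMention,
    DrugReference,
    LabelSection,
    PDDIMention,
    classify_length,
    length_threshold,
)
from .segment import segment_sentences


@dataclass(frozen=True)
class AnnotatorProfile:
    """Behavioral rates of a simulated annotator.

    Defaults are calibrated to the reported behavior of the study's
    nonexpert annotators under full preannotation assistance.  In
    unassisted mode ``p_fix_nlp_fn`` doubles as the base sensitivity.
    """

    p_fix_nlp_fn: float = 0.58
    p_drop_nlp_tp: float = 0.26
    p_accept_nlp_fp: float = 0.054
    spontaneous_fp_per_section: float = 0.3

    def validate(self) -> None:
        for name in ("p_fix_nlp_fn", "p_drop_nlp_tp", "p_accept_nlp_fp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.spontaneous_fp_per_section < 0:
            raise ValueError("spontaneous_fp_per_section must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus and simulators."""

    n_sections: int = 205
    drugs_per_section: tuple[int, int] = (6, 10)
    pddis_per_section: tuple[int, int] = (2, 4)
    p_negative_modality: float = 0.12
    p_quantitative: float = 0.5
    single_drug_sentences: tuple[int, int] = (4, 7)
    fp_sites_per_section: int = 2
    extra_product_sentence_p: float = 0.15
    paraphrase_noise: float = 0.0
    cue_distractor_noise: float = 0.0
    n_ingredients: int = 120
    n_products: int = 30
    n_metabolites: int = 30
    nlp_sentence_recall: float = 0.81
    nlp_sentence_precision: float = 0.86
    annotator: AnnotatorProfile = field(default_factory=AnnotatorProfile)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "p_negative_modality",
            "p_quantitative",
            "paraphrase_noise",
            "cue_distractor_noise",
            "nlp_sentence_recall",
            "nlp_sentence_precision",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        self.annotator.validate()


# ---------------------------------------------------------------------------
# name generation

_ONSETS = (
    "b", "c", "d", "f", "g", "k", "l", "m", "n", "p", "r", "s", "t", "v", "z",
    "br", "cl", "dr", "fl", "gr", "pr", "st", "tr",
)
_VOWELS = ("a", "e", "i", "o", "u")
_INGREDIENT_SUFFIXES = (
    "ib", "ol", "ine", "azole", "micin", "pril", "sartan", "oxetine", "idone",
)
_PRODUCT_SUFFIXES = ("ex", "ax", "or", "il", "on")
_METABOLITE_PREFIXES = ("Nor", "Hydroxy", "Desmethyl")

#: lower-cased words that generated names must not start with (template
#: vocabulary plus cue/verb stems), so NER and cue detection stay clean
_NAME_STOPLIST_PREFIXES = (
    "auc", "cmax", "clearance", "concentration", "half", "pharmaco",
    "inhibit", "induce", "increase", "decrease", "reduce", "elevate",
    "prolong", "alter", "drug", "patient", "plasma", "clinical", "both",
    "coadmin", "absorp", "store", "no", "did", "does", "was", "were",
)


def _make_name(rng: np.random.Generator, syllables: int) -> str:
    parts = []
    for _ in range(syllables):
        parts.append(str(rng.choice(_ONSETS)))
        parts.append(str(rng.choice(_VOWELS)))
    return "".join(parts)


def _fresh_name(
    rng: np.random.Generator, taken: set[str], suffix: str, syllables: int = 2
) -> str:
    while True:
        base = _make_name(rng, syllables) + suffix
        name = base.capitalize()
        low = name.lower()
        if low in taken:
            continue
        if any(low.startswith(p) for p in _NAME_STOPLIST_PREFIXES):
            continue
        taken.add(low)
        return name


def make_lexicon(config: GeneratorConfig, rng: np.random.Generator) -> Lexicon:
    """Synthetic lexicon: ingredients, sole-ingredient products, metabolites."""
    taken: set[str] = set()
    entries: list[LexiconEntry] = []
    ingredient_ids: list[str] = []
    for i in range(config.n_ingredients):
        name = _fresh_name(rng, taken, str(rng.choice(_INGREDIENT_SUFFIXES)))
        cid = f"ING{i:04d}"
        entries.append(LexiconEntry(cid, name, "active_ingredient"))
        ingredient_ids.append(cid)
    relations: dict[str, str] = {}
    for i in range(config.n_products):
        name = _fresh_name(rng, taken, str(rng.choice(_PRODUCT_SUFFIXES)))
        cid = f"PRD{i:04d}"
        entries.append(LexiconEntry(cid, name, "drug_product"))
        relations[cid] = str(rng.choice(ingredient_ids))
    by_id = {e.concept_id: e for e in entries}
    for i in range(config.n_metabolites):
        parent = str(rng.choice(ingredient_ids))
        prefix = str(rng.choice(_METABOLITE_PREFIXES))
        name = prefix + by_id[parent].name.lower()
        if name.lower() in taken:
            name = _fresh_name(rng, taken, "one")
        else:
            taken.add(name.lower())
        entries.append(
            LexiconEntry(f"MET{i:04d}", name, "metabolite", synonyms=())
        )
    for i, word in enumerate(("placebo", "lactose", "food", "alcohol")):
        entries.append(LexiconEntry(f"NON{i:04d}", word, "non_drug"))
    lex = Lexicon(entries=entries, product_to_ingredient=relations)
    lex.validate()
    return lex


# ---------------------------------------------------------------------------
# section building

@dataclass(frozen=True)
class _Slot:
    surface: str
    entry: LexiconEntry
    normalized_id: str
    unmapped: bool = False


class _SectionBuilder:
    """Accumulates sentences as part lists and renders exact offsets."""

    def __init__(self, section_id: str, label_id: str):
        self.section_id = section_id
        self.label_id = label_id
        self.sentences: list[list[object]] = []

    def add(self, *parts: object) -> int:
        """Append a sentence; returns its (pre-shuffle) index."""
        self.sentences.append(list(parts))
        return len(self.sentences) - 1

    def render(
        self,
    ) -> tuple[str, list[tuple[int, int]], list[DrugMention], dict[int, int]]:
        text_parts: list[str] = []
        spans: list[tuple[int, int]] = []
        mentions: list[DrugMention] = []
        offset = 0
        index_map: dict[int, int] = {}
        for new_idx, sentence in enumerate(self.sentences):
            index_map[new_idx] = new_idx
            start = offset
            for part in sentence:
                if isinstance(part, _Slot):
                    mentions.append(
                        DrugMention(
                            section_id=self.section_id,
                            char_start=offset,
                            char_end=offset + len(part.surface),
                            surface=part.surface,
                            entity_type=part.entry.entity_type,
                            concept_id=part.entry.concept_id,
                            normalized_ingredient_id=part.normalized_id,
                            unmapped_product=part.unmapped,
                        )
                    )
                    text_parts.append(part.surface)
                    offset += len(part.surface)
                else:
                    text_parts.append(str(part))
                    offset += len(str(part))
            spans.append((start, offset))
            text_parts.append(" ")
            offset += 1
        text = "".join(text_parts).rstrip()
        return text, spans, mentions, index_map


def _slot(entry: LexiconEntry, lex: Lexicon) -> _Slot:
    normalized = entry.concept_id
    unmapped = False
    if entry.entity_type == "drug_product":
        mapped = lex.product_to_ingredient.get(entry.concept_id)
        if mapped is not None:
            normalized = mapped
        else:
            unmapped = True
    return _Slot(entry.name, entry, normalized, unmapped)


@dataclass
class FPSite:
    """A two-drug non-PDDI sentence usable as a plausible false positive."""

    section_id: str
    sentence_index: int
    precipitant: DrugReference
    object: DrugReference
    has_cue: bool
    used_by_nlp: bool = False

    def mention(self) -> PDDIMention:
        return PDDIMention(
            section_id=self.section_id,
            sentence_indices=frozenset({self.sentence_index}),
            precipitant=self.precipitant,
            object=self.object,
            statement="qualitative",
            modality="positive",
        )


@dataclass
class RefRecord:
    """Planted truth plus downstream outcomes for one reference mention."""

    mention: PDDIMention
    paraphrased: bool
    nlp: str | None = None  # "tp" | "fn"
    users: dict[str, str] = field(default_factory=dict)  # "tp" | "fn"


@dataclass
class NLPFPRecord:
    mention: PDDIMention
    users: dict[str, bool] = field(default_factory=dict)  # kept?


@dataclass
class GroundTruthLedger:
    """Per-mention bookkeeping that downstream agreement tables must equal."""

    ref_records: list[RefRecord] = field(default_factory=list)
    nlp_fp_records: list[NLPFPRecord] = field(default_factory=list)
    spontaneous: dict[str, list[PDDIMention]] = field(default_factory=dict)
    fp_sites: list[FPSite] = field(default_factory=list)

    def expected_cells(self, annotator_id: str) -> dict[str, int]:
        """Aggregate the ledger into agreement-table cells for one annotator."""
        cells = dict.fromkeys(
            (
                "nlp_fn_user_fn",
                "nlp_fn_user_tp",
                "nlp_tp_user_fn",
                "nlp_tp_user_tp",
                "nlp_fp_user_tn",
                "nlp_fp_user_fp",
                "nlp_tn_user_fp",
            ),
            0,
        )
        for rec in self.ref_records:
            user = rec.users.get(annotator_id, "fn")
            cells[f"nlp_{rec.nlp}_user_{user}"] += 1
        for rec in self.nlp_fp_records:
            kept = rec.users.get(annotator_id, False)
            cells["nlp_fp_user_fp" if kept else "nlp_fp_user_tn"] += 1
        cells["nlp_tn_user_fp"] = len(self.spontaneous.get(annotator_id, []))
        return cells


@dataclass
class SyntheticStudy:
    """Bundle returned by :func:`generate_corpus`."""

    config: GeneratorConfig
    corpus: Corpus
    lexicon: Lexicon
    reference: AnnotationSet
    ledger: GroundTruthLedger


# PDDI sentence templates; each returns the list of sentence parts with the
# precipitant slot X and object slot Y, matching the extractor's rule grammar.
def _pddi_sentence(
    rng: np.random.Generator,
    x: _Slot,
    y: _Slot,
    modality: str,
    statement: str,
    paraphrased: bool,
) -> list[object]:
    if paraphrased:
        if modality == "negative":
            return ["No change in ", y, " levels was seen with ", x, "."]
        return ["Exposure to ", y, " tends to rise when taken together with ", x, "."]
    if modality == "negative":
        if statement == "quantitative":
            pct = int(rng.integers(3, 10))
            return [
                x, " did not increase the AUC of ", y,
                f" by more than {pct}%.",
            ]
        if rng.random() < 0.5:
            return [
                "Coadministration of ", x,
                " had no effect on the pharmacokinetics of ", y, ".",
            ]
        return [x, " did not alter the AUC of ", y, "."]
    if statement == "quantitative":
        choice = rng.integers(3)
        if choice == 0:
            pct = int(rng.integers(4, 19)) * 5
            return [x, " increased the AUC of ", y, f" by {pct}%."]
        if choice == 1:
            fold = int(rng.integers(2, 6))
            return [
                x, " increased ", y,
                f" plasma concentration approximately {fold}-fold.",
            ]
        pct = int(rng.integers(4, 19)) * 5
        return [
            "The AUC of ", y, f" was increased by {pct}% following ",
            "coadministration of ", x, ".",
        ]
    choice = rng.integers(3)
    if choice == 0:
        return [x, " decreased the clearance of ", y, "."]
    if choice == 1:
        return [x, " may inhibit the metabolism of ", y, "."]
    return ["The clearance of ", y, " was reduced by ", x, "."]


_SINGLE_DRUG_TEMPLATES = (
    (None, " is extensively bound to plasma proteins."),
    (None, " is administered orally once daily."),
    ("The recommended starting dose of ", " is one tablet."),
    (None, " is excreted primarily in urine."),
    ("Absorption of ", " is unaffected by food."),
)


def generate_corpus(config: GeneratorConfig | None = None) -> SyntheticStudy:
    """Generate a corpus, lexicon, reference set and ground-truth ledger.

    Deterministic given ``config.seed``.  Scenario assignment is left to
    :func:`pddikit.design.assign_scenarios`; sections start unassigned
    (scenario "1").
    """
    if config is None:
        config = GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    lexicon = make_lexicon(config, rng)
    ingredients = [e for e in lexicon.entries if e.entity_type == "active_ingredient"]
    products = [e for e in lexicon.entries if e.entity_type == "drug_product"]
    metabolites = [e for e in lexicon.entries if e.entity_type == "metabolite"]
    met_parent = {
        e.concept_id: next(
            (
                i
                for i in ingredients
                if e.name.lower().endswith(i.name.lower())
            ),
            ingredients[0],
        )
        for e in metabolites
    }

    sections: dict[str, LabelSection] = {}
    reference = AnnotationSet(source_id="reference", source_kind="reference")
    ledger = GroundTruthLedger()
    lengths: list[int] = []
    raw_sections: list[tuple[str, str, list[tuple[int, int]], list[DrugMention]]] = []

    for si in range(config.n_sections):
        sid = f"S{si:04d}"
        builder = _SectionBuilder(sid, label_id=f"L{si:04d}")
        pool_size = int(
            rng.integers(config.drugs_per_section[0], config.drugs_per_section[1] + 1)
        )
        pool = list(rng.choice(len(ingredients), size=pool_size, replace=False))
        pool_entries = [ingredients[i] for i in pool]

        sentence_specs: list[tuple[str, object]] = []
        sentence_specs.append(("opening", None))

        n_pddi = int(
            rng.integers(config.pddis_per_section[0], config.pddis_per_section[1] + 1)
        )
        for _ in range(n_pddi):
            xi, yi = rng.choice(len(pool_entries), size=2, replace=False)
            modality = (
                "negative" if rng.random() < config.p_negative_modality else "positive"
            )
            statement = (
                "quantitative" if rng.random() < config.p_quantitative else "qualitative"
            )
            paraphrased = rng.random() < config.paraphrase_noise
            sentence_specs.append(
                ("pddi", (pool_entries[int(xi)], pool_entries[int(yi)], modality, statement, paraphrased))
            )

        met = metabolites[int(rng.integers(len(metabolites)))]
        sentence_specs.append(("metabolite", met))

        n_products = 1 + int(rng.random() < config.extra_product_sentence_p)
        for _ in range(n_products):
            prod = products[int(rng.integers(len(products)))]
            sentence_specs.append(("product", prod))

        for _ in range(config.fp_sites_per_section):
            ai, bi = rng.choice(len(pool_entries), size=2, replace=False)
            cue_noise = rng.random() < config.cue_distractor_noise
            sentence_specs.append(
                ("fp_site", (pool_entries[int(ai)], pool_entries[int(bi)], cue_noise))
            )

        n_single = int(
            rng.integers(
                config.single_drug_sentences[0], config.single_drug_sentences[1] + 1
            )
        )
        for _ in range(n_single):
            z = pool_entries[int(rng.integers(len(pool_entries)))]
            t = int(rng.integers(len(_SINGLE_DRUG_TEMPLATES)))
            sentence_specs.append(("single", (z, t)))

        sentence_specs.append(("closing", None))

        # shuffle everything except the opening sentence
        body = sentence_specs[1:]
        order = rng.permutation(len(body))
        sentence_specs = [sentence_specs[0]] + [body[i] for i in order]

        pddi_plants: list[tuple[int, tuple]] = []
        fp_plants: list[tuple[int, tuple]] = []
        for kind, payload in sentence_specs:
            if kind == "opening":
                builder.add(
                    "Drug interaction studies were conducted in healthy adult volunteers."
                )
            elif kind == "closing":
                builder.add(
                    "Patients should consult their healthcare provider before "
                    "starting any new medication."
                )
            elif kind == "pddi":
                x_entry, y_entry, modality, statement, paraphrased = payload
                idx = builder.add(
                    *_pddi_sentence(
                        rng,
                        _slot(x_entry, lexicon),
                        _slot(y_entry, lexicon),
                        modality,
                        statement,
                        paraphrased,
                    )
                )
                pddi_plants.append(
                    (idx, (x_entry, y_entry, modality, statement, paraphrased))
                )
            elif kind == "metabolite":
                met_slot = _slot(payload, lexicon)
                parent_slot = _slot(met_parent[payload.concept_id], lexicon)
                idx = builder.add(
                    met_slot, " is the principal metabolite of ", parent_slot, "."
                )
            elif kind == "product":
                idx = builder.add(
                    "Patients receiving ",
                    _slot(payload, lexicon),
                    " tablets should be monitored for adverse events.",
                )
            elif kind == "fp_site":
                a_entry, b_entry, cue_noise = payload
                if cue_noise:
                    idx = builder.add(
                        "Plasma concentration monitoring is recommended when ",
                        _slot(a_entry, lexicon),
                        " and ",
                        _slot(b_entry, lexicon),
                        " are used together.",
                    )
                else:
                    idx = builder.add(
                        "Both ",
                        _slot(a_entry, lexicon),
                        " and ",
                        _slot(b_entry, lexicon),
                        " have been administered together in clinical studies.",
                    )
                fp_plants.append((idx, (a_entry, b_entry, cue_noise)))
            elif kind == "single":
                z_entry, t = payload
                prefix, suffix = _SINGLE_DRUG_TEMPLATES[t]
                if prefix is None:
                    builder.add(_slot(z_entry, lexicon), suffix)
                else:
                    builder.add(prefix, _slot(z_entry, lexicon), suffix)

        text, spans, drug_mentions, _ = builder.render()
        # the canonical segmentation must agree with the construction
        assert segment_sentences(text) == spans, sid
        lengths.append(len(text))
        raw_sections.append((sid, text, spans, drug_mentions))

        reference.drug_mentions.extend(drug_mentions)
        for idx, (x_entry, y_entry, modality, statement, paraphrased) in pddi_plants:
            mention = PDDIMention(
                section_id=sid,
                sentence_indices=frozenset({idx}),
                precipitant=DrugReference(x_entry.concept_id, "active_ingredient"),
                object=DrugReference(y_entry.concept_id, "active_ingredient"),
                statement=statement,
                modality=modality,
            )
            reference.pddi_mentions.append(mention)
            ledger.ref_records.append(
                RefRecord(mention=mention, paraphrased=paraphrased)
            )
        for idx, (a_entry, b_entry, cue_noise) in fp_plants:
            ledger.fp_sites.append(
                FPSite(
                    section_id=sid,
                    sentence_index=idx,
                    precipitant=DrugReference(a_entry.concept_id, "active_ingredient"),
                    object=DrugReference(b_entry.concept_id, "active_ingredient"),
                    has_cue=cue_noise,
                )
            )

    threshold = length_threshold(lengths)
    for sid, text, spans, _mentions in raw_sections:
        sections[sid] = LabelSection(
            section_id=sid,
            label_id=sid.replace("S", "L"),
            text=text,
            sentence_spans=tuple(spans),
            length_class=classify_length(len(text), threshold),
        )
    corpus = Corpus(
        sections=sections,
        scenario_assignment={sid: "1" for sid in sections},
    )
    corpus.validate()
    reference.validate(corpus)
    return SyntheticStudy(
        config=config,
        corpus=corpus,
        lexicon=lexicon,
        reference=reference,
        ledger=ledger,
    )


def simulate_nlp(
    study: SyntheticStudy,
    rng: np.random.Generator | None = None,
) -> AnnotationSet:
    """Sample an NLP output at the configured recall/precision operating point.

    Each reference PDDI mention is emitted with probability
    ``nlp_sentence_recall``; false positives are drawn per emitted true
    positive so that the expected precision equals
    ``nlp_sentence_precision``, and are realized at planted two-drug
    non-PDDI sentences.  Updates the ledger.
    """
    config = study.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    out = AnnotationSet(source_id="nlp", source_kind="nlp")
    out.drug_mentions = list(study.reference.drug_mentions)
    n_tp = 0
    for rec in study.ledger.ref_records:
        if rng.random() < config.nlp_sentence_recall:
            rec.nlp = "tp"
            out.pddi_mentions.append(rec.mention)
            n_tp += 1
        else:
            rec.nlp = "fn"
    # FP count: per true positive, floor(q) plus Bernoulli(frac(q)) where
    # q = (1-p)/p, so E[FP] = TP*(1-p)/p and E[precision] ~= p
    p = config.nlp_sentence_precision
    q = (1.0 - p) / p if p > 0 else 0.0
    n_fp = 0
    for _ in range(n_tp):
        n_fp += int(q) + int(rng.random() < (q - int(q)))
    free_sites = [s for s in study.ledger.fp_sites if not s.used_by_nlp]
    order = rng.permutation(len(free_sites))
    for k in range(min(n_fp, len(free_sites))):
        site = free_sites[int(order[k])]
        site.used_by_nlp = True
        mention = site.mention()
        out.pddi_mentions.append(mention)
        study.ledger.nlp_fp_records.append(NLPFPRecord(mention=mention))
    return out


def simulate_annotator(
    study: SyntheticStudy,
    nlp: AnnotationSet,
    annotator_id: str,
    profile: AnnotatorProfile | None = None,
    assisted: bool = True,
    rng: np.random.Generator | None = None,
) -> AnnotationSet:
    """Sample one annotator's final annotation set; updates the ledger.

    Assisted mode models correction of preannotations: NLP true positives
    are kept with probability ``1 - p_drop_nlp_tp``, NLP misses are fixed
    with probability ``p_fix_nlp_fn``, NLP false positives are accepted with
    probability ``p_accept_nlp_fp``, and spontaneous false positives arise
    per section at rate ``spontaneous_fp_per_section`` (realized at unused
    planted two-drug sentences).  Unassisted mode finds each reference
    mention with probability ``p_fix_nlp_fn`` (the base sensitivity) and
    adds spontaneous false positives only.
    """
    config = study.config
    if profile is None:
        profile = config.annotator
    profile.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 101)
    out = AnnotationSet(source_id=annotator_id, source_kind="human")
    for rec in study.ledger.ref_records:
        if assisted:
            if rec.nlp == "tp":
                found = rng.random() >= profile.p_drop_nlp_tp
            else:
                found = rng.random() < profile.p_fix_nlp_fn
        else:
            found = rng.random() < profile.p_fix_nlp_fn
        rec.users[annotator_id] = "tp" if found else "fn"
        if found:
            out.pddi_mentions.append(rec.mention)
    if assisted:
        for rec in study.ledger.nlp_fp_records:
            kept = rng.random() < profile.p_accept_nlp_fp
            rec.users[annotator_id] = kept
            if kept:
                out.pddi_mentions.append(rec.mention)
    spontaneous: list[PDDIMention] = []
    free_by_section: dict[str, list[FPSite]] = {}
    for site in study.ledger.fp_sites:
        if not site.used_by_nlp:
            free_by_section.setdefault(site.section_id, []).append(site)
    for sid in sorted(study.corpus.sections):
        n = int(rng.poisson(profile.spontaneous_fp_per_section))
        sites = free_by_section.get(sid, [])
        for site in sites[:n]:
            mention = site.mention()
            spontaneous.append(mention)
            out.pddi_mentions.append(mention)
    study.ledger.spontaneous[annotator_id] = spontaneous
    return out


def simulate_study(
    config: GeneratorConfig | None = None,
    annotators: dict[str, AnnotatorProfile] | None = None,
    assisted: bool = True,
) -> tuple[SyntheticStudy, AnnotationSet, dict[str, AnnotationSet]]:
    """Generate a corpus and run the NLP and annotator simulators over it."""
    study = generate_corpus(config)
    config = study.config
    nlp = simulate_nlp(study, rng=np.random.default_rng(config.seed + 1))
    if annotators is None:
        annotators = {"annotator-1": config.annotator}
    user_sets: dict[str, AnnotationSet] = {}
    for k, (name, profile) in enumerate(sorted(annotators.items())):
        user_sets[name] = simulate_annotator(
            study,
            nlp,
            annotator_id=name,
            profile=profile,
            assisted=assisted,
            rng=np.random.default_rng(config.seed + 101 + k),
        )
    return study, nlp, user_sets


def with_overrides(config: GeneratorConfig, **kwargs) -> GeneratorConfig:
    """Functional-update helper for :class:`GeneratorConfig`."""
    return dataclasses.replace(config, **kwargs)
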