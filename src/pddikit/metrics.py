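"""Span-overlap matching of PDDI mentions and per-label P/R/F1.

A candidate mention counts as a true positive iff it (a) matches the
reference mention's precipitant, object, and modality — drug identity is
compared on the normalized ingredient id, so a drug-product mention matches
an active-ingredient reference of its sole ingredient — and (b) its selected
sentences at least partially overlap the reference's.  Statement type
(quantitative vs qualitative) is deliberately not part of the criterion.

Pairing is one-to-one per section: candidates are seeded in (first sentence,
precipitant) order and the pairing is completed by augmenting paths, so the
number of pairs always equals the maximum bipartite matching size under the
match predicate and no mention is double counted.

Metrics are computed per product-label section ("by label") and then
macro-averaged, unweighted, within each scenario and overall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .model import AnnotationSet, Corpus, PDDIMention, ValidationError


def is_match(candidate: PDDIMention, reference: PDDIMention) -> bool:
    """Match criterion: same section, drugs and modality; sentences overlap."""
    return (
        candidate.section_id == reference.section_id
        and candidate.precipitant.normalized_ingredient_id
        == reference.precipitant.normalized_ingredient_id
        and candidate.object.normalized_ingredient_id
        == reference.object.normalized_ingredient_id
        and candidate.modality == reference.modality
        and bool(candidate.sentence_indices & reference.sentence_indices)
    )


@dataclass
class MatchResult:
    """One-to-one pairing of candidate and reference PDDI mentions."""

    pairs: list[tuple[PDDIMention, PDDIMention]] = field(default_factory=list)
    candidate_fp: list[PDDIMention] = field(default_factory=list)
    reference_fn: list[PDDIMention] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.pairs)


def _match_lists(
    candidates: list[PDDIMention], references: list[PDDIMention]
) -> MatchResult:
    """Deterministic maximum one-to-one matching via augmenting paths."""
    cands = sorted(candidates, key=PDDIMention.sort_key)
    refs = sorted(references, key=PDDIMention.sort_key)
    adjacency = [
        [j for j, r in enumerate(refs) if is_match(c, r)] for c in cands
    ]
    ref_owner: list[int | None] = [None] * len(refs)

    def try_assign(ci: int, banned: set[int]) -> bool:
        for rj in adjacency[ci]:
            if rj in banned:
                continue
            banned.add(rj)
            if ref_owner[rj] is None or try_assign(ref_owner[rj], banned):
                ref_owner[rj] = ci
                return True
        return False

    for ci in range(len(cands)):
        try_assign(ci, set())

    cand_of_ref = {rj: ci for rj, ci in enumerate(ref_owner) if ci is not None}
    matched_cands = set(cand_of_ref.values())
    result = MatchResult()
    for rj in sorted(cand_of_ref):
        result.pairs.append((cands[cand_of_ref[rj]], refs[rj]))
    result.candidate_fp = [
        c for i, c in enumerate(cands) if i not in matched_cands
    ]
    result.reference_fn = [
        r for j, r in enumerate(refs) if ref_owner[j] is None
    ]
    return result


def match_sets(
    candidate: AnnotationSet, reference: AnnotationSet, corpus: Corpus | None = None
) -> MatchResult:
    """Match candidate against reference PDDI mentions, section by section."""
    if corpus is not None:
        candidate.validate(corpus)
        reference.validate(corpus)
    sections = sorted(
        {m.section_id for m in candidate.pddi_mentions}
        | {m.section_id for m in reference.pddi_mentions}
    )
    combined = MatchResult()
    for sid in sections:
        res = _match_lists(
            [m for m in candidate.pddi_mentions if m.section_id == sid],
            [m for m in reference.pddi_mentions if m.section_id == sid],
        )
        combined.pairs.extend(res.pairs)
        combined.candidate_fp.extend(res.candidate_fp)
        combined.reference_fn.extend(res.reference_fn)
    return combined


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LabelMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class MetricsReport:
    """Per-label counts/metrics plus unweighted per-scenario and overall means.

    A metric that is undefined for a label (e.g. precision with zero
    candidate mentions) is excluded from the averages rather than imputed;
    labels with neither reference nor candidate mentions do not appear.
    """

    per_label: dict[str, LabelMetrics]
    label_scenario: dict[str, str]

    @staticmethod
    def _mean(values: list[float]) -> float | None:
        return sum(values) / len(values) if values else None

    def _summary(self, labels: list[str]) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for name in ("precision", "recall", "f1"):
            vals = [
                getattr(self.per_label[lbl], name)
                for lbl in labels
                if getattr(self.per_label[lbl], name) is not None
            ]
            out[name] = self._mean(vals)
        return out

    @property
    def per_scenario(self) -> dict[str, dict[str, float | None]]:
        scenarios = sorted(set(self.label_scenario.values()))
        return {
            sc: self._summary(
                [l for l in self.per_label if self.label_scenario[l] == sc]
            )
            for sc in scenarios
        }

    @property
    def overall(self) -> dict[str, float | None]:
        return self._summary(list(self.per_label))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lbl in sorted(self.per_label):
            m = self.per_label[lbl]
            rows.append(
                {
                    "label": lbl,
                    "scenario": self.label_scenario[lbl],
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        """Per-label, per-scenario and overall blocks, 2-decimal half-up."""
        blocks = [self.to_frame()]
        scen_rows = []
        for sc, summary in self.per_scenario.items():
            scen_rows.append({"scenario": sc, **summary})
        scen_rows.append({"scenario": "overall", **self.overall})
        summary_df = pd.DataFrame(scen_rows)
        for col in ("precision", "recall", "f1"):
            summary_df[col] = summary_df[col].map(
                lambda v: None if v is None else round_half_up(v, 2)
            )
        blocks.append(summary_df)
        with open(path, "w", encoding="utf-8") as fh:
            for block in blocks:
                block.to_csv(fh, sep="\t", index=False)
                fh.write("\n")


def compute_metrics(
    match: MatchResult,
    corpus: Corpus,
    scenario_assignment: dict[str, str] | None = None,
) -> MetricsReport:
    """Per-label TP/FP/FN and P/R/F1, macro-averaged by scenario."""
    assignment = scenario_assignment or corpus.scenario_assignment
    counts: dict[str, LabelMetrics] = {}

    def bump(sid: str, kind: str) -> None:
        if sid not in corpus.sections:
            raise ValidationError(f"match references unknown section {sid!r}")
        lm = counts.setdefault(sid, LabelMetrics(0, 0, 0))
        setattr(lm, kind, getattr(lm, kind) + 1)

    for cand, _ref in match.pairs:
        bump(cand.section_id, "tp")
    for c in match.candidate_fp:
        bump(c.section_id, "fp")
    for r in match.reference_fn:
        bump(r.section_id, "fn")

    label_scenario = {
        sid: assignment.get(sid, "1") for sid in counts
    }
    return MetricsReport(per_label=counts, label_scenario=label_scenario)
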