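"""Three-way user / NLP / reference agreement cross-tabulation.

For each reference-standard PDDI mention, classify whether the NLP
preannotation found it and whether the user's final annotation found it,
giving four cells whose counts partition the reference mentions.  NLP
mentions that match no reference mention form the NLP false-positive pool,
split by whether the user kept a matching mention; user mentions matching
neither the reference nor any NLP false positive are user-only false
positives (reported as a bare count, with no natural denominator).

Percentages are count/denominator, half-up to one decimal; integral
percentages render without the trailing ".0" (so 93/93 prints as "(100)").
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from .metrics import MatchResult, _match_lists, match_sets
from .model import AnnotationSet, Corpus, ValidationError


def format_percent(cell: int, denominator: int) -> float | None:
    """100*cell/denominator, rounded half-up to one decimal.

    A zero denominator yields ``None`` (an undefined marker), never 0.
    """
    if denominator == 0:
        return None
    pct = Decimal(100) * Decimal(cell) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def render_percent(cell: int, denominator: int) -> str:
    """Count with parenthesized percent, e.g. ``"59 (39.1)"``, ``"93 (100)"``."""
    pct = format_percent(cell, denominator)
    if pct is None:
        return f"{cell} (—)"
    text = f"{pct:.1f}".removesuffix(".0")
    return f"{cell} ({text})"


@dataclass(frozen=True)
class AgreementTable:
    """Counts of user/NLP outcomes against the reference standard."""

    n_reference: int
    nlp_fn_user_fn: int
    nlp_fn_user_tp: int
    nlp_tp_user_fn: int
    nlp_tp_user_tp: int
    n_nlp_fp: int
    nlp_tn_user_fp: int
    nlp_fp_user_tn: int
    nlp_fp_user_fp: int

    def validate(self) -> None:
        tp_sum = (
            self.nlp_fn_user_fn
            + self.nlp_fn_user_tp
            + self.nlp_tp_user_fn
            + self.nlp_tp_user_tp
        )
        if tp_sum != self.n_reference:
            raise ValidationError(
                f"reference cells sum to {tp_sum}, expected {self.n_reference}"
            )
        if self.nlp_fp_user_tn + self.nlp_fp_user_fp != self.n_nlp_fp:
            raise ValidationError(
                "NLP false-positive cells do not sum to the pool size"
            )

    def tp_cells(self) -> tuple[int, int, int, int]:
        return (
            self.nlp_fn_user_fn,
            self.nlp_fn_user_tp,
            self.nlp_tp_user_fn,
            self.nlp_tp_user_tp,
        )

    def tp_percents(self) -> tuple[float | None, ...]:
        return tuple(
            format_percent(c, self.n_reference) for c in self.tp_cells()
        )

    def fp_percents(self) -> tuple[float | None, float | None]:
        return (
            format_percent(self.nlp_fp_user_tn, self.n_nlp_fp),
            format_percent(self.nlp_fp_user_fp, self.n_nlp_fp),
        )

    def to_row(self) -> dict:
        return {
            "n_reference": self.n_reference,
            "nlp_fn_user_fn": render_percent(self.nlp_fn_user_fn, self.n_reference),
            "nlp_fn_user_tp": render_percent(self.nlp_fn_user_tp, self.n_reference),
            "nlp_tp_user_fn": render_percent(self.nlp_tp_user_fn, self.n_reference),
            "nlp_tp_user_tp": render_percent(self.nlp_tp_user_tp, self.n_reference),
            "nlp_tn_user_fp": str(self.nlp_tn_user_fp),
            "n_nlp_fp": self.n_nlp_fp,
            "nlp_fp_user_tn": render_percent(self.nlp_fp_user_tn, self.n_nlp_fp),
            "nlp_fp_user_fp": render_percent(self.nlp_fp_user_fp, self.n_nlp_fp),
        }


def build_agreement(
    user: AnnotationSet,
    nlp: AnnotationSet,
    reference: AnnotationSet,
    corpus: Corpus,
    scenario_filter: str | None = "3",
) -> AgreementTable:
    """Cross-tabulate user and NLP outcomes against the reference standard.

    ``scenario_filter`` restricts the analysis to sections of one scenario
    (the preannotation-assisted condition by default); ``None`` keeps all.
    """
    for aset in (user, nlp, reference):
        aset.validate(corpus)
    if scenario_filter is not None:
        keep = set(corpus.scenario_sections(scenario_filter))
        user = user.in_sections(keep)
        nlp = nlp.in_sections(keep)
        reference = reference.in_sections(keep)

    nlp_match = match_sets(nlp, reference)
    user_match = match_sets(user, reference)
    nlp_found = {r.key() for _, r in nlp_match.pairs}
    user_found = {r.key() for _, r in user_match.pairs}

    cells = {"ff": 0, "ft": 0, "tf": 0, "tt": 0}
    for r in reference.pddi_mentions:
        key = ("t" if r.key() in nlp_found else "f") + (
            "t" if r.key() in user_found else "f"
        )
        cells[key[0] + key[1]] += 1

    # user false positives vs the NLP false-positive pool: one-to-one again,
    # with the NLP mentions playing the reference role
    fp_match = _match_lists(user_match.candidate_fp, nlp_match.candidate_fp)
    nlp_fp_user_fp = fp_match.tp
    nlp_fp_user_tn = len(nlp_match.candidate_fp) - nlp_fp_user_fp
    nlp_tn_user_fp = len(fp_match.candidate_fp)

    table = AgreementTable(
        n_reference=len(reference.pddi_mentions),
        nlp_fn_user_fn=cells["ff"],
        nlp_fn_user_tp=cells["ft"],
        nlp_tp_user_fn=cells["tf"],
        nlp_tp_user_tp=cells["tt"],
        n_nlp_fp=len(nlp_match.candidate_fp),
        nlp_tn_user_fp=nlp_tn_user_fp,
        nlp_fp_user_tn=nlp_fp_user_tn,
        nlp_fp_user_fp=nlp_fp_user_fp,
    )
    table.validate()
    return table


def load_reported_agreement_counts() -> pd.DataFrame:
    """The packaged per-participant agreement counts reported by the study."""
    with resources.as_file(
        resources.files("pddikit.data").joinpath("scenario3_agreement_counts.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def reported_agreement_tables() -> dict[str, AgreementTable]:
    """Packaged study counts as :class:`AgreementTable` objects per participant."""
    df = load_reported_agreement_counts()
    tables: dict[str, AgreementTable] = {}
    for _, row in df.iterrows():
        table = AgreementTable(
            n_reference=int(
                row.nlp_fn_user_fn
                + row.nlp_fn_user_tp
                + row.nlp_tp_user_fn
                + row.nlp_tp_user_tp
            ),
            nlp_fn_user_fn=int(row.nlp_fn_user_fn),
            nlp_fn_user_tp=int(row.nlp_fn_user_tp),
            nlp_tp_user_fn=int(row.nlp_tp_user_fn),
            nlp_tp_user_tp=int(row.nlp_tp_user_tp),
            n_nlp_fp=int(row.nlp_fp_user_tn + row.nlp_fp_user_fp),
            nlp_tn_user_fp=int(row.nlp_tn_user_fp),
            nlp_fp_user_tn=int(row.nlp_fp_user_tn),
            nlp_fp_user_fp=int(row.nlp_fp_user_fp),
        )
        table.validate()
        tables[str(row.participant)] = table
    return tables


def write_agreement_tsv(tables: dict[str, AgreementTable], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fieldnames = ["participant"] + list(next(iter(tables.values())).to_row())
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t")
        writer.writeheader()
        for name, table in tables.items():
            writer.writerow({"participant": name, **table.to_row()})
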