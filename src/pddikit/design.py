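"""Scenario assignment and descriptive study summaries.

Annotation scenarios represent assistance levels (1: unassisted, 2: drug
mentions preannotated, 3: drug + PDDI mentions preannotated, 4: unassisted
repeat, plus a small training set).  Sections are distributed so that each
scenario receives roughly the same number of long and short sections: the
corpus is stratified at the median length and per-scenario stratum quotas
are set by largest-remainder apportionment, then sections are dealt
round-robin within each stratum after a seeded shuffle.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .model import Corpus, ValidationError

DEFAULT_TARGET_SIZES = {"training": 3, "1": 52, "2": 52, "3": 53, "4": 48}
TIME_CATEGORIES = ("<1h", "1-3h", "3-5h", ">5h")
SCENARIO_ORDER = ("training", "1", "2", "3", "4")


@dataclass
class ScenarioPlan:
    assignment: dict[str, str]
    target_sizes: dict[str, int]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sc in self.assignment.values():
            out[sc] = out.get(sc, 0) + 1
        return out

    def validate(self) -> None:
        if self.counts() != {k: v for k, v in self.target_sizes.items() if v}:
            raise ValidationError(
                f"assignment counts {self.counts()} != targets {self.target_sizes}"
            )


def _largest_remainder_quotas(
    sizes: dict[str, int], stratum_total: int, grand_total: int
) -> dict[str, int]:
    """Apportion ``stratum_total`` seats proportionally to scenario sizes."""
    exact = {
        sc: sizes[sc] * stratum_total / grand_total for sc in sizes
    }
    quotas = {sc: int(exact[sc]) for sc in sizes}
    shortfall = stratum_total - sum(quotas.values())
    order = sorted(
        sizes,
        key=lambda sc: (-(exact[sc] - quotas[sc]), SCENARIO_ORDER.index(sc)),
    )
    for sc in order[:shortfall]:
        quotas[sc] += 1
    return quotas


def assign_scenarios(
    corpus: Corpus,
    target_sizes: dict[str, int] | None = None,
    seed: int = 0,
) -> ScenarioPlan:
    """Deal sections into scenarios, balanced on the short/long strata.

    Deterministic given ``seed``; fails if target sizes do not sum to the
    corpus size.
    """
    sizes = dict(target_sizes or DEFAULT_TARGET_SIZES)
    unknown = set(sizes) - set(SCENARIO_ORDER)
    if unknown:
        raise ValidationError(f"unknown scenarios in target_sizes: {sorted(unknown)}")
    if sum(sizes.values()) != len(corpus):
        raise ValidationError(
            f"target sizes sum to {sum(sizes.values())} but corpus has "
            f"{len(corpus)} sections"
        )
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {"short": [], "long": []}
    for sid in sorted(corpus.sections):
        strata[corpus.sections[sid].length_class].append(sid)

    grand_total = len(corpus)
    quotas = {
        name: _largest_remainder_quotas(sizes, len(members), grand_total)
        for name, members in strata.items()
    }
    # reconcile rounding across strata so every scenario hits its target
    for sc in sizes:
        total = sum(quotas[name][sc] for name in strata)
        while total > sizes[sc]:
            donor = max(strata, key=lambda n: quotas[n][sc])
            receiver = min(
                (s for s in sizes if sum(quotas[n][s] for n in strata) < sizes[s]),
                key=lambda s: SCENARIO_ORDER.index(s),
            )
            quotas[donor][sc] -= 1
            quotas[donor][receiver] += 1
            total -= 1

    assignment: dict[str, str] = {}
    for name, members in strata.items():
        members = list(members)
        rng.shuffle(members)
        deal_order = [
            sc
            for sc in SCENARIO_ORDER
            if sc in sizes
            for _ in range(quotas[name][sc])
        ]
        # interleave scenarios instead of dealing in blocks
        round_robin: list[str] = []
        remaining = {sc: quotas[name][sc] for sc in sizes}
        while any(remaining.values()):
            for sc in SCENARIO_ORDER:
                if remaining.get(sc, 0) > 0:
                    round_robin.append(sc)
                    remaining[sc] -= 1
        assert len(round_robin) == len(deal_order)
        for sid, sc in zip(members, round_robin):
            assignment[sid] = sc

    plan = ScenarioPlan(assignment=assignment, target_sizes=sizes)
    plan.validate()
    return plan


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class UsabilitySummary:
    per_participant: dict[str, float]
    per_scenario: dict[str, float]
    group_means: dict[str, float]


@dataclass
class UsabilityResponses:
    """Ratings on a 5-point ease-of-use scale, per participant and scenario."""

    ratings: dict[tuple[str, str], int] = field(default_factory=dict)

    def validate(self) -> None:
        for (p, s), r in self.ratings.items():
            if not 1 <= r <= 5:
                raise ValidationError(f"rating {r} for ({p}, {s}) outside 1-5")

    def participants(self) -> list[str]:
        return sorted({p for p, _ in self.ratings})

    def scenarios(self) -> list[str]:
        return sorted({s for _, s in self.ratings})


def summarize_usability(
    resp: UsabilityResponses,
    groups: dict[str, str] | None = None,
) -> UsabilitySummary:
    """Margin means of the ratings grid, half-up to 2 decimals.

    Requires a complete participants x scenarios grid.  ``groups`` maps each
    participant to a group name ("expert"/"nonexpert"); when omitted it is
    inferred from the participant id prefix.  A group mean is the mean of
    all of that group's ratings.
    """
    resp.validate()
    participants = resp.participants()
    scenarios = resp.scenarios()
    missing = [
        (p, s)
        for p in participants
        for s in scenarios
        if (p, s) not in resp.ratings
    ]
    if missing:
        raise ValidationError(f"missing usability cells: {missing}")
    if groups is None:
        groups = {
            p: ("nonexpert" if p.lower().startswith("non") else "expert")
            for p in participants
        }
    per_participant = {
        p: _round2(
            sum(resp.ratings[(p, s)] for s in scenarios) / len(scenarios)
        )
        for p in participants
    }
    per_scenario = {
        s: _round2(
            sum(resp.ratings[(p, s)] for p in participants) / len(participants)
        )
        for s in scenarios
    }
    group_means: dict[str, float] = {}
    for g in sorted(set(groups.values())):
        vals = [
            r for (p, _s), r in resp.ratings.items() if groups.get(p) == g
        ]
        group_means[g] = _round2(sum(vals) / len(vals))
    return UsabilitySummary(
        per_participant=per_participant,
        per_scenario=per_scenario,
        group_means=group_means,
    )


def tally_time_categories(
    reports: dict[tuple[str, str], str]
) -> pd.DataFrame:
    """Participant x time-category contingency table of self-reported times."""
    for (p, s), cat in reports.items():
        if cat not in TIME_CATEGORIES:
            raise ValidationError(
                f"unknown time category {cat!r} for ({p}, {s})"
            )
    participants = sorted({p for p, _ in reports})
    table = pd.DataFrame(
        0, index=participants, columns=list(TIME_CATEGORIES), dtype=int
    )
    for (p, _s), cat in reports.items():
        table.loc[p, cat] += 1
    table.index.name = "participant"
    return table


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("pddikit.data").joinpath(name)) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_reported_ratings() -> UsabilityResponses:
    """The study's reported ease-of-use ratings, as packaged."""
    df = _read_fixture("usability_ratings.tsv")
    return UsabilityResponses(
        ratings={
            (str(r.participant), str(r.scenario)): int(r.rating)
            for _, r in df.iterrows()
        }
    )


def load_reported_times() -> dict[tuple[str, str], str]:
    """The study's reported completion-time categories, as packaged."""
    df = _read_fixture("completion_times.tsv")
    return {
        (str(r.participant), str(r.scenario)): str(r.category)
        for _, r in df.iterrows()
    }


def write_plan_tsv(plan: ScenarioPlan, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["section_id", "scenario"])
        for sid in sorted(plan.assignment):
            w.writerow([sid, plan.assignment[sid]])
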