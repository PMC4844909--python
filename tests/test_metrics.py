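"""Matching rule, one-to-one pairing vs a brute-force oracle, and P/R/F1."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pddikit import (
    AnnotationSet,
    DrugReference,
    PDDIMention,
    compute_metrics,
    is_match,
    match_sets,
)
from pddikit.metrics import LabelMetrics, MetricsReport, _match_lists, round_half_up
from pddikit.model import Corpus

from .conftest import make_section


def pddi(sid, sentences, precip="A", obj="B", modality="positive",
         statement="qualitative"):
    return PDDIMention(
        section_id=sid,
        sentence_indices=frozenset(sentences),
        precipitant=DrugReference(precip, "active_ingredient"),
        object=DrugReference(obj, "active_ingredient"),
        statement=statement,
        modality=modality,
    )


class TestIsMatch:
    def test_identical_mentions_match(self):
        assert is_match(pddi("s", {1}), pddi("s", {1}))

    def test_partial_sentence_overlap_suffices(self):
        assert is_match(pddi("s", {1, 2}), pddi("s", {2}))

    def test_disjoint_sentences_do_not_match(self):
        assert not is_match(pddi("s", {1}), pddi("s", {2}))

    def test_modality_must_match(self):
        assert not is_match(
            pddi("s", {1}, modality="positive"), pddi("s", {1}, modality="negative")
        )

    def test_statement_deliberately_ignored(self):
        assert is_match(
            pddi("s", {1}, statement="quantitative"),
            pddi("s", {1}, statement="qualitative"),
        )

    def test_roles_are_directional(self):
        assert not is_match(
            pddi("s", {1}, precip="A", obj="B"), pddi("s", {1}, precip="B", obj="A")
        )

    def test_different_sections_false_by_contract(self):
        assert not is_match(pddi("s1", {1}), pddi("s2", {1}))


class TestMatchSets:
    def test_identical_sets_fully_paired(self):
        refs = [pddi("s", {i}) for i in range(3)]
        res = _match_lists(list(refs), refs)
        assert res.tp == 3 and not res.candidate_fp and not res.reference_fn

    def test_duplicate_candidates_count_once(self):
        ref = [pddi("s", {1})]
        cands = [pddi("s", {1}), pddi("s", {1, 2})]
        res = _match_lists(cands, ref)
        assert res.tp == 1
        assert len(res.candidate_fp) == 1

    def test_counts_conserve_set_sizes(self):
        cands = [pddi("s", {1}), pddi("s", {2}), pddi("s", {5})]
        refs = [pddi("s", {2}), pddi("s", {3})]
        res = _match_lists(cands, refs)
        assert res.tp + len(res.candidate_fp) == len(cands)
        assert res.tp + len(res.reference_fn) == len(refs)

    def test_augmentation_beats_naive_greedy(self):
        # a pure first-match greedy would pair the {0,1} candidate with ref
        # {0} and strand the {0} candidate; maximum matching pairs both
        refs = [pddi("s", {0}), pddi("s", {1})]
        cands = [pddi("s", {0, 1}), pddi("s", {0})]
        res = _match_lists(cands, refs)
        assert res.tp == 2


def brute_force_max_matching(cands, refs) -> int:
    """Independent oracle: exhaustive search for the largest one-to-one pairing."""
    edges = [
        [j for j, r in enumerate(refs) if is_match(c, r)] for c in cands
    ]

    def best(i: int, used: frozenset) -> int:
        if i == len(cands):
            return 0
        top = best(i + 1, used)
        for j in edges[i]:
            if j not in used:
                top = max(top, 1 + best(i + 1, used | {j}))
        return top

    return best(0, frozenset())


def realize_instance(adjacency: np.ndarray):
    """Build mention lists whose is_match graph equals the 0/1 adjacency."""
    n_c, n_r = adjacency.shape
    edge_id = {}
    for ci in range(n_c):
        for rj in range(n_r):
            if adjacency[ci, rj]:
                edge_id[(ci, rj)] = len(edge_id)
    base = len(edge_id)
    cands = [
        pddi(
            "s",
            {edge_id[(ci, rj)] for rj in range(n_r) if adjacency[ci, rj]}
            | {base + ci},
        )
        for ci in range(n_c)
    ]
    refs = [
        pddi(
            "s",
            {edge_id[(ci, rj)] for ci in range(n_c) if adjacency[ci, rj]}
            | {base + n_c + rj},
        )
        for rj in range(n_r)
    ]
    return cands, refs


def test_matcher_equals_oracle_on_all_instances_up_to_3x3():
    for n_c, n_r in itertools.product(range(4), range(4)):
        if n_c * n_r > 9 or (n_c == 0 and n_r == 0):
            continue
        for bits in range(2 ** (n_c * n_r)):
            adj = np.array(
                [(bits >> k) & 1 for k in range(n_c * n_r)]
            ).reshape(n_c, n_r)
            cands, refs = realize_instance(adj)
            assert _match_lists(cands, refs).tp == brute_force_max_matching(
                cands, refs
            )


def test_matcher_equals_oracle_on_random_instances_up_to_8x8():
    rng = np.random.default_rng(2024)
    for _ in range(150):
        n_c = int(rng.integers(1, 9))
        n_r = int(rng.integers(1, 9))
        adj = (rng.random((n_c, n_r)) < rng.uniform(0.1, 0.6)).astype(int)
        cands, refs = realize_instance(adj)
        assert _match_lists(cands, refs).tp == brute_force_max_matching(cands, refs)


def test_adding_candidates_moves_recall_monotonically():
    refs = [pddi("s", {i}) for i in range(4)]
    cands = [pddi("s", {0}), pddi("s", {1})]

    def recall(c):
        res = _match_lists(c, refs)
        return res.tp / len(refs)

    base = recall(cands)
    assert recall(cands + [pddi("s", {9})]) == base  # non-matching: no change
    assert recall(cands + [pddi("s", {2})]) > base  # matching: increases


class TestComputeMetrics:
    @pytest.fixture
    def corpus(self):
        sections = {
            sid: make_section(sid, "One. Two. Three. Four. Five. Six.")
            for sid in ("a", "b", "c", "d")
        }
        return Corpus(
            sections=sections,
            scenario_assignment={"a": "1", "b": "1", "c": "2", "d": "2"},
        )

    def test_perfect_label(self, corpus):
        refs = AnnotationSet("r", "reference", pddi_mentions=[pddi("a", {0}), pddi("a", {1})])
        res = match_sets(refs, refs, corpus)
        report = compute_metrics(res, corpus)
        m = report.per_label["a"]
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_half_metrics_closed_form(self, corpus):
        cands = AnnotationSet("c", "nlp", pddi_mentions=[pddi("a", {0}), pddi("a", {5})])
        refs = AnnotationSet("r", "reference", pddi_mentions=[pddi("a", {0}), pddi("a", {2})])
        report = compute_metrics(match_sets(cands, refs, corpus), corpus)
        m = report.per_label["a"]
        assert (m.precision, m.recall, m.f1) == (0.5, 0.5, 0.5)

    def test_zero_candidates_excludes_precision_recall_zero(self, corpus):
        cands = AnnotationSet("c", "nlp")
        refs = AnnotationSet("r", "reference", pddi_mentions=[pddi("a", {0})])
        report = compute_metrics(match_sets(cands, refs, corpus), corpus)
        m = report.per_label["a"]
        assert m.precision is None
        assert m.recall == 0.0

    def test_scenario_means_are_unweighted(self, corpus):
        # scenario 1: labels a (P=1) and b (P=0.5): mean 0.75
        cands = AnnotationSet(
            "c",
            "nlp",
            pddi_mentions=[pddi("a", {0}), pddi("b", {0}), pddi("b", {5})],
        )
        refs = AnnotationSet(
            "r",
            "reference",
            pddi_mentions=[pddi("a", {0}), pddi("b", {0}), pddi("c", {0})],
        )
        report = compute_metrics(match_sets(cands, refs, corpus), corpus)
        assert report.per_scenario["1"]["precision"] == 0.75
        assert report.per_scenario["1"]["recall"] == 1.0
        # scenario 2: only c appears (zero candidates there)
        assert report.per_scenario["2"]["precision"] is None
        assert report.per_scenario["2"]["recall"] == 0.0
        # label d untouched: excluded entirely
        assert "d" not in report.per_label

    def test_macro_average_matches_planted_count_oracle(self):
        rng = np.random.default_rng(5)
        sections = {
            f"s{i}": make_section(f"s{i}", "A. B. C.") for i in range(10)
        }
        assignment = {f"s{i}": str(1 + i % 2) for i in range(10)}
        corpus = Corpus(sections=sections, scenario_assignment=assignment)
        counts = {
            f"s{i}": (int(rng.integers(1, 5)), int(rng.integers(0, 3)),
                      int(rng.integers(0, 3)))
            for i in range(10)
        }
        report = MetricsReport(
            per_label={s: LabelMetrics(*c) for s, c in counts.items()},
            label_scenario=assignment,
        )
        # spreadsheet-style oracle over the planted counts
        for scenario in ("1", "2"):
            labels = [s for s in counts if assignment[s] == scenario]
            expect_p = sum(
                counts[s][0] / (counts[s][0] + counts[s][1]) for s in labels
            ) / len(labels)
            assert report.per_scenario[scenario]["precision"] == pytest.approx(expect_p)
        expect_r = sum(
            c[0] / (c[0] + c[2]) for c in counts.values()
        ) / len(counts)
        assert report.overall["recall"] == pytest.approx(expect_r)

    def test_f1_between_min_and_max_of_p_and_r(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            tp, fp, fn = (int(x) for x in rng.integers(0, 10, size=3))
            m = LabelMetrics(tp, fp, fn)
            if m.precision is None or m.recall is None or m.f1 is None:
                continue
            lo, hi = sorted((m.precision, m.recall))
            assert lo - 1e-12 <= m.f1 <= hi + 1e-12


def test_display_rounding_is_half_up():
    assert round_half_up(0.625, 2) == 0.63
    assert round_half_up(0.664999, 2) == 0.66
    assert round_half_up(2.0 / 3.0, 2) == 0.67
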