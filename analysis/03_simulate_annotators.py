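#!/usr/bin/env python
"""Simulate the NLP preannotation and the four annotators.

Rebuilds the study deterministically, samples an NLP output at the
scenario-3-implied operating point, and samples each annotator twice: an
assisted pass (used for the preannotation-assisted scenario) and an
unassisted pass (used for the other scenarios).  The composite per-annotator
set takes assisted behavior on scenario-3 sections and unassisted behavior
elsewhere.  Writes all annotation sets under scratch/study/.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ANNOTATOR_PROFILES, SCRATCH, SEED, STUDY_CONFIG  # noqa: E402

from pddikit import (
    AnnotationSet,
    assign_scenarios,
    generate_corpus,
    simulate_annotator,
    simulate_nlp,
)
from pddikit.io import write_annotations


def main() -> None:
    study = generate_corpus(STUDY_CONFIG)
    plan = assign_scenarios(study.corpus, seed=SEED)
    study.corpus.scenario_assignment = plan.assignment
    scenario3 = set(study.corpus.scenario_sections("3"))

    nlp = simulate_nlp(study, rng=np.random.default_rng(SEED + 1))
    SCRATCH.mkdir(parents=True, exist_ok=True)
    write_annotations(nlp, SCRATCH / "nlp.json", study.corpus)

    for k, (name, profile) in enumerate(sorted(ANNOTATOR_PROFILES.items())):
        assisted = simulate_annotator(
            study, nlp, f"{name}-assisted", profile=profile, assisted=True,
            rng=np.random.default_rng(SEED + 100 + k),
        )
        unassisted = simulate_annotator(
            study, nlp, f"{name}-unassisted", profile=profile, assisted=False,
            rng=np.random.default_rng(SEED + 200 + k),
        )
        composite = AnnotationSet(source_id=name, source_kind="human")
        composite.pddi_mentions = [
            m for m in assisted.pddi_mentions if m.section_id in scenario3
        ] + [
            m for m in unassisted.pddi_mentions if m.section_id not in scenario3
        ]
        for aset, suffix in ((assisted, "assisted"), (composite, "composite")):
            write_annotations(aset, SCRATCH / f"{name}-{suffix}.json", study.corpus)
        n3 = sum(1 for m in composite.pddi_mentions if m.section_id in scenario3)
        print(
            f"{name}: {len(composite.pddi_mentions)} mentions "
            f"({n3} in the assisted scenario)"
        )
    print(f"NLP: {len(nlp.pddi_mentions)} PDDI mentions")
    print(f"Annotation sets written to {SCRATCH}")


if __name__ == "__main__":
    main()
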