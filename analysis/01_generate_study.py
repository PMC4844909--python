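#!/usr/bin/env python
"""Generate the synthetic study corpus and reference standard.

Writes the corpus (manifest + section texts), lexicon and reference
annotation set under scratch/study/, assigns the four annotation scenarios
balanced on section length, and records a composition summary under
results/.
"""

from __future__ import annotations

import collections
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, SEED, STUDY_CONFIG  # noqa: E402

from pddikit import assign_scenarios, generate_corpus, write_corpus, write_lexicon
from pddikit.design import write_plan_tsv
from pddikit.io import write_annotations


def main() -> None:
    study = generate_corpus(STUDY_CONFIG)
    plan = assign_scenarios(study.corpus, seed=SEED)
    study.corpus.scenario_assignment = plan.assignment

    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    write_corpus(study.corpus, SCRATCH)
    write_lexicon(study.lexicon, SCRATCH / "lexicon.tsv", SCRATCH / "relations.tsv")
    write_annotations(study.reference, SCRATCH / "reference.json", study.corpus)
    write_plan_tsv(plan, RESULTS / "scenario_plan.tsv")

    mix = collections.Counter(
        d.entity_type for d in study.reference.drug_mentions
    )
    summary = pd.DataFrame(
        [
            {"quantity": "sections", "count": len(study.corpus)},
            {"quantity": "annotated_sections",
             "count": sum(1 for s in plan.assignment.values() if s != "training")},
            {"quantity": "pddi_mentions", "count": len(study.reference.pddi_mentions)},
            {"quantity": "active_ingredient_mentions",
             "count": mix["active_ingredient"]},
            {"quantity": "drug_product_mentions", "count": mix["drug_product"]},
            {"quantity": "metabolite_mentions", "count": mix["metabolite"]},
        ]
    )
    summary.to_csv(RESULTS / "corpus_composition.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nScenario counts: {plan.counts()}")
    print(f"Corpus written to {SCRATCH}")


if __name__ == "__main__":
    main()
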