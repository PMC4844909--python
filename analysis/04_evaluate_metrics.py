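#!/usr/bin/env python
"""Score every simulated annotator and the NLP against the reference standard.

Per-label (section) precision/recall/F1, macro-averaged by scenario — the
study's evaluation design — computed from the annotation sets written by
03_simulate_annotators.py.  Writes results/scenario_metrics.tsv.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ANNOTATOR_PROFILES, RESULTS, SCRATCH  # noqa: E402

from pddikit import compute_metrics, load_corpus, match_sets, read_annotations
from pddikit.metrics import round_half_up


def main() -> None:
    corpus = load_corpus(SCRATCH / "manifest.json")
    reference = read_annotations(SCRATCH / "reference.json", corpus)
    sources = {"nlp": SCRATCH / "nlp.json"}
    for name in ANNOTATOR_PROFILES:
        sources[name] = SCRATCH / f"{name}-composite.json"

    rows = []
    for source, path in sources.items():
        candidate = read_annotations(path, corpus)
        report = compute_metrics(match_sets(candidate, reference, corpus), corpus)
        for scenario, summary in report.per_scenario.items():
            if scenario == "training":
                continue
            rows.append({"annotator": source, "scenario": scenario, **summary})
        rows.append({"annotator": source, "scenario": "overall", **report.overall})
    df = pd.DataFrame(rows)
    for col in ("precision", "recall", "f1"):
        df[col] = df[col].map(lambda v: None if v is None else round_half_up(v, 2))
    RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(RESULTS / "scenario_metrics.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(
        "\nAssistance only operates in scenario 3; the simulated annotators' "
        "scenario-3 F1 reflects the planted correction rates against the "
        "low-operating-point NLP."
    )


if __name__ == "__main__":
    main()
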