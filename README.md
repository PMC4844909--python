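# pddikit

Tools for studying how humans and NLP pipelines annotate **pharmacokinetic
drug–drug interactions (PDDIs)** in drug product labeling.

Free-text structured product labels (SPLs) are a primary — but incomplete
and hard-to-compute — source of PDDI information. One line of research asks
whether curation can be scaled up by (a) recruiting nonexpert annotators and
(b) showing them machine *preannotations* to correct, and evaluates both
against an expert-consensus reference standard. `pddikit` implements the
computational core of such an annotation study as a reusable, tested
library:

- **Data model & interchange** — label sections with canonical sentence
  segmentation; typed drug mentions (active ingredient, metabolite, drug
  product) with RxNorm-style normalization of sole-ingredient products; PDDI
  mentions anchoring a precipitant/object drug pair plus statement type
  (quantitative vs qualitative) and modality (positive vs negative) to a set
  of sentences; Open-Annotation-style JSON serialization
  (`pddikit.model`, `pddikit.io`, `pddikit.lexicon`).
- **Preannotation pipeline** — deterministic dictionary NER
  (case-insensitive, token-anchored, longest-leftmost) with entity-type
  filtering and product→ingredient normalization, followed by a transparent
  rule-based sentence-level PDDI extractor (cue co-occurrence, negation
  scoping, magnitude detection, active/passive role frames)
  (`pddikit.ner`, `pddikit.rules`).
- **Evaluation** — the study's matching rule (same precipitant, object and
  modality; sentence sets at least partially overlapping; statement type
  deliberately ignored), one-to-one maximum matching per section, and
  per-label precision/recall/F₁ macro-averaged by scenario
  (`pddikit.metrics`).
- **Agreement analysis** — three-way user/NLP/reference cross-tabulations:
  for each reference mention, whether NLP and the user found it; for each
  NLP false positive, whether the user kept it; user-only false positives
  as a bare count (`pddikit.agreement`).
- **Study design** — scenario assignment balanced on section length, and the
  descriptive summaries (usability means, completion-time tallies)
  (`pddikit.design`).
- **Simulation** — a synthetic corpus generator (templated label prose with
  planted mentions), an NLP simulator with a configurable sentence-level
  recall/precision operating point (defaults 0.81/0.86), and a four-rate
  annotator behavior model, all tracked by a ground-truth ledger that
  downstream agreement tables must reproduce exactly (`pddikit.synth`).

## The metrics at the core

For candidate set *C* and reference set *R* on one label section, a
candidate *c* matches reference *r* iff

> precip(c) = precip(r) ∧ obj(c) = obj(r) ∧ mod(c) = mod(r) ∧
> sent(c) ∩ sent(r) ≠ ∅

with drug identity on normalized ingredient ids. TP is the size of a
maximum one-to-one matching under this predicate; then per label
P = TP/(TP+FP), R = TP/(TP+FN), F₁ = 2PR/(P+R), and scenario scores are
unweighted means over labels. Agreement tables cross-classify each
reference mention by NLP outcome × user outcome (4 cells summing to *N*),
and split the NLP false-positive pool by user acceptance.

## Worked example

```python
from pddikit import (GeneratorConfig, generate_corpus, run_pipeline,
                     match_sets, compute_metrics)

study = generate_corpus(GeneratorConfig(n_sections=12, seed=1))
sec = next(iter(study.corpus.sections.values()))
print(sec.sentence_text(1))

nlp = run_pipeline(study.corpus, study.lexicon)
res = match_sets(nlp, study.reference, study.corpus)
print(len(study.reference.pddi_mentions), res.tp, len(res.candidate_fp))
print(compute_metrics(res, study.corpus).overall)
```

prints

```
The clearance of Danasartan was reduced by Lastiol.
36 36 0
{'precision': 1.0, 'recall': 1.0, 'f1': 1.0}
```

The generator planted 36 PDDI statements in grammar-clean prose; the rule
pipeline recovers every one (the sampled sentence is a passive frame, so
Lastiol — the drug after "by" — is the precipitant and Danasartan the
object). Re-generating with `paraphrase_noise`/`cue_distractor_noise` > 0
degrades recall and precision monotonically; see
`analysis/02_preannotate.py`.

## Command line

```bash
pddikit generate --seed 5 --out study/          # synthetic study bundle
pddikit preannotate --corpus study/manifest.json --lexicon study/lexicon.tsv \
    --relations study/relations.tsv -o nlp.json
pddikit evaluate --candidate nlp.json --reference study/reference.json \
    --corpus study/manifest.json -o metrics.tsv
pddikit agreement --user study/annotator-1.json --nlp study/nlp.json \
    --reference study/reference.json --corpus study/manifest.json -o agreement.tsv
pddikit plan --corpus study/manifest.json --seed 0 -o plan.tsv
pddikit validate study/reference.json --corpus study/manifest.json
```

## Analysis scripts

`analysis/01_generate_study.py` … `analysis/06_study_summaries.py` walk the
full study: generate the 208-section corpus and scenario plan, run and
stress the preannotation pipeline, simulate the NLP and four annotators
(behavioral rates read off the study's reported agreement rows), score
everyone per scenario, build agreement tables, and recompute the
descriptive summaries. Small result tables land in `results/`; bulk
corpora in `scratch/`.

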