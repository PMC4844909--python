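# Methods

This note documents the models, rules and numerical choices behind
`pddikit`, and what the synthetic experiments do and do not show.

## The annotation model

A corpus is a set of product-label **sections**; each section is segmented
into sentences exactly once, at load time, and every downstream consumer
shares those sentence indices. Character offsets are 0-based and half-open
(a convention choice, stated in the interchange schema). A **drug mention**
is a typed span — active ingredient, metabolite, or drug product — with a
lexicon concept id and a normalized ingredient id: a drug product with a
known sole-active-ingredient relation normalizes to that ingredient;
products without such a relation keep their own id and are flagged. A
**PDDI mention** anchors a precipitant/object pair of normalized drug
references to a non-empty set of sentence indices (multi-sentence
selections need not be contiguous — annotators select freely) and carries a
statement type (quantitative: a magnitude is given; qualitative: direction
only) and a modality (positive claim vs explicit denial). Serialization is
Open-Annotation-inspired JSON — target with section id and position
selectors quoting the exact text, plus a typed body — not full JSON-LD;
unknown body keys round-trip through a pass-through slot.

Sentence identity by index (rather than raw offsets) makes the
"partially or exactly overlapping sentences" part of the matching rule
decidable; the cost is that sets from different segmentations are not
comparable, which the pipeline avoids by segmenting once at corpus load.

## Sentence segmentation

Rule-based: a sentence ends at `.`/`!`/`?` followed by whitespace and an
upper-case letter, digit, or end of text, unless the terminating token is
in a packaged abbreviation list ("e.g.", "i.v.", "Dr.", …). Decimal points
and in-token periods never split. Properties enforced by tests: spans are
sorted, non-overlapping, cover every non-whitespace character exactly once,
and the procedure is deterministic.

## Dictionary NER

Case-insensitive longest-leftmost matching of all lexicon surface forms
(preferred names plus synonyms), anchored at token boundaries; token
characters are `[0-9A-Za-z-]`, so hyphens are internal to tokens ("warfarin"
does not match inside "warfarin-treated", and hyphenated drug names match
whole). Ties at one start position go to the longest surface ("warfarin
sodium" beats "warfarin"); scanning resumes after each match, so spans never
overlap. Matches typed `non_drug` are consumed and discarded — this models
an entity-type postfilter over a noisy terminology hit list. Ambiguous
surfaces resolve to the first lexicon entry, deterministically.

## Rule-based PDDI extraction

A stand-in for a learned classifier, chosen for transparency: every rule is
inspectable and its term lists ship as editable TSV files.

Per sentence window (size 1 by default, 2 optionally), a window is
PDDI-positive iff **two distinct normalized ingredients co-occur** and at
least one **pharmacokinetic cue** stem occurs (AUC, clearance,
concentration, half-life, pharmacokinetic-, inhibit-, induce-, increase-,
decrease-, reduce-, elevate-, prolong-). Then:

- **modality** = negative iff a negation cue occurs in the window
  ("no effect", "did not", "no significant", "not altered", …);
- **statement** = quantitative iff a numeric magnitude matches
  (`45%`, `30 percent`, `5-fold`, `3 times`);
- **roles**: a passive frame (`was/were/is/are … <verb> … by` with exactly
  one of the pair after the `by`) makes the post-`by` drug the precipitant;
  otherwise an active frame (a causative verb with one drug before and the
  other after) makes the pre-verb drug the precipitant; otherwise the
  first-mentioned drug is the precipitant — an explicit, logged fallback,
  since role assignment is undecidable for cue-only sentences.

One mention is emitted per unordered drug pair per window, anchored to the
sentences actually containing the pair's first mentions. The pipeline
(NER → extraction over every section in sorted order) is deterministic:
identical inputs and configuration give byte-identical serialized output.
The frames and term lists are this package's own formalization; no claim is
made that they replicate any particular production classifier, whose
published operating points are used here only as simulation parameters.

## Matching and metrics

A candidate matches a reference mention iff section, normalized precipitant
id, normalized object id and modality all agree and the sentence sets
intersect. Statement type is deliberately excluded from the criterion.
Because identity is on normalized ids, a drug-product candidate matches an
active-ingredient reference of its sole ingredient — mirroring the
pipeline's normalization.

Pairing is one-to-one per section. A purely greedy first-match pairing can
be strictly smaller than the maximum matching (candidates with sentence
sets {0,1} and {0} against references {0} and {1}: greedy in first-sentence
order strands the second candidate), so `match_sets` seeds candidates in
(first sentence, precipitant) order and completes the pairing with
augmenting paths (Kuhn's algorithm). This is deterministic and always
attains the maximum matching size, which tests verify against a brute-force
enumeration oracle on all bipartite structures up to 3×3 and random
structures up to 8×8.

Metrics are computed per label section and macro-averaged, unweighted,
within scenario and overall. Undefined metrics are excluded rather than
imputed: a label with neither reference nor candidate mentions does not
appear; with references but no candidates, precision is excluded and recall
is 0 (symmetrically for the FP-only case); F₁ is defined only where both P
and R are. This avoids arbitrary 0/0 conventions. Display rounding is
half-up to 2 decimals.

## Agreement tables

For one scenario's sections, each reference mention is classified by NLP
outcome × user outcome (via `match_sets` against the reference), giving
four cells that always sum to the reference count. NLP mentions unmatched
to the reference form the NLP false-positive pool; user mentions unmatched
to the reference are matched one-to-one against that pool (the same
matching rule, with the NLP mentions in the reference role) to split it
into user-accepted vs user-rejected; user mentions matching neither are
reported as a bare count, which has no natural denominator. Percentages
are `100·cell/denominator` rounded half-up to one decimal; integral
percentages print without a trailing `.0` (so 93/93 renders "(100)"), and a
zero denominator yields an explicit undefined marker, never 0.

## Scenario assignment

Sections are stratified short/long at the median section length (the
natural two-class reading of "long and short"; finer stratification is
possible by supplying a different corpus `length_class`). Per-scenario
stratum quotas come from largest-remainder apportionment, reconciled so
every scenario hits its exact target size; within each stratum sections are
shuffled with the seed and dealt round-robin. Compared with sort-and-deal
followed by trim/fill, the quota construction achieves the same ±1 balance
guarantee without a repair pass. Defaults: training 3, scenarios 52/52/53/48
from a 208-section corpus, leaving 205 annotated sections.

Usability summaries are plain margin means on a complete participants ×
scenarios grid, half-up to 2 decimals; a group mean is the mean of all of
that group's ratings (so the nonexpert group mean is over nine ratings).
The packaged ratings grid follows the study's tabulated per-cell values;
where its narrative summary disagrees with the table, the table is taken as
authoritative and the discrepancy left unresolved. Completion-time reports
are tallied into a participant × category contingency table over the
closed set {<1h, 1–3h, 3–5h, >5h}. The repeat-unassisted scenario exists
only as a labeled split; no longitudinal statistic is computed.

## The synthetic study

**Corpus.** Each section is templated prose: an opening and closing
sentence, 2–4 planted PDDI sentences, one metabolite sentence, one
(sometimes two) drug-product sentences, two two-drug non-PDDI sentences,
and 4–7 single-drug sentences, shuffled. Drug names are generated
pronounceable single tokens (ingredient/product/metabolite morphology),
screened against template and cue vocabulary so NER and cue detection stay
exact. PDDI sentences are rendered from the extractor's own rule grammar —
active, passive, negated and quantitative variants — so on a noise-free
corpus the pipeline is exact by construction, and `precision = recall = 1`
is a *consistency* check between generator and extractor, not evidence
about real label prose. Two noise channels break that consistency
deliberately: `paraphrase_noise` rephrases planted statements outside the
grammar (recall decays) and `cue_distractor_noise` adds cue terms to
two-drug distractors (precision decays); degradation is monotone in the
rate.

Default composition (205 sections) is calibrated to a reference standard of
~607 PDDI mentions with an active-ingredient : product : metabolite mention
mix of roughly 3351 : 234 : 201; generated totals land within 10% of each.
The negative-modality rate (0.12) and quantitative rate (0.5) are package
choices — plausible for interaction sections, where most statements assert
an interaction and magnitudes are common — as the composition of real
reference standards by modality/statement is not published.

**NLP simulator.** Each reference mention is emitted independently with
probability `nlp_sentence_recall`; per emitted mention, false positives are
drawn as `⌊q⌋ + Bernoulli(q−⌊q⌋)` with `q = (1−p)/p`, so expected precision
is `p`. Defaults 0.81/0.86 follow published sentence-level performance of a
PDDI extraction system (a document-level pair, 0.84/0.88, is the known
alternative; the sentence-level pair matches the sentence-anchored model
here). False positives are realized at the planted two-drug non-PDDI
sentences, so they are plausible (two co-mentioned drugs) and can never
accidentally match a reference mention (disjoint sentences). The per-section
site capacity bounds the simulable FP load: very low precision or high
spontaneous-FP rates need `fp_sites_per_section` raised above the default 2
(the analysis configuration uses 3 for its 0.31-precision operating point).

**Annotator simulator.** Four rates: fix an NLP miss (`p_fix_nlp_fn`), drop
an NLP hit (`p_drop_nlp_tp`), accept an NLP false positive
(`p_accept_nlp_fp`), and invent spontaneous false positives per section
(Poisson rate, realized at unused sites). This is the minimal model whose
cell expectations are exactly the agreement-table cells; defaults are
calibrated to reported nonexpert behavior (fix ≈ 0.58, drop ≈ 0.26, accept
≈ 0.054, ≈ 0.3 spontaneous/section). Unassisted mode reuses `p_fix_nlp_fn`
as base sensitivity rather than adding a fifth parameter (overridable by
passing a different profile). The ledger records every mention's planted
outcome, and `build_agreement` must reproduce the ledger aggregation
cell-for-cell on every run — an exact, not statistical, test.

All randomness flows through `numpy.random.default_rng` seeded from the
configuration, so outputs are byte-identical across runs of the same
version.

**What the simulations do not show.** Real SPL prose is far messier than the
template grammar (tables, enumerations, cross-references, anaphora), real
NER faces terminology ambiguity the synthetic vocabulary avoids by
construction, and real annotators are not stationary Bernoulli processes.
Recovery of planted rates validates the *bookkeeping* (matching, metrics,
agreement arithmetic), not the difficulty of the real task; headline corpus
F₁ values from human studies are accordingly not reproduction targets here.

## Problem sizes and tolerances

Statistical recovery checks run at ≥ 5000 reference mentions (1800
sections) with fixed seeds and 3-binomial-SE tolerances; exhaustive matcher
validation covers all ≤ 3×3 bipartite structures plus 150–200 random
structures up to 8×8; pipeline exactness and ledger identity use 25–40
section corpora. These sizes make the full suite run in seconds while
keeping every statistical check comfortably powered.
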