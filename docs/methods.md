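# Methods

## The measurement model

Each dream report is compared with each of a participant's three task
plans. A plan is represented by its five subtask sentences; a text is
represented by an embedding vector, and similarity is the cosine of the
angle between vectors. Two branches mirror two ways of localizing
incorporation:

* **Whole-text**: the report (optionally summarized first) is embedded
  once; its score against a plan is `max_j cos(report, subtask_j)` over
  the plan's five subtasks. The maximum, not the mean, is used because
  incorporation is expected to touch a single action of a plan, not the
  whole script.
* **Sentence-wise**: every report sentence is embedded (no
  summarization) and scored against every subtask; the per-plan score is
  the maximum of the sentence × subtask matrix. This branch feeds the
  forced choice: the report is allocated to the execution status of the
  plan with the highest score.

Inference is count-based. With threshold θ, a report (or sentence)
counts as incorporating a plan when its score is ≥ θ (inclusive
boundary). Counts per status are tested with the Pearson goodness-of-fit
statistic against equal expected counts, `df = k − 1`, upper-tail p, no
continuity correction, computed on **raw counts**: the printed statistics
of count designs are only recoverable this way, and a chi-square on
normalized proportions is not well-defined. Per-cell proportions
(count / reports available in the cell) are emitted for reporting only.
Pairwise comparisons are 2-cell goodness-of-fit tests, for which the
statistic has the closed form `(a − b)² / (a + b)`; no multiplicity
correction is applied by default (a Bonferroni option exists).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.85 | inclusive incorporation criterion on cosine scores; calibrated to the upper tail of a real contextual encoder's score range. For the non-semantic test embedder, whose scores live near 0–0.4, choose a corpus-quantile or generator-calibrated value instead. |
| `sweep` | 0.75–0.85 | robustness sweep; counts are monotone non-increasing along it |
| `counting_unit` | report | `report` counts reports whose best score passes; `sentence` counts individual sentences (denominators switch accordingly) |
| `EmbedderSpec.dimension` | 256 | hash-bin count of the test backend; larger dimensions reduce collision noise |
| `EmbedderSpec.pooling` | mean_tokens | external backend pooling; mean pooling is the standard choice for semantic similarity with encoder models, first-token pooling is available |
| tie tolerance | 1e−12 | two scores closer than this are an exact tie |

Forced-choice ties are resolved by the fixed priority completed >
interrupted > uncompleted and flagged. The direction is deliberate: the
hypothesis predicts *fewer* completed allocations, so ties can only work
against it, making positive findings conservative. Ties are not rare
with the test embedder, because sentence–subtask pairs with no shared
token can hash to exactly orthogonal vectors.

## The synthetic generator

`GeneratorConfig` encodes the emulated study: 19 participants, 4–6
awakenings each split evenly between REM and N2, 73.5 % dream recall,
reports of 3–10 sentences, and per-sentence incorporation rates of 0.10
(completed) vs 0.30 (uncompleted, interrupted). An incorporating
sentence replaces half its tokens (`mixing_rate = 0.5`) with tokens from
the plan's vocabulary; a sentence incorporates at most one plan. Plan
vocabularies are pairwise disjoint by default; a `plan_vocab_overlap`
knob deliberately reproduces the failure mode of too-similar plans.
Plan-to-status assignment cycles through the six bijections, balancing
plans across statuses as in the emulated design. Report counts arise
from simulated awakenings × recall, so corpus size varies around ~70
reports at the defaults.

The generator produces token-level text, not grammar: that is exactly
what a bag-of-words embedder can see, so it exercises every pipeline
contract, but passing tests say nothing about how a contextual encoder
behaves on real narrative German. Results that depend on real
transcripts and real encoder/summarizer weights — the 0.54–0.90 score
range of the original whole-text analysis, its specific above-criterion
counts — cannot be reproduced here; the package carries such counts only
as printed inputs to the chi-square layer.

## Monte-Carlo validation choices

Two replicate studies (`dreamincorp.validation`) validate the pipeline:

* **Ordering recovery** (planted effect): 100 replicates at 140
  participants (~500 reports each), whole-text branch, criterion at the
  75th percentile of the pooled score distribution — mirroring how the
  real criterion sits in the upper tail of its scale. Success means the
  completed condition has strictly the fewest above-criterion reports.
* **Null calibration** (equal rates 0.30): 500 replicates at 40
  participants (~150 reports), sentence-unit counts at a fixed threshold
  of 0.25, chosen above the background-score upper tail of the generator.
  Two deliberate differences from the ordering arm: (1) *sentence-unit*
  counts are used because each sentence incorporates at most one plan,
  making the status cells multinomial under the null, whereas
  report-level cells are underdispersed by the balanced design (a
  report's three scores share its text, and plan-level quirks cancel
  across statuses), which makes the test conservative; (2) a *fixed*
  threshold is used because a quantile threshold fixes the total count,
  and the boundary cut then trims surplus categories toward equality,
  again deflating the statistic. With these choices the empirical
  rejection rate at α = .05 sits inside the binomial 95 % band.

Problem sizes (replicate counts, participants per replicate) are the
package's chosen study sizes; they keep each study to a few minutes on
one CPU while leaving the binomial bands tight enough to be informative.

## Numerical details and degenerate inputs

* Embeddings are L2-normalized at creation; cosine reduces to a dot
  product and is clipped into [−1, 1] against rounding.
* The test backend hashes tokens with keyed BLAKE2b (the spec seed is
  the key), giving ±1 signs so disjoint-vocabulary texts have expected
  cosine 0; weights are `log(1 + count)`; byte-identical inputs give
  byte-identical vectors.
* Argmax comparisons use exact floating-point equality; only the tie
  band (1e−12) is tolerant.
* Empty text, zero vectors, non-bijective assignments, unknown sleep
  stages, and empty record sets raise named errors; statistical stages
  inside the pipeline degrade to warnings (recorded in the result and
  the run log) so a one-report corpus still yields its score tables.
* Chi-square and one-way ANOVA delegate to scipy (`chisquare`,
  `f_oneway`); the all-identical-groups ANOVA edge case is defined as
  F = 0.
* The within/between score-spread comparison reports sample variances
  (ddof = 1) and their ratio descriptively; no F test is attached, since
  the two variances are computed on structurally different units.
* A corpus matching a printed plan × status report-count matrix is
  constructed by integral Birkhoff–von Neumann decomposition, which
  exists exactly when row and column sums are equal (each report
  contributes one cell per plan row).

## Known limitations

* The default filler lexicon and abbreviation list are small editable
  resources; real transcript editing involves human grammar correction,
  which is out of scope.
* Bullet-to-sentence conversion is template-based and English-templated
  by default; users supply their own template for other languages.
* The summarization stage has no offline implementation; identity is
  the only backend that runs without external weights.
* Sentence-level above-criterion counts can exceed the number of
  reports in a cell (several sentences of one report may pass); both
  counting units are supported and denominators switch accordingly.
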