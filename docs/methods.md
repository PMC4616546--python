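# Methods

## The screening model

The screen treats marker discovery as a deterministic two-sided filter on
reference-normalized expression rather than a differential-expression test.
Expression units (RSEM, RPKM, ...) are opaque non-negative abundances;
dividing each gene by a housekeeping reference gene (*TBP* by default)
within each sample makes cohorts processed in different units comparable.
Samples in which the reference gene reads zero are dropped with a warning
rather than propagated as infinities, which keeps the percentile summaries
finite; a cohort whose reference is zero everywhere is an error.

For a target subtype T with background subtypes B₁…Bₖ, gene G is a hit iff

* median(G | T) > `median_min` (default 8), and
* Pq(G | Bᵢ) < `background_q_max` (default 0.15) for **every** i, where Pq
  is the `percentile`-th percentile (default 95).

The two conditions encode what a diagnostic immunostain needs: robust
expression in the majority of target cases (median, not mean — single
outliers must not rescue a gene), and near-absence even in the upper tail
of every confusable subtype (a 95th percentile, not a mean — 5% of
background cases may stain without destroying specificity). Both
inequalities are strict, matching the "more than" / "less than" definition
of the original operating point. The thresholds are configuration, not
constants: their published values are not derived from any optimality
argument, and other tissue systems will need different ones.

**Percentile convention.** The defining publication of the screen does not
state an interpolation method. The default is linear interpolation between
closest order statistics (sorted x(1..n), position p = 1 + (q/100)(n−1)),
the common default in scientific software; `nearest-rank` (smallest order
statistic with rank ≥ qn/100) is available because genes whose background
percentile sits at the threshold can flip between conventions. Summaries
require at least `min_samples` (default 3) samples per subtype — a median
of one or two cases is not a cohort statistic.

Hits are reported sorted by target median descending with lexicographic
gene-id tie-break, so reports are byte-reproducible.

## IHC diagnostics

Grades are ordinal pairs: intensity ∈ {negative, weak, strong} and
proportion ∈ {none (<1%), partial (1–90%), diffuse (≥90%)}, with
`negative ⇔ none` enforced (a stain with no positive cells has no
intensity, and vice versa). Clinical language fuses the axes ("strong
diffuse positivity", "weak positivity"); the `PositivityRule` abstraction
makes that fusion explicit as an accepted set of grade pairs, so rules are
data, not code. Built-ins:

* `strict` — {(strong, diffuse)};
* `lenient` — {(strong, diffuse), (weak, diffuse), (weak, partial)}.

Enlarging a rule's accepted set can only raise sensitivity and lower
specificity (monotonicity, property-tested). Sensitivity and specificity
are kept as exact rationals internally; display values are half-up rounded
percentages to one decimal. Confidence intervals use the Wilson score
method, chosen because marker validation cohorts routinely hit 0% and
100% proportions where Wald intervals collapse. Tumor types that are not
the diagnostic target but are screened for marker overlap (renal
oncocytoma here) are handled as plain labels via `positivity_rate`, since
sensitivity/specificity against them is not the scientific question.

The package ships `reference_ihc_records()`, the published BSND/ATP6V1G3
grade frequencies across 200 renal tumors (23 chromophobe / 153 clear cell
/ 10 papillary / 14 oncocytoma), reconstructed by exact largest-remainder
apportionment. The published counts do not split the 8 weak ATP6V1G3
clear cell cases between diffuse and partial extent; the reconstruction
uses 4 + 4, which no built-in rule distinguishes.

## Methylation association

Per CpG probe, on the intersection of samples shared by the β table, the
normalized expression matrix and the annotation (missing β excluded
pairwise):

* **Hypomethylation gap.** `delta_median` = min over background subtypes
  of (background median β − target median β); `hypo_flag` is true iff the
  gap strictly exceeds `delta_threshold` (default 0.25). The min
  aggregation requires the target to be hypomethylated relative to *every*
  background, the multi-group analogue of "lower than in both other
  subtypes"; the flag is monotone in the threshold.
* **Kruskal–Wallis** across subtype groups, tie-corrected, p from the
  chi-square approximation with k−1 degrees of freedom. β data is heavily
  tied after platform rounding, so mid-ranks are used everywhere. If all
  pooled observations are identical the tie correction degenerates; by
  convention H = 0, p = 1 with a warning. An exact/permutation mode
  (`exact=True`) is available for small groups (≲10 per group) where the
  chi-square approximation is rough.
* **Spearman ρ** between β and the linked gene's reference-normalized
  expression — the same unit the screen uses — computed pooled over all
  shared samples and within each subtype, both reported, since pooled ρ
  mixes between- and within-subtype coupling. A constant vector leaves ρ
  undefined (NaN with a warning). The p-value uses the t approximation.

Probe→gene linkage is an explicit two-column table; no genome annotation
lookup is performed.

## Synthetic cohorts

`SimulationConfig` defaults define the study conditions used throughout
the tests: 2,000 genes; subtypes chromophobe/clear cell/papillary of
40/300/100 samples; 5 markers planted in chromophobe with hot-subtype
median 15 (log-normal, log-sd 0.2) and all other samples uniform below a
ceiling of 0.05. Background genes are i.i.d. log-normal (log-mean 0,
log-sd 1) with a 30% point mass at zero (dropout), giving the near-zero
background tails the screen exploits while their 95th percentiles stay far
above 0.15 — so null genes essentially never pass condition 2 and planted
recovery has both precision and recall 1 at these effect sizes. Values are
generated on the normalized scale and multiplied back by a strictly
positive per-sample reference value, so normalization recovers the design
exactly. One global seed is split into per-generator streams
(expression/methylation/IHC), making each generator a pure function of the
config and insensitive to draws added in the others.

Coupled CpG probes follow β = clip(0.55 − 0.12·z, 0, 1) + N(0, 0.05),
with z the standardized log1p normalized expression of the planted marker.
At the default cohort sizes this yields a hot-subtype median β ≈ 0.17
versus ≈ 0.59 in the backgrounds (gap ≈ 0.4 > 0.25) and a pooled Spearman
ρ ≈ −0.28 (recorded as `target_rho`). The magnitude is bounded by the
cohort's block structure: with 40 hot among 440 samples, perfect
two-block rank separation alone gives ρ ≈ −0.25, so strongly negative
pooled values are unreachable regardless of noise — a useful reminder that
pooled rank correlations on imbalanced cohorts understate the coupling
visible within the hot subtype (within-chromophobe ρ ≈ −0.6). Null probes
are baseline + N(0, 0.10), independent of expression; ~1% of entries are
masked missing.

What the generator does **not** emulate: batch effects, tumor purity,
platform normalization artifacts, gene–gene correlation, or realistic β
distributions at extreme values. Passing tests therefore demonstrate the
pipeline's correctness and its behavior under the designed signal
structure, not performance on consortium data.

IHC simulation draws one record per case × marker from configured grade
distributions; with `ihc_exact_counts` (default) counts are apportioned by
largest remainder, reproducing a frequency table deterministically, while
multinomial sampling is available for calibration studies.

## Numerical and design choices

* Matrices are dense in memory; the design targets desk-scale cohorts
  (≤ ~25k genes × ~1k samples). Id matching is exact and case-sensitive.
* Input dialect (TSV/CSV) is auto-detected by extension, overridable.
* Output CSVs carry a commented provenance line (tool version +
  parameters); the run manifest `run.json` holds the full parameter set
  and the only timestamp, so repeated runs produce byte-identical CSVs.
* Planted-marker specs that cannot clear the default screen thresholds
  (e.g. hot median 5) are constructible — they are the negative controls
  of recovery tests — and produce a logged warning rather than an error.
* Problem sizes in the test suite: full default cohorts for recovery and
  coupling checks (20 seeds); scaled-down cohorts (a few hundred genes,
  ~70 samples, hot subtype kept the clear minority as in the full design)
  for pipeline plumbing tests.

## Known limitations

* The screen's thresholds are cohort- and unit-specific; there is no
  internal calibration step.
* The Kruskal–Wallis chi-square p and Spearman t-approximation p are
  asymptotic; use the permutation mode for very small groups.
* Pooled Spearman ρ on imbalanced cohorts is structurally bounded (see
  above); per-subtype values should be read alongside it.
* No survival/outcome analysis, no image analysis, no methylation array
  preprocessing: inputs are assumed already processed to expression
  abundances and β values.
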