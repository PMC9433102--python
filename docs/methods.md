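# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data generator does and does
not emulate.

## UMI pipeline

Reads have the layout `barcode + 12-bp UMI + V-tag + CDR3nt + J-tag`.
Demultiplexing is by exact barcode prefix. Reads sharing a UMI within a
sample form one group; consensus calling within a group:

1. Reads whose mean Phred over the UMI region falls below the quality
   floor (default 10) are dropped.
2. Remaining reads are clustered by sequence identity: a read joins the
   first cluster whose representative is within 1 mismatch (equal length
   required). This is the conflict-split rule — genuinely different
   molecules that collided on a UMI stay apart instead of being averaged.
3. Each cluster with at least `min_reads` (default 3) reads emits one
   position-wise majority-vote consensus; ties go to the
   lexicographically smallest base for determinism.

Annotation is near-exact lookup of the flanking 20-nt V/J tags against
the bundled mini-reference (20 V and 10 J segments per chain, synthetic
tags kept ≥5 mismatches apart so lookup at the ≤2-mismatch tolerance is
unambiguous). A full germline alignment is deliberately out of scope:
the reference is synthetic, matching the generator, and annotation
accuracy is exercised by round-trip tests rather than by alignment
heuristics. Records failing V or J lookup, mixing chains, or with
out-of-frame CDR3s are dropped with a count.

Functional filtering removes CDR3s containing stop codons and records
with fewer than 3 supporting reads. Collapse produces one row per
clonotype key with the number of distinct supporting UMIs. Two key
levels exist because the analyses need both: richness and diversity use
chain+V+J+CDR3aa; overlap and decontamination additionally use CDR3nt.

## Decontamination

Two samples sharing an identical (12-bp UMI, nucleotide clonotype) pair
almost certainly reflect physical carry-over: at typical per-sample
diversities of ~1e6 UMIs and ~1e4 TCRs the chance of independent
recurrence is ~1e-10. Collision groups are resolved by PCR amplification
time (an ordinal batch label attached per sample): the unique earliest
record is kept; a tie at the earliest time removes the whole group,
since the true source is then unknowable. Keying is nucleotide-level
because contamination is a property of molecules; amino-acid collapse
would remove convergent clones that merely share a translated junction.

## Cell accounting

Circulating cells of a subset = lymphocytes/µL × subset fraction ×
blood volume. Blood volume is Nadler's anthropometric formula
(male 0.3669·h³ + 0.03219·w + 0.6041 L; female 0.3561·h³ + 0.03308·w +
0.1833 L; h in metres, w in kg). Heights are metres internally with an
explicit cm conversion helper — the cubic height term makes silent unit
mixups the main hazard. The richness projection target is 1/100 of the
subset total (rarefaction-model extrapolation to the full population is
computationally out of reach, so all richness values are "per 1 % of
circulating cells"); rounding is round-half-even and applied only at
that final step.

## Richness extrapolation

The rarefaction curve (mean unique clonotypes vs subsample size) is
estimated by multivariate-hypergeometric resampling (default 1000
resamples; an exact closed form is available and is used in tests as the
infinite-resample oracle). Subsample sizes are ~20 geometrically spaced
points from 1 % of depth to full depth. When samples are compared, a
common normalised depth (minimum total UMI across the set) should be
passed via `depth=`.

Candidate models are 8 named curve forms registered in an extensible
registry: Michaelis–Menten, power, logarithmic, negative exponential,
scaled Weibull CDF, rational 2/1, Gompertz and shifted logistic. This is
a reduced ensemble standing in for the 50-model library of the original
DivE-style approach; what is preserved is the ensemble logic — several
independently fitted saturating forms, scored, filtered and averaged
geometrically — not the exact model inventory. Each model is fitted by
bounded least squares (`scipy.optimize.curve_fit`, trust-region
reflective; per-model initial values and bounds chosen so every form
starts plausible and saturating forms cannot undershoot the observed
richness). Non-convergent models are dropped with a log entry.

Scoring: `100 × (MAPE_fit + MAPE_half)` where MAPE_fit is the mean
absolute percentage error of the full-depth fit and MAPE_half is the
error of a fit to the half-depth curve evaluated at the full-depth
sizes (an internal extrapolation test), plus 1000 per violated
plausibility criterion on the extrapolation interval: the curve must be
non-decreasing, decelerating, and end at or above the observed unique
count. Models scoring above 250 are discarded; the 3 lowest-scoring
models are used, extended to at most 5 while scores stay within 10 % of
the best; the estimate is the geometric mean of their values at the
target population. The numeric score scale is this package's own; the
250 cutoff and 3–5/geometric-mean aggregation follow the published
interface. When no model passes, `RichnessEstimationError` is raised —
an absent estimate must not be silently consumable.

On synthetic log-normal (σ=1.5) populations of richness 5,000 sampled
at 10 % depth, the median estimate over 20 seeds is within a few percent
of truth (the declared acceptance band is ±30 %).

## Inverse Simpson's Index

ISI = 1/λ, λ = Σpᵢ² with pᵢ the UMI fraction of clonotype i. Bounds
1 ≤ ISI ≤ clone count; equality with the clone count under perfect
evenness; concentration of mass strictly lowers it.

## Paired-αβ richness

`paired = M·(f·α + β) + max(f·α, β)`. f (fraction of cells with exactly
one distinct TCRα) corrects bulk α richness for dual-TCRα cells and is
applied before both the sum and the max. M is fitted through the origin
(`M = Σxy/Σx²`, x = f·α+β, y = paired − max(f·α, β)) on per-sample
single-cell triples; samples under 2,000 cells are first merged by
greedy accumulation in input order (the residual below threshold passes
through). The max-subtraction and zero intercept guarantee
paired ≥ max(f·α, β), and the estimator is homogeneous of degree 1, so
relative (percent-per-year) trends in chain richness propagate to
paired richness unchanged. Published constants (CD4 M=0.138, f=0.870;
CD8 M=0.035, f=0.846) ship as defaults; no outlier handling is applied
when fitting.

## Overlap, retention, publicity

Unique overlap defaults to the Jaccard percentage and total overlap to
the symmetric UMI-weighted reading
`100·(UMI_A(shared)+UMI_B(shared))/(UMI_A+UMI_B)`; Sørensen and a
one-sided-mean reading are selectable, and every result records the
metric and key level used, because the literature states these
statistics in several algebraically different but similarly named
forms. Publicity pools both visits of a donor before counting donors
per clonotype (amino-acid key); abundance-by-publicity cumulates a
donor's UMI counts across tables, computes per-TCR UMI percentages,
takes the per-TCR median across carrying donors and reports per-level
medians with a log10 column.

## Longitudinal inference

Responses are log10-transformed and fitted with
`statsmodels` MixedLM: fixed effects age and sex (no interaction),
random intercept per donor, REML. The age coefficient is converted via
`S_new = (10^S_old − 1)×100` to %/year of the raw response. Wald
p-values on the age coefficient are reported with the conventional 0.05
threshold. Degenerate inputs (noise-free or otherwise singular fits)
fall back to ordinary least squares with a logged warning rather than
failing. Replicate SD is the sample SD (ddof=1) of log10 richness
across aliquots of the same draw; per-donor change classification
requires a strictly-greater-than-1-SD move on the log10 scale
("exactly 1 SD" is no change). Operating on log10 rather than raw
estimates is a choice — it matches the scale on which all other
analyses run; a raw-scale option exists.

## Synthetic-data generator

The generator's defaults encode the emulated study conditions:

* 30 donors, 15 male / 15 female, first-visit ages uniform on 28–76 y,
  visit gap uniform on 7–11 y (mean 9 y, inside the reported 7–13 y
  range).
* log10 richness = subset baseline + slope·(age − 52) + donor intercept
  (SD 0.3 log10) + residual (SD 0.1 log10); visit 2 compounds visit 1 by
  (1 + pct/100)^gap with fresh residual noise. The intercept and
  residual SDs were chosen so the simulated spread covers about two
  decades, like the observed per-donor richness range.
* Generative %/year slopes default to the published naive-subset
  estimates (CD4 α −0.66, β −2.27; CD8 α −2.19, β −3.48) and 0 for
  memory subsets, where no significant richness change was reported.
* Clone sizes: log-normal σ=1.5 on weights (assumed, not measured — the
  source data's clone-size law is not published; power-law and uniform
  are selectable), every clone guaranteed ≥1 cell, mean 10 cells/clone.
* Sequencing: ~30 reads per UMI (deterministic per UMI), per-base
  substitution error 0.001, Phred 35, 12-bp UMIs unique within a
  sample.
* Dual-TCRα cell fraction 0.13 (CD4; 0.154 reproduces the CD8 single-α
  fraction of 84.6 %).
* Per-subset baseline richness 1,000–4,000 — a deliberate desk-scale
  reduction from the real 1e4–1e6 so suites and the acceptance script
  run in about a minute; all recovery statements are made at this
  scale.
* Retention: each visit-1 clone persists to visit 2 with probability
  0.10 (assumed; observed longitudinal overlap percentages are
  depth-dependent and do not directly pin the underlying retention
  rate).

What the generator does **not** emulate: real VDJ recombination
statistics and germline alleles (the V/J reference is synthetic with
unambiguous tags), indels, quality-score variation, thymic selection,
HLA restriction, correlated α–β pairing structure, and index-hopping.
Consequently, passing tests demonstrate the correctness of the
algorithms under the stated generative assumptions — exact bookkeeping,
rule application, and parameter recovery — not the biological accuracy
of richness extrapolation on real repertoires, where clone-size
distributions are unknown and deeper confounders (library efficiency,
RNA copy number per cell) apply.

## Numerical and interface decisions

* Clonotype tables are AIRR-Rearrangement-style pandas DataFrames
  (`v_call`, `j_call`, `junction`, `junction_aa`, `duplicate_count`),
  written/read as plain TSV.
* All stochastic steps take explicit seeds; numpy `default_rng`
  sequences derived from (config seed, donor index, subset, chain,
  salt) make every per-donor object reproducible in isolation.
* Consensus/collapse outputs are deterministically ordered (first-seen
  or mergesort on keys) so fixed inputs give byte-identical outputs.
* Truth records derive clone registries lazily from stored seeds and
  cache them; a full default cohort would otherwise materialise ~10⁶
  clone keys that slope analyses never read.
* Known limitations: the consensus clusterer is O(clusters) per read
  and assumes equal read lengths (no indel handling); greedy
  1-mismatch clustering is order-dependent in pathological chains of
  near-identical reads; `curve_fit` bounds make fits robust but mean
  the "best" model is best only within the registered forms.
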