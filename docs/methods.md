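# Methods

## The experiment being analysed

A chromatin preparation is eluted sequentially: first with an isotonic
buffer (IB) that washes out nucleoplasmic and cytoplasmic background,
then with 2%, 5% and 10% 1,6-hexanediol (HD2/HD5/HD10). 1,6-hexanediol
weakens the hydrophobic contacts that hold liquid-like condensates
together, so proteins released at low concentration are the most
condensate-dependent. Each fraction is quantified by label-free LC-MS,
giving a protein × sample peak-area table with replicates per group.
`hexelute` takes that table (plus peptide evidence, protein sequences,
externally predicted disorder intervals and GMT annotation sets) and
produces the downstream statistics.

## Quantification processing

The chain is fixed and enforced (each stage records itself on the table
it returns; running a stage out of order raises `PipelineOrderError`):

1. **High-confidence filter** — keep proteins with at least one unique
   peptide and two strict peptides (strict = Mascot ion score ≥ 20), or
   more than two strict peptides. Filtering consumes the provided
   counts; the score threshold itself is upstream metadata.
2. **Detection filter** — keep proteins observed in ≥ 1 sample
   (`min_detected_samples`, default 1).
3. **Minimum imputation** — replace each missing cell with the minimum
   observed value of its sample column (`impute_scope: column`, default)
   or of the whole matrix (`global`). Per-column is the default because
   detection limits are sample-specific in label-free MS. Observed
   cells are never altered; a per-cell provenance matrix
   ({observed, imputed}) is kept.
4. **Quantile normalization** — rank each column and replace rank *r*
   with the mean of the *r*-th order statistics across columns. Tied
   values within a column receive the mean of the reference values of
   their tied ranks (the common convention). With ties present this tie
   rule means the transform is not exactly idempotent and tied columns
   do not share the untied columns' sorted vector; for tie-free input —
   which continuous peak areas are in practice — both properties hold
   and are property-tested.
5. **log2 / Z-scoring** — per treatment group, group abundance is the
   arithmetic mean of the replicate columns on the raw scale; Z-scores
   are computed over proteins from log2 abundance with the sample (n−1)
   standard deviation.

## Elution statistics

Ratio statistics deliberately use **raw replicate means with undetected
groups at zero**, not the imputed/normalized values: imputation exists
to make normalization and Z-scoring well-defined, and would fabricate
abundance in groups where a protein was never observed, inflating its
apparent share there.

* HD ratio = pooled HD abundance / (IB + pooled HD). Pooling is the sum
  of the three concentration groups (`hd_pooling: sum`, default):
  sequential elution fractions are physically distinct material, so
  their peak areas add. `max` is available as an alternative.
* Concentration shares divide each HD group's abundance by the summed
  HD abundance; the IB control is excluded from this denominator by
  construction (the share asks "of what was hexanediol-eluted, at which
  concentration?").
* Classification: representative of a concentration iff its share
  **strictly** exceeds `rep_threshold` (default 0.5 — at most one group
  can); else common iff the maximal share lies in
  [`common_low`, `rep_threshold`] (default [0.2, 0.5], closed); else
  minor. The strict/closed boundary reading follows the definitions
  "exceeding 50%" and "between 20 and 50%". With three shares summing
  to 1 the maximum is always ≥ 1/3, so `minor` only occurs with a
  raised `common_low`.
* Set-wise abundance ratios sum member abundances before dividing, so
  abundant members dominate — intentionally, as the set-level statistic
  describes where the set's material elutes. `include_ib` adds the IB
  abundance to the denominator for control-vs-gradient comparisons.

Proteins with zero abundance everywhere (or in all HD groups) get an
undefined ratio (or shares) and the class `undefined`; they are counted
and logged, never silently dropped.

## Sequence features

* **Low-complexity fraction.** Shannon compositional entropy is
  computed for every window of W = 12 residues; windows ≤ 2.2 bits
  (locut) trigger segments, which extend over contiguous windows ≤ 2.5
  bits (hicut); overlapping extended regions are merged, and the
  fraction is the merged length over the protein length. W/locut/hicut
  are the published defaults of the classic SEG detector. The
  optimal-subsegment refinement stage of original SEG is omitted — the
  downstream statistic is a length fraction, for which boundary
  refinement is second-order — so absolute fractions can differ
  slightly from SEG builds. The detector is verified against a
  brute-force oracle that enumerates all windows and performs
  extension/merge exhaustively. Note that a *merged* segment can span
  several compositionally distinct biased blocks, so its aggregate
  entropy may exceed hicut even though every window inside the
  pre-merge runs is ≤ hicut; the per-segment `complexity` field reports
  the aggregate.
* **Disorder fraction** — union length of the externally predicted
  intervals (BED-like, 0-based half-open, cross-checked against
  sequence length) over protein length. Disorder prediction itself is
  out of scope; intervals are consumed as input.
* **FCR** — count of D, E, K, R over full length; histidine excluded,
  matching the localCIDER `get_FCR` convention.
* **Uversky hydropathy** — mean Kyte–Doolittle value rescaled by
  (KD + 4.5)/9 to [0, 1]. X residues are excluded from composition
  counts and hydropathy means with the length reduced; an all-X window
  is treated as maximally complex (log2 20 bits) and logged.

## Tests and enrichment

* Chi-square (Pearson, no continuity correction) compares protein-type
  membership counts between the HD-detected and IB-detected protein
  sets, one test per type set (TF/TC/RBP-style GMT input).
* The independent-samples t test defaults to Welch's unequal-variance
  form (robust to group-variance differences); pooled-variance
  Student's is available. Two constant equal samples give p = 1 by
  convention.
* Mann–Whitney U is exact by enumeration when the combined sample size
  is ≤ 12 and tie-free, otherwise the normal approximation with tie and
  continuity corrections.
* Enrichment is an upper-tail hypergeometric test of a query (e.g. the
  representative_HD2 proteins) against each annotation set intersected
  with the universe (all profiled proteins), with Benjamini–Hochberg
  FDR across sets. p-values are floored at the smallest positive float
  so that p, q ∈ (0, 1] and −log10(p) stays finite when the survival
  function underflows.
* The "high-abundance vs low-abundance" contrast per treatment group is
  operationalized as Q4 vs Q1 of the group's Z-scored abundance
  (`abundance_split: quartile`, default; `median` available). Quartile
  assignment breaks ties by protein id so the split is deterministic.

## Synthetic studies

The generator plants the structure the analysis is designed to detect.
Defaults (the study conditions used throughout the tests and the
acceptance script):

| parameter | default | rationale |
|---|---|---|
| n_proteins | 2,000 | order of a chromatin-enrichment proteome |
| replicates | 2 per group | typical for exploratory gradient designs |
| class fractions | llps 0.25 / structured 0.35 / background 0.40 | condensate-prone proteins a sizeable minority |
| llps_like shares (IB, HD2, HD5, HD10) | 0.10, 0.60, 0.20, 0.10 | low-concentration-eluting, HD-sensitive |
| structured shares | 0.70, 0.05, 0.10, 0.15 | buffer-eluted, HD-resistant |
| background shares | 0.40, 0.15, 0.20, 0.25 | intermediate |
| total abundance | LogNormal(μ=18, σ=1.5), natural log | peak-area scale spanning ~4 orders of magnitude |
| replicate noise | LogNormal(0, 0.2), multiplicative | label-free replicate CV ≈ 20% |
| missing rate | 0.10, rank-weighted toward low abundance | left-censored-like missingness of label-free MS |

llps_like sequences (300–800 aa) carry S/G/Q/P-rich low-complexity
blocks covering 30–60% of the length, with disorder intervals tracking
the blocks; structured proteins have near-uniform composition and < 10%
disorder; background is intermediate. Peptide evidence is drawn so
~97% of proteins pass the high-confidence filter. Generation uses a
single integer-seeded generator: same seed, byte-identical outputs.

What the generator does **not** emulate: peptide-level quantification,
shared peptides, batch effects, correlated replicate noise, and real
proteome sequence statistics. Passing recovery tests therefore shows
the pipeline recovers planted structure under idealized label-free
noise, not that it is robust to every artefact of real MS data.

At these defaults (seed 1) a single frozen calibration run gave:
representative_HD2 recall of planted llps_like proteins 0.992, AUROC of
the HD ratio separating llps_like from structured 0.991, Spearman
between planted and estimated shares 0.922, and a mean low-complexity
fraction gap of 0.514 between llps_like and structured — all
regression-tested at the bounds 0.9 / 0.9 / 0.9 / 0.15. The acceptance
script recomputes these quantities from scratch at any seed.

## Numerical and degenerate-input choices

* Missing encoding on input: empty cell or "NA" (any case); zeros are
  observed values (instrument peak areas are never exactly zero, and
  imputation targets missing, not zero).
* Coordinates are 0-based half-open everywhere.
* Duplicate protein ids, samples missing from the sample sheet,
  negative abundances, non-integer peptide counts, out-of-bounds
  disorder intervals, duplicate GMT set names and all-missing columns
  are hard errors naming the offending record — parsers never silently
  drop rows.
* An all-missing sample column cannot be imputed; a zero-variance group
  cannot be Z-scored; a single-protein group has no sample SD: all hard
  errors naming the group/column.

## Known limitations

* The low-complexity detector intentionally simplifies SEG (no P0
  subsegment refinement); fractions are comparable within a run, not
  bit-identical to SEG output.
* Enrichment assumes an unordered query against unordered sets; no
  rank-based (GSEA-style) statistic is provided.
* External LLPS predictor scores (PScore/catGRANULE/SaPS/PdPS
  analogues) are consumed as precomputed columns only.
* The pipeline analyses one experiment; no cross-study batch
  correction.
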