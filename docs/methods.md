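# Methods

## Scope and data model

`synscreen` analyzes sparse pairwise drug-combination screens: per assay
(one cell line at one dose level), every drug pair is measured in a single
well, every drug alone in one (or few) singlet wells, and a set of DMSO
vehicle wells anchors the plate. The canonical input is a long CSV of well
records (plate, row/column, cell line, dose level, drug annotations,
control flag, nuclei count); 1536-well geometry (32 × 48) is the default
but any plate shape works, and plates need not be full.

## Preprocessing

Counts are normalized per plate in three steps.

1. **Median polish (optional, default on).** One iteration of Tukey median
   polish — one row sweep, then one column sweep, medians ignoring missing
   cells — applied to log10 counts over the physical plate grid, then
   re-exponentiated as `10^(overall + residual)`. Working on logs guarantees
   the adjusted counts stay positive. Zero counts are replaced by a
   pseudocount (default 0.5) with a logged warning.
2. **DMSO control value.** The 10%-per-side trimmed mean
   (`floor(n·0.10)` values removed per side) of the adjusted control-well
   counts, per plate.
3. **Viability.** `V = adjusted count / control value` for every well.
   Viabilities are never capped at 1: values above 1 are informative noise
   that the model handles, and capping would bias the fit.

DMSO wells are themselves converted to `W = -log10 V` and pooled across all
of an assay's plates; their unbiased sample variance is the assay's
experimental-noise estimate. Pooling (rather than per-plate variances)
gives one stable null per assay.

**A caveat on median polish at small plate sizes.** Because treatments are
laid out randomly, the row/column medians of a plate contain a sample of
the treatment-effect distribution itself, not only spatial artifacts. On a
full 1536-well plate that sampling error is modest; on the 384-well plates
of the desk-scale synthetic screens it reaches ~0.05–0.1 on the W scale and
becomes the dominant noise source (on the default synthetic screen it drops
R² from 0.93 to 0.70). The polish therefore earns its keep only when real
spatial artifacts are at least comparable to it. What the polish does
guarantee — and what the test suite asserts exactly — is absorption of true
row/column effects: a plate with a uniform multiplicative artifact on one
row polishes to the same viabilities as the artifact-free plate (to 1e-9).
The statistical validation experiments (noiseless recovery, power,
cross-dose consistency, noise robustness) are accordingly run with polish
disabled and no simulated artifacts, which is their clean study condition.

## The Bliss linear model

On `W = -log10 V`, Bliss independence is additive, so the pair wells of one
assay form the over-determined system `W_i + W_j ≈ W_ij` — one equation per
observed pair, one unknown per drug, no intercept (a constant shift is not
identifiable on a pure pair design and has no physical meaning here).
Measured singlet wells never enter the fit; they are reserved for
validation. The design is solved by ordinary least squares via the normal
equations (`X'X` is the degree-plus-adjacency matrix of the pair graph,
Cholesky-factorized; smallest-eigenvalue check at relative tolerance
1e-10). A connected pair design guarantees full column rank; disconnected
designs raise an error listing the components.

Reported per assay:

* `Ŵ_i` with standard errors `se_i = sqrt(σ̂² · [(X'X)⁻¹]_ii)`,
  `σ̂² = RSS/(m−n)`, and 95% CIs `Ŵ_i ± 1.96·se_i`;
* residuals `r_ij = W_ij − (Ŵ_i + Ŵ_j)`, signed so that positive means the
  combination killed more than the Bliss expectation (synergy);
* `R² = 1 − RSS/TSS` with TSS about the mean of the `W_ij`. The model has
  no intercept, but the mean-model baseline is what makes R² comparable to
  a standard linear-model report, and it doubles as a per-assay QC surface:
  assays with low R² and high DMSO variance are noisy assays.

## Synergy inference

The null hypothesis for a pair is pure measurement noise, Gaussian on the W
scale with mean 0 and variance

```
var_null(i,j) = var_DMSO + se_i² + se_j²
```

— the plate noise of a single well plus the (small) uncertainty of the two
solved singlets. `z = r_ij / sqrt(var_null)` yields one-sided
`p_syn = 1 − Φ(z)` and `p_ant = Φ(z)`; Benjamini–Hochberg is applied per
direction across all pairs of the assay, and calls use `q < α`
(default 0.05). Pairs with `V_ij < 0.1` carry a `low_viability` flag: the
W-scale variance of a nearly-empty well may be underestimated, so such
calls deserve caution rather than correction. A pair is synergistic in a
cell line if either dose assay calls it.

Because `var_DMSO` grows with assay noise, a noisy assay automatically
demands a larger deviation for significance — the number of model-based
calls does not inflate with noise, in sharp contrast to thresholding the
raw excess-over-Bliss score. Both EOB variants are still reported per pair
(`eob_raw` from measured singlets, `eob_model` from solved singlets) for
comparison and visualization.

Numerical guard: on exactly noise-free data both the residual and the null
variance sit at machine zero; when `var_null < 1e-20` and `|r| < 1e-10` the
z value is defined as 0 (no evidence) instead of an ill-conditioned 0/0.

## Scores

`T_ij` counts the cell lines in which pair (i,j) is (dose-combined)
synergistic. The specificity score standardizes `T_ij` against each drug's
partner distribution — mean and *sample* SD (n−1) over all partners k ≠ i,
the pair's own entry included (a config option excludes it) — and takes the
smaller of the two sides. Drugs whose partner scores have zero SD
contribute a neutral 0 rather than an infinity. Pairs are ranked by `T`
descending with `Sc` as tie-break, with a percentile of `Sc` across pairs.

## Randomization nulls

* **Within-cell-line permutation**: each cell line's boolean pair vector is
  uniformly permuted; per-cell-line totals are conserved exactly. Planted
  specific synergies show up as excess mass at 0 and at high `T` relative
  to this null.
* **Binomial drug-marginal null**: `T'_ij ~ Binomial(N, clip(p_i + p_j, 0, 1))`
  with per-drug propensities fitted by coordinate descent to minimize the
  squared mismatch of expected vs observed per-drug totals (moment start
  `p_i = O_i / (2N(n−1))`; bounded scalar minimization per coordinate;
  convergence when the vector-scaled change `max|Δp|/‖p‖∞` falls below
  1e-8, near-zero coordinates snapped to the bound; 500-sweep cap with a
  gradient-norm report on failure). The additive-and-clip link is the
  simplest form that is monotone in both drugs and reproduces marginals.
* **High-score test**: the observed number of pairs with `T` above a
  threshold (default 12 cell lines) against `n_rand` (default 1000) null
  matrices, with the +1-corrected empirical p
  `(1 + #{null ≥ obs}) / (1 + n_rand)` — never exactly zero; an observation
  above all 1000 draws reports `p = 1/1001 < 0.001`. Replicate draws use
  seed streams spawned deterministically from one master seed.

## Evaluation (internal consistency)

With no technical replicates, the high/low-dose assays of a cell line act
as a replication proxy: per drug, the Pearson correlation of singlet values
across cell lines between doses is computed for measured and for estimated
singlets (exact t-transform test, two-sided, α = 0.05; drugs with < 3
paired values are skipped), and the two per-drug correlation vectors are
compared with a paired t test (the same drugs are measured twice; an
unpaired variant is available). Per drug, synergy overlap between doses is
tested with a two-sided Fisher exact test on the (partner drug, cell line)
grid. Per assay, estimated vs measured singlet viabilities are compared by
Pearson correlation on the V scale.

## Synthetic screens

The generator produces complete plate tables under the model's own
assumptions, so that inference is exactly calibrated under the generator
and every deviation observed in tests is attributable to the procedure
being tested:

* true high-dose potencies `W_i ~ N(0.15, 0.15²)` per (drug, cell line) —
  most drugs weakly active (V ≈ 0.5–1), some strong;
* true low-dose potencies `0.4 · W_high + N(0, 0.03²)`: a five-fold dose
  reduction scales effects down while keeping the across-cell-line
  structure shared between doses — without this, cross-dose consistency
  would be vacuously zero for measured and estimated singlets alike;
* combination wells `W_ij = W_i + W_j + Δ_planted + N(0, σ_w²)` with
  σ_w = 0.05 by default; singlet wells carry 3× the noise SD (a single
  well is noisier than what n−1 combinations jointly imply — the screen's
  core motivation); DMSO wells are `W = 0` plus noise;
* counts `base_count · 10^(−W)` (base 1000), optional per-plate row/column
  log10 artifacts and optional Poisson count noise;
* pseudo-random well layout over as many plates as needed (384-well
  geometry with 16 DMSO wells per plate at desk scale);
* planted effects: specific synergies/antagonisms per (pair, cell-line set,
  dose set) with `|ΔW| = 0.25` (5σ) by default, and promiscuous sensitizers
  whose partners are Bernoulli-drawn once and then synergize across all
  cell lines and doses.

Everything is deterministic given the spec's seed. The default desk-scale
spec is 20 drugs (190 pairs) × 8 cell lines × 2 doses ≈ 3 600 wells, which
keeps every experiment below a minute; the validation experiments use
100 replicate screens for power/type-I, 20 replicate screens for the
cross-dose contrast, and 1000 null draws for the randomization test. What
the generator does **not** emulate: dose–response curvature (doses are two
discrete levels), count-level overdispersion beyond Poisson, plate edge
effects or gradients beyond separable row/column terms, and any genomic
structure across cell lines. Passing tests therefore validate the
statistical machinery, not robustness to those real-data features.

For the noise-robustness contrast (model calls vs raw `EOB > 0.3`
thresholding under 5× assay noise) the singlet-well multiplier is set to 1:
the contrast isolates assay-wide noise, and with 3× singlet wells the raw
baseline is already singlet-noise-inflated, saturating the ratio.

## Export

The heatmap JSON payload carries the score matrix (absolute + specificity
per pair) and, per pair and assay, observed vs Bliss-expected viabilities
with error bars and the call flags — everything a viewer needs. W-scale
standard errors map to the viability scale by the delta method
(`se_V ≈ V · ln 10 · se_W`); the observed error bar is the DMSO SD mapped
the same way. A JSON-schema document ships with the package and a
structural validator enforces the contract. The interactive viewer itself
is out of scope; the payload is designed so any front end can consume it.

## Known limitations

* The Gaussian null on W is exact for log-normal count noise only; heavy
  count-level overdispersion would misestimate tails.
* `var_DMSO` may understate the variance of wells with very low viability
  (flagged, not corrected).
* One-iteration median polish injects layout-sampling distortion on small
  or sparse plates (see above); consider `polish=False` below 1536 wells.
* BH is applied per assay and per direction; families are not pooled
  across doses or cell lines.
* Specificity scores on nearly-flat score matrices are defined (neutral 0
  on zero SD) but not informative.
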