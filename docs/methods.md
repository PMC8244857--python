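# Methods

## Statistics

All expression statistics are computed on group means of FPKM+1 values:
the offset is added to each sample's FPKM before averaging, so a silent
gene has group mean exactly 1 and every log ratio is finite. The offset is
a parameter (`offset`, default 1) of `compute_group_means`. Whether one
adds the offset before or after averaging is not uniquely determined by
the FPKM+1 convention; this package adds it per sample first, which
commutes with averaging anyway (mean(x)+1 = mean(x+1)), so the choice is
cosmetic for the mean but recorded here for clarity.

Specificity values are log₂ ratios of a group's mean to the per-gene
average over **all** groups of the same class, including the focal group.
A leave-one-out variant (`exclude_self=True`) is available but off by
default. Because the denominator is the within-class average, specificity
obeys a conservation identity — per gene, Σⱼ 2^(value) × (cross-group
average) equals Σⱼ (group mean) — which the tests verify to 1e-9, and it
is invariant under any global rescaling of the expression values.

Relative expression r = log₂(cancer mean / paired-tissue mean) is computed
on the intersection of gene ids; genes present in only one matrix are
dropped with a logged count rather than imputed, since the ratio is
undefined without both sides. Tissues serving several cancers (the
kidney/lung situation) are simply reused column-wise.

All logs in expression statistics are base 2.

## PCA embedding and distance ratios

Cancers and normal tissues are embedded jointly: entities are
observations, genes are variables, genes are centered across entities, and
no unit-variance scaling is applied (scaling is exposed as a flag but
off, following the usual convention for transcriptome PCA where the
common log scale already makes genes commensurable). Raw mean matrices
are log₂-transformed before PCA — Euclidean distance on untransformed
FPKM would be dominated by a handful of highly expressed genes — while
specificity matrices are already log-scale and enter as-is. Both choices
are flags and are recorded in the embedding metadata written by the CLI.

The relative distance of a cancer is its Euclidean distance to the paired
tissue in the first `dims` components divided by its average distance to
every other entity. The averaging set excludes the focal cancer and its
paired tissue; an option includes the pair. `dims=2` gives the
first-two-components report; `dims="all-nonzero"` uses every component
with non-zero variance, where PC distances coincide with centered-data
distances exactly (PCA is a rotation — asserted to 1e-8 in the tests).
The distance ratio divides the specificity-space relative distance by the
raw-space one; values below 1 mean the specificity transform draws the
pair together.

## Correlation analyses

Spearman correlations use mid-rank ties (scipy); the test suite verifies
them against an independent brute-force midrank + explicit-Pearson oracle
to 1e-10. Only point estimates are reported — with 2000+ genes per vector
and strong inter-gene dependence, nominal p-values would be meaningless.

The pairwise fold-change correlation between cancers a and b is the
Pearson correlation of vᶜ = {cᵢₐ/cᵢᵦ} against vⁿ = {nᵢₐ/nᵢᵦ}, computed
on the offset mean scale so all ratios are finite. The filtered variant
first removes genes whose normal-tissue fold-change is ≤ 0.5 or ≥ 2 from
both vectors. Pearson on raw ratio vectors is not symmetric under
swapping a and b (1/x is not a linear transform); both orientations are
stored in the matrix, and a `log_ratios` option — recommended for new
analyses — makes the statistic exactly symmetric and much less
outlier-dominated. The raw-ratio form remains the default because it is
the established formulation this package mirrors.

## Survival analysis

Per-gene survival association follows the pathology-atlas cutoff-scan
scheme: expression is dichotomized at each percentile from 20 to 80 in
steps of 1, a two-group log-rank test (chi-square, 1 df) is run at each
cutoff, and the minimum p is retained without multiplicity correction.
This minimum-p scan is anti-conservative — the type-I rate at nominal
0.05 exceeds 0.05 — and deliberately left so, because the downstream
signed score is defined by this construction; the bias is demonstrated by
a dedicated test rather than corrected. The scan grid is configurable
(`lo_pct`, `hi_pct`, `step_pct`), and a single-cutoff scan at the median
reduces exactly to a median-split log-rank test.

Direction is decided by the Kaplan–Meier restricted-mean survival of the
high-expression group over the follow-up window (robust when curves
cross); exact ties are labelled unfavorable with a warning. The signed
score is s = −log p for favorable genes and +log p for unfavorable ones,
natural log by default: s only ever enters rank correlations and
sign-based selections, so the base is provably inconsequential (a test
confirms rank invariance).

The log-rank machinery is vectorized over (gene, cutoff) pairs — the
event-time grid is shared, group memberships form a boolean matrix, and
at-risk/event tallies are segment reductions — so a full 2000-gene scan
for one cancer takes about a second. It is verified to 1e-10 against a
brute-force per-event-time tabulation and against lifelines.

Specificity filtering for survival uses fold-change bounds 0.8× and 1.2×
expressed on the same base-2 log scale as n\* (thresholds log₂ 0.8 ≈
−0.322 and log₂ 1.2 ≈ +0.263). Reading the bounds in the same base as the
statistic they are compared against is the only self-consistent
convention; natural-log presets are available via the `low`/`high`
arguments. The favorable analysis removes genes down-regulated in the
paired tissue; the unfavorable analysis removes genes up-regulated there.

## Competitive gene-set testing

The pre-ranked competitive test is implemented from its published
formula: for a set of m measured members among G genes, the difference
between in-set and out-of-set mean statistics is scaled by the pooled
standard deviation and by √(VIF/m + 1/(G−m)) with VIF = 1 + (m−1)ρ, and
referred to a t distribution on G−2 degrees of freedom. ρ (`inter_gene_corr`)
defaults to 0.01, the cited method's conventional setting. With ρ = 0 the
statistic is exactly the pooled two-sample t-test; the test suite verifies
both this limit and numerical agreement with Bioconductor limma's
`cameraPR` (used strictly as an independent oracle). A rank-based variant
(`use_ranks=True`) replaces statistics by mid-ranks first. P-values are
invariant under positive affine transforms of the gene statistics, and
increasing ρ never decreases a p-value (VIF monotonicity); both are
property-tested.

Directional analyses set the p of any set enriched opposite the target
direction to 1.0, producing the characteristic vertical tail in Q-Q plots.
Null calibration is checked under an i.i.d. normal gene-statistic model
with ρ = 0, matching the generative independence; with the default ρ =
0.01 the test is intentionally conservative under independent statistics.

Q-Q comparison sorts both p-value lists and pairs them at matching
quantile levels, linearly interpolating the shorter list when lengths
differ. The improvement fraction counts strictly smaller filtered
quantiles; the dominance checks in the acceptance suite use the weak
(≤) form pooled over all cancers, mirroring the pan-cancer pooling of the
published Q-Q comparisons.

## Synthetic cohorts

The generator emulates the joint structure the analyses assume:

* **Baseline** — per-gene log₂ mean drawn N(3, 2), i.e. log-normal FPKM
  with a heavy right tail (both parameters configurable).
* **Tissue programs** — a disjoint block of `frac_specific` (default 5%)
  of genes per tissue is elevated by `specific_log2fc` (default 3 log₂
  units) in that tissue only.
* **Cancer coupling** — each cancer's expected profile is its paired
  tissue's profile with the program elevation multiplied by
  `dedifferentiation` (default 0.5: tumors retain half the tissue
  program, making n\* vs r negative) and a fixed random subset
  (`frac_cancer_axis`, default 10%) of genes shifted by
  `cancer_axis_log2fc` (default 2) in *every* cancer. Because the axis
  shift is common to all cancers it cancels in the cross-cancer average,
  so it separates cancers from normals on the raw scale while leaving
  specificity values untouched — exactly the mechanism behind distance
  ratios below 1. Multiple cancers per tissue reuse the same normal
  profile.
* **Per-sample program activity** — each tumour draws activations u, w ~
  N(0, `program_sd`) (default 0.5) added to its tissue-program and
  cancer-axis genes on the log₂ scale. This per-subject variability is
  what couples expression to survival: without it, averaging independent
  noise across a 100-gene block would leave per-subject hazards
  essentially constant and no gene-level survival signal could exist.
* **Noise** — independent per-sample, per-gene log-normal noise
  (`noise_sd`, default 0.5 log₂ units). Setting `noise_sd=0` and
  `program_sd=0` makes cancer samples exactly equal to their expected
  profiles.
* **Survival** — exponential times with log-hazard `surv_effect`·(w − u):
  tissue-program activity is protective, cancer-axis activity
  deleterious; ground-truth per-gene coefficients are returned. Censoring
  is independent uniform U(0, M), with M solved numerically so the
  expected censored fraction at the baseline hazard equals `censor_rate`
  (default 0.3).

The reference study conditions are 2000 genes, 6 tissues with one cancer
each, 3 donors per normal tissue (matching the Human Protein Atlas
design, which profiles three individuals) and 60 tumors per cancer — a
desk-scale panel that preserves the qualitative structure while keeping a
20-cohort replicate suite within a few minutes on one CPU.

What the generator does **not** emulate: read-count sampling (no negative
binomial layer), batch effects, within-tissue cell-type composition,
copy-number or mutation structure, correlated gene-gene noise beyond the
block programs, and non-proportional hazards. Passing tests therefore
demonstrate that the statistics and filters behave as designed under the
assumed generative structure, not that real tumor cohorts will show
effects of the same magnitude.

Synthetic gene-set collections (50 sets, sizes 50–200) mix sets enriched
in cancer-axis genes, sets enriched in tissue-program genes, and uniform
background sets, so that directional enrichment and specificity filtering
have true signal to find; real GMT collections are fully supported.

## Numerical and design notes

* Group and gene ordering follows first appearance in the input design,
  so repeated runs are bit-identical; all randomness flows from a single
  integer seed through `numpy.random.default_rng`.
* Degenerate inputs fail loudly: constant matrices in PCA, constant
  vectors in correlations, empty groups, zero pooled variance in the
  gene-set test, and a zero raw relative distance in the distance ratio
  all raise typed errors rather than returning NaN. Two exceptions return
  a flagged neutral value: a log-rank test with zero events returns p = 1
  with a warning, and constant-expression genes are skipped (not failed)
  in whole-matrix survival scans.
* Cutoff-scan ties in p are broken toward the lowest percentile;
  specificity-filter boundary ties are broken by gene id order; best-match
  tissue ties are broken lexicographically — each with a logged warning.
* The pipeline manifest records every stage parameter alongside its
  documented default and an `overridden` flag, plus SHA-256 checksums of
  all outputs, so identical configurations are verifiably identical runs.

## Known limitations

* The cutoff-scan p-values are anti-conservative by construction (see
  above); they are ranking devices, not calibrated significance
  statements.
* Raw-ratio Pearson fold-change correlations are asymmetric and
  outlier-sensitive; prefer `log_ratios=True` when not reproducing the
  original formulation.
* With only three donors per normal tissue, n\* estimates carry
  substantial sampling noise; the analyses lean on means and ranks, which
  mitigates but does not remove this.
* The competitive test's single scalar ρ is a crude model of inter-gene
  correlation; calibration under correlated nulls depends on how well ρ
  matches the data.
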