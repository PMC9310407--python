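# Methods

## Expression quantification and filtering

Counts are converted to RPKM, `1e9 · c_gs / (L_g · N_s)`, where `L_g` is the
exon-model length (bp) and the library size `N_s` is the **column sum of the
analysed count matrix**.  In a full mapping pipeline the "per million reads"
denominator would be total mapped reads; using the matrix's own column sums
keeps the analysis self-contained and differs from mapped-read totals only by
a per-sample constant when the matrix covers the annotated gene set.

The expression filter keeps gene *g* when `RPKM_gs > threshold` in at least
`min_fraction` of samples, with defaults threshold = 4 (strict `>`) and
fraction = 0.5 (inclusive `>=`).  The filter is applied once per tissue over
all samples of that tissue's analysis (all groups pooled), so every contrast
of a flow shares one gene universe.  It is idempotent by construction.

## Differential expression

Each contrast is a two-sided Welch (unequal-variance) *t*-test per gene on
`log2(RPKM + 1)`; the log2 fold change is the difference of group means on
that transformed scale (comparison − reference), not the log of the ratio of
raw means.  The Welch–Satterthwaite degrees of freedom are used.  Genes with
zero variance in both groups get *p* = 1 when the means agree (and fold
change 0) and *p* = 0 otherwise, so degenerate rows never produce NaN.

The pseudocount (default 1) and the transform are configurable on
`TwoGroupContrast`; users who prefer a count-model fit (e.g. a
negative-binomial GLM) can substitute its per-gene *p*-values and fold
changes into the classifiers, which only consume contrast tables.

Benjamini–Hochberg adjustment is the step-up
`q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1, computed over the contrast's gene
universe with a stable sort; tied *p*-values share the most favourable
(largest-rank) factor through the running minimum.

## Reversal classification

Over one gene universe and three contrasts — set 1: old-vehicle vs young,
set 2: old-treated vs old-vehicle, set 3: old-treated vs young — a gene is

* `not_aging_deg` when `q₁ ≥ 0.1`;
* otherwise an aging DEG with direction `sign(lfc₁)`;
* `reverted` when additionally `p₂ < 0.05`, `sign(lfc₂) = −sign(lfc₁)`, and
  `p₃ > 0.05`; else `aging_not_reverted`.

Design choices worth noting:

* Sets 2 and 3 are tested on **raw** *p*-values; only the aging call uses the
  FDR.  Both thresholds are configurable.
* "Reversing" is strict sign opposition of the fold changes; no magnitude of
  reversal is required.
* Criterion 3 accepts the null (`p₃ > 0.05`) as evidence of equivalence with
  young expression.  This is a known statistical weakness — low power in
  set 3 *favours* a reversal call — and is kept deliberately because it is
  the rule the classifier is meant to formalise; an equivalence test (TOST)
  would be the principled alternative.
* All comparisons are strict inequalities, so a value exactly at a threshold
  fails the test.  A gene whose set-2 fold change is exactly 0 with a passing
  *p* has no sign to oppose and stays `aging_not_reverted` (logged).
* The three tables must share one gene universe exactly; a mismatch is an
  error listing the symmetric difference rather than a silent intersection.

## Dependence classification

From the wild-type and knockout treatment contrasts (treated vs vehicle in
each genotype): DEG when `q_WT < 0.2`; a DEG is `dependent` when
`p_KO > 0.05` and `independent` when `p_KO < 0.05`.  A knockout *p* exactly
at the threshold resolves to `dependent` (the conservative reading for a
rule whose two printed branches are both strict) with a logged note.
`summarize_partition` reports counts and percentages with the DEG total as
denominator, rounded to one decimal; an empty DEG set yields an explicit
`None` marker instead of a division error.

## Survival analysis

The median lifespan of an arm is the Kaplan–Meier median: the smallest time
at which the product-limit survivor estimate is ≤ 0.5 (a 1e-9 tolerance on
the boundary absorbs floating-point round-off in the cumulative product).
On fully observed data this is the empirical lower median.  Maximum lifespan
is the longest *observed* death time — censored times are excluded; a
top-decile-mean variant is provided (`top_decile_mean_lifespan`) but is not
the default.  Lifespan change is `(treated − reference,
100·Δ/reference)`, displayed at two decimals (months) and one decimal
(percent).  Arm comparison is the unweighted log-rank (Mantel–Cox) test with
hypergeometric tie variance (via lifelines); for very small arms an exact
label-permutation *p* enumerates all `C(n, n_b)` arm assignments and reports
the fraction whose chi-square statistic is at least the observed one.

## The simulator

Counts are negative binomial with `Var = μ + φμ²` and

`μ_gs = 2^(b_g + shift_gs) · L_g[kb] · N_s / 1e6`,

so `b_g` is a baseline log2-RPKM and planted effects are log2-unit shifts —
exactly the scale the downstream Welch test estimates.  Planted structure:

* a floor(`frac_aging`·G) block of aging genes, half up / half down, shifted
  ±`effect_size` in old groups (age ≥ 18 months);
* the first floor(`frac_reverted`·n_aging) of them also get the opposite
  shift in old **treated** groups (`reversal_fraction` scales this; default
  1.0 = full reversal, since the magnitude of reversal in real tissue is
  unspecified);
* factorial designs with no age contrast plant floor(`frac_responsive`·G)
  directly treatment-responsive genes instead;
* floor(`frac_dependent`·n_responsive) of the treatment-responsive genes
  have their treatment shift zeroed in knockout groups.

Remainder genes after flooring stay unaffected.  Truth labels record the
planted assignment exactly, so class counts follow the floor rule by
construction.

Defaults and why: 5 samples/group and 2000 genes (the recovery-study size;
null calibration uses 5000 genes), effect 2.0 log2 units and dispersion
φ = 0.05–0.1 (typical biological-replicate bulk RNA-seq overdispersion),
library sizes log-normal with mean 2×10⁷ (study-like sequencing depth) and
CV 0.2, gene lengths uniform on 200–10 000 bp, baseline log2-RPKM uniform on
[3, 8] so most genes clear the RPKM > 4 filter while strongly down-shifted
genes can genuinely drop out of it.  Survival arms are Weibull with shape 8
and scale set so the theoretical median is exact
(`scale = median / (ln 2)^{1/shape}`); baseline median 25.95 months with a
+2.25-month treated shift, censored at 40 months of follow-up (effectively
uncensored).  Weibull is used rather than Gompertz because the median
inverts in closed form and no parametric mortality model is fitted anywhere
downstream.

What the simulator does **not** emulate: batch effects, correlated genes,
isoform structure, length-dependent dispersion trends, GC or mappability
bias, and delayed entry in the survival arms.  Passing recovery tests
therefore demonstrate that the classifiers implement their rules correctly
and have the expected power under clean negative-binomial data — not that
the thresholds are well calibrated for any particular real cohort.

## Numerical and degenerate-input conventions

* z-scores use the sample (n−1) SD; constant rows map to zeros with a
  logged warning.  PCA centres each gene across samples but does not rescale
  (inputs are typically already z-scored).
* Fraction-to-count rounding in the simulator: floor, remainder genes
  unaffected.
* Determinism: every random draw flows from one `numpy.random.default_rng`
  seeded from the spec; identical spec + seed gives bit-identical matrices,
  and pipeline reruns on identical inputs are byte-identical (the
  provenance record excludes the output directory from its hash for this
  reason).
* Validation errors name the offending field, gene, sample or cell.

## Problem sizes used in validation

Null calibration runs 3 seeds × 5000 genes × 15 samples; parameter recovery
3 seeds × 2000 genes for each design; the under-null log-rank uniformity
check uses 500 replicates of 50 + 50 animals.  These sizes give Monte-Carlo
error comfortably below the tolerances asserted (e.g. ±0.01 on a 0.05
type-I rate pooled over 5000 genes).

## Known limitations

* Welch-on-log-RPKM is not a count model; at very low counts its *p*-values
  are only approximately calibrated.  The classifiers accept any contrast
  table, so a pydeseq2/edgeR-style fit can be dropped in.
* The reversal rule's acceptance-of-null criterion (set 3) rewards low
  power, as noted above.
* KM medians and maximum lifespan are reported without confidence
  intervals; the exact-permutation log-rank is limited to small arms by
  combinatorial growth.
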