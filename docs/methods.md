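# Methods

This note records the models the package implements, the assumptions
behind them, the defaults that matter, and the choices made where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study structure assumed by the pipeline

A longitudinal case/control design: pregnant participants sampled in
three antenatal collection windows — ≤12, 13–20 and ≥23 weeks of
gestation — and once post-partum, with a binary outcome (preeclampsia
vs normotensive) and an optional severity stratum. Windows are defined
as ga ≤ 12.99, 13 ≤ ga < 21 and ga ≥ 23; gestational ages in the gap
(21 to <23 weeks) are labelled `unassigned` and excluded from
window-based statistics rather than silently merged into a neighbour.
Post-partum status is a flag, not an age rule. Repeat samples from one
participant are autocorrelated, so every window-level statistic uses at
most one sample per participant (the earliest in the window, ties
broken by sample id), and all data splits in the classifier keep a
participant's samples on one side.

## Sample QC

Three metrics: degradation (fraction of detected genes whose reads all
map to the 3′-most exon, in transcript orientation), contamination
(intron:exon read ratio; undefined with zero exonic reads and then
treated as failing, since such a sample carries no usable signal), and
reads assigned. Exclusion uses the empirical 95th percentile (linear
interpolation between order statistics) computed over the pooled
collection; a sample fails when its value is **≥** the bound or when no
reads were assigned. Bounds are recomputed per dataset by default, with
`fixed_bounds` available for cross-study reuse. `percentile=100` is
interpreted as "no empirical exclusion": under the ≥ rule the maximum
value would otherwise always fail at its own bound, which would
contradict the intended no-op meaning.

## Normalization

TMM factors follow the canonical algorithm: reference sample = the one
whose upper-quartile depth-scaled count is closest to the mean upper
quartile; per-sample factor = 2^(precision-weighted mean of M-values
doubly trimmed at 30% (M) and 5% (A)); factors rescaled to geometric
mean 1. Trim fractions and the prior count (0.5) are the method's
canonical defaults — the analysis convention names the method, not its
parameters. logCPM uses the moderated transform with the prior scaled
by relative effective library size and the denominator offset by twice
the scaled prior, keeping the transform monotone and depth-invariant.
Correctness is pinned by a fixture frozen once from the reference
implementation (tests/data/, agreement to 1e−6).

The 0.5-CPM / 75%-of-discovery-samples detection filter computes CPM on
**raw** library sizes: detection precedes normalization in the pipeline
order, and whether scaled or raw CPM was intended is not pinned by the
convention; the choice is configurable. Batch-offset removal is
per-gene least squares under sum-to-zero coding, preserving the gene
mean, and is outcome-blind: it serves fold-change estimation and
display after testing, not the tests themselves.

## Differential signal

The per-gene test is the Mann–Whitney rank test (exact enumeration when
both groups have ≤8 samples and no ties, otherwise the tie-corrected
normal approximation), BH-corrected across the filtered gene universe.
The mixed-effects spline model used by full-scale cohort analyses is
deliberately out of scope; the rank test is this pipeline's DEG
selector and is labelled as such.

log₂FC = median(case logCPM) − median(control logCPM) per window. The
stability statistic bootstraps **participants** within each group
(percentile intervals, 1,000 iterations by default): for log₂FC > 0,
∂ = log₂FC − (5th bootstrap percentile); for log₂FC < 0,
∂ = (95th percentile) − log₂FC; CV = ∂/|log₂FC|. This one-sided reading
reproduces the defining property CV = 1 ⇔ the bound touches zero fold
change and CV > 1 ⇔ the interval crosses zero. ∂ is clipped at 0 (a
bootstrap percentile can land beyond the point estimate by sampling
noise); CV is undefined (NaN) at log₂FC = 0.

## Longitudinal trends

k-means (Euclidean, 25 greedy-k-means++ restarts, seeded) on the genes
× windows fold-change matrix for k = 1…16; k chosen at the kneedle knee
of the inertia curve (sensitivity 1.0), with near-ties (<1% relative
inertia difference) resolved toward smaller k — the simpler model — and
a manual override available. Inertia curves that are not nonincreasing
are smoothed by running minimum with a warning.

The permutation control permutes each gene's window values
independently. Its flatness summary holds the **unpermuted**
gene→cluster assignment fixed and recomputes per-cluster per-window
medians on permuted values: genuine time structure collapses to nearly
flat profiles. A k-means refit on permuted data is also returned for
inspection but is not the yardstick — refitting rediscovers artifact
clusters (rows grouped by where their large values landed), which is a
property of clustering, not of the data's time structure.

Heatmap segregation selects genes with |log₂FC| ≥ 1 and CV below 0.5
(0.4 in the 13–20-week window, whose larger gene yield would otherwise
exceed the sample count), tightening the CV cut in 0.05 steps until the
gene count does not exceed the window's sample count. Samples are
clustered on per-gene z-scores (average linkage, Euclidean), the tree
cut at two clusters, the majority-case cluster called the case cluster,
and the split's sensitivity/specificity reported. The two-cluster cut
and majority mapping are this package's choices; the source convention
reports the metrics without defining them.

## Tissue and cell-type signatures

Gini specificity G(x) = Σᵢⱼ|xᵢ−xⱼ|/(2T·Σx) ∈ [0, (T−1)/T], computed by
the sorted-vector identity with tiny negative float dust snapped to 0.
A gene joins a category's profile when G ≥ the source cut (0.6 tissue,
0.8 cell type) and its maximum (mean) expression is in that category;
strict tissue profiles additionally require an enriched/enhanced
annotation, guaranteeing single-category membership for trajectory
tracking. Cell-type subtypes can be merged into parent categories by
averaging their mean expression before the Gini step. Merging a
whole-body reference with individual-atlas annotations takes the union,
resolves per-gene conflicts toward the individual atlas, and requires
individual-atlas genes to also pass tissue-level specificity (G ≥ 0.6).

Enrichment is the one-sided hypergeometric survival function at k−1
with M = universe genes specific to any category, n = specific to the
tested category, N = differential genes specific to any category, k =
differential genes specific to the tested category; categories need
k ≥ 2 to be tested; BH across tested categories. The universe is
restricted to genes passing the detection filter (configurable) — the
convention does not name the universe, and N/k follow the standard
draws/successes reading.

Signature score = sum of logCPM over profile genes (≥5 present
required). The relative score subtracts the participant's post-partum
score, so post-partum samples score exactly 0 — the anchor chosen
because the pipeline tracks maternal organ state over gestation.
Scaling divides by the category's IQR of relative scores **without**
median centering, which would destroy the zero post-partum baseline.
Trajectories are per-group medians with a 75% bootstrap interval
(1,000 iterations), a non-parametric standard-deviation analogue.

## Risk classifier

Inputs are samples collected at 5–16 weeks of gestation. Normalization:
subtract the per-cohort per-gene median logCPM; divide by the gene's
discovery-cohort IQR (zero-IQR genes dropped); then subtract, per
sample, the median normalized value over internal-control genes —
genes with differential-stage BH-adjusted p > 0.99 — excluding controls
whose raw logCPM is exactly 0 (technical dropout). Note that only a
small minority of truly null genes attain adjusted p > 0.99 under BH
(the step-up correction leaves most null genes with adjusted p well
below 1), so the control set is a high-precision, low-recall sample of
the null pool; the tests assert its purity, not its coverage.

Training splits the discovery cohort 80/20 by participant (stratified
by outcome). Fold change and CV for pre-selection are computed on the
80% split only. The grid — fc_cut ∈ {0, 0.25, 0.5, 0.75, 1.0},
cv_cut ∈ {0.25, 0.5, 0.75, 1.0}, C over 6 log-spaced values in
[1e−2, 1e3], l1_ratio ∈ {0.1, 0.5, 0.9} — is scored by 5-fold
stratified **grouped** CV AUROC on the 80% split (groups =
participants, guarding against repeat-sample leakage across folds),
plus the 20%-split AUROC of the model fitted on the full 80%. The
selected point maximizes the minimum of the two AUROCs; ties are
resolved toward the **larger** gene set, the package's robustness
choice (a broader panel degrades more gracefully under single-gene
dropout, and performance empirically improves with panel size in the
subset sweep). An empty pre-selection result is an invalid grid point.
The winning model is the one fitted on the 80% split — no refit on the
full discovery cohort; only threshold tuning sees all discovery
samples. The threshold is the smallest one attaining FPR ≤ 10% on the
discovery ROC, rounded to the nearest 0.05 with halves away from zero;
the call rule is positive iff P(case) ≥ threshold, and participants
with several eligible samples are scored by their maximum probability.

The subset sweep retrains (C, l1_ratio re-tuned, no pre-selection) on
seeded random gene subsets per size and reports test AUROC with a
weakly-predictive flag (AUROC > 0.5).

## Performance metrics

Proportions carry 90% Jeffreys intervals — Beta(x+½, n−x+½) quantiles
with exact endpoints at x = 0 and x = n; zero-denominator metrics are
undefined (NaN), never 0. AUROC is the rank statistic with ties counted
half; its default CI is the Hanley–McNeil binormal-exponential standard
error with a normal quantile, clipped to [0, 1] — the named "binormal
approximation" is underspecified, so a nonparametric bootstrap CI is
available behind a flag. Report rounding is half away from zero to
whole percent.

## Synthetic cohorts: what they emulate, and what they do not

Counts are negative binomial with per-gene log-normal baseline
abundances, gamma dispersions (mean 0.2), log-normal library sizes
(median 2×10⁶, σ 0.3), per-batch per-gene log₂ offsets (σ 0.15), and
planted case effects as per-window multiplicative fold changes. The two
default trend shapes bracket the magnitudes the analysis is designed to
detect: a V-shaped decrease (−0.38, −0.585, −0.38 log₂ units, minimum
at mid-gestation, attenuated to −0.05 post-partum, mimicking a
placenta-linked signal that resolves after delivery) and an early peak
(+0.8, +0.8, +0.38, +0.38). Default cohort sizes (49 controls / 24
cases), gene counts (6,000 with 7.5% planted differential genes split
40:60 between the shapes) and 66 housekeeping genes mirror a realistic
discovery cohort; tests use smaller instances of the same generative
process, with sizes stated in each test. QC metrics are simulated at
metric level (beta degradation, log-normal contamination) with a
planted outlier fraction pushed past the clean 95th percentile —
read-level simulation is alignment-scale and out of scope. The
reference atlas gives each category exclusive high-expression genes
with a tunable leakage term, optionally aligned with the cohort's
planted early-peak genes so signature recovery is testable end to end.

Not emulated: fragment-level cfRNA biophysics, sequencing depth of tens
of millions of reads, gene–gene correlation beyond compositional
coupling, ambient/contaminating RNA structure, and real clinical
covariates (BMI, race/ethnicity, fetal sex). Passing recovery tests
therefore demonstrates the statistical machinery is correct and
well-calibrated under its stated model, not that real cohorts will
reach the same operating points — on clean synthetic signal the
classifier's held-out AUROC is near-perfect, which real plasma data
will not reproduce.

## Numerical conventions

Seeds thread through every stochastic step (simulation, bootstraps,
k-means restarts, CV folds, subset sampling); identical config + seed
reproduces output tables byte-for-byte. Quantiles are linear-interpolated
order statistics throughout. Degenerate inputs fail loudly with the
offending identifiers (duplicate ids, negative counts, all-zero
samples, empty groups, single-class splits), except where a documented
degradation applies (missing atlas or QC table → stage skipped with a
logged notice; all-zero control genes in a sample → no shift, warning).

## Known limitations

The rank-test DEG stage is less powerful than the spline mixed model it
stands in for and ignores gestational-age trends within windows. The
elbow rule inherits kneedle's sensitivity to flat inertia curves (the
near-tie rule and the manual override mitigate this). Hypergeometric
enrichment treats profiles as fixed and ignores expression-level bias
in category assignment. The Hanley–McNeil CI undercovers for AUROC near
1 with small samples — the printed intervals there are optimistic; use
the bootstrap flag when it matters.
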