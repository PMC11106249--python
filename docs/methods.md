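# Methods

This note documents the statistical model behind each stage, the defaults
and why they hold, the numerical choices that affect results, what the
synthetic data do and do not emulate, and known limitations.

## Study design assumed by the pipeline

Three taxa with declared phylogenetic roles: two ingroups bearing the
structure under test (cattle horn buds at two juvenile ages with a skin
control; deer antler tissues with skin and bone controls) and one outgroup
without it (pig skin, bone, cartilage). Every taxon also carries the six
pooled somatic organs (muscle, kidney, heart, liver, spleen, lung) that
serve as the common DE reference, and every tissue has at least three
biological replicates. Each taxon's matrix is filtered and normalized
separately; cross-taxon comparisons happen only at the level of per-gene
calls, matched by uppercase gene symbol. Symbols absent from a taxon's
filtered universe are carried as `absent`, which is distinct from `ns`
(tested but not significant): an ingroup cannot gain support from an
absent gene, while an absent outgroup gene is non-contradicting.

## Filtering, TMM, grouped LCPM

*Filter.* Keep gene *g* iff (a) there exists a tissue in which **every**
sample has CPM ≥ `cpm_min` (default 10) and (b) total CPM across samples is
≥ `cpm_total_min` (default 15), CPM computed on raw library sizes. Verbal
descriptions of this kind of filter are usually ambiguous about how the
CPM condition quantifies over samples and tissues; this package fixes the
reading above, exposes both thresholds in the config, and resolves every
threshold boundary to "≥". The filter is monotone: raising `cpm_min` never
adds genes.

*TMM.* Reference sample = the one whose 75th-percentile CPM (type-7,
linear-interpolation quantile — fixed so the choice is deterministic) is
closest to the mean 75th percentile. For each sample, per-gene
M = log₂ ratio vs reference and A = average log₂ abundance over genes
positive in both; drop the top/bottom 30% of M and 5% of A (the method's
published defaults, configurable); factor = 2^(weighted mean of remaining
M) with inverse binomial-delta-method variances as weights; factors
rescaled to geometric mean 1. Because the precision weights depend on
absolute counts, scaling one column by c changes that sample's factor very
slightly (≈0.03 on a 40-gene toy) even though M-values and trimming are
exactly invariant; tests assert the invariance at 0.05 absolute tolerance.

*Grouped LCPM.* Per (taxon, tissue): `log2((Σy + 0.5) / (Σ N·f) · 1e6)`
with the 0.5 prior count, or exactly `lcpm_zero_sentinel` (−21) when the
group's raw sum is zero — the sentinel is what downstream exclusion logic
consumes, so it is hard-coded rather than emerging from a depth-dependent
prior. Genes are retained when ≥ two-thirds of replicates in at least one
tissue have raw count ≥ 10 ("at least one" rather than "every" tissue;
under "every", nearly all genes would fail in a many-tissue design).

## Differential expression

NB log-linear model per gene with offset log(effective library size) —
TMM-effective sizes enter only through the offset; no re-normalization
happens inside the fit. The design is intercept + test indicator (all test
tissues vs the pooled somatic group) + categorical covariates (age, sex,
species where they vary). Covariate collinearity is detected by design-
matrix rank and raises an error naming the offending covariate — never a
silent drop. This is why the per-age horn-bud models omit the age
covariate by construction.

Dispersion: an initial fit at φ = 0.1 gives fitted means; the Cox–Reid
adjusted profile likelihood is evaluated on a 61-point log-spaced grid
(10⁻⁴–5) with means held fixed (one-step approximation), maximized with
parabolic refinement; a lowess trend (frac 0.5) of log φ over average
log₂-CPM gives the abundance trend (floored at 10⁻⁶, hence non-negative);
the tagwise estimate is shrunk toward the trend by a log-space weighted
average with prior weight `dispersion_prior_df` (default 10) against the
per-gene residual df, so the shrunk value always lies between tagwise and
trend. Testing: full and reduced (no test column) fits at the shrunk φ;
quasi-dispersion s² = deviance/df is moderated across genes by
moment-matching a scaled-F prior (trigamma inversion); the contrast is an
F statistic (deviance difference over moderated s²) on (1, d₀ + df) df.
The contract here is calibration, not numerical identity with any existing
implementation: under a pure null (2000 genes, φ = 0.1, 3 vs 3) the
fraction of p < 0.05 sits in [0.03, 0.07] across seeds, and planted
2-log₂-unit effects at μ ≈ 100 are recovered to within ±0.3 in the median.
BH adjustment is applied within each analysis (per contrast, the
convention of the standard tooling); `direction` is a pure function of
(FDR, sign of log₂FC, α). IRLS numerical guards: linear predictor clipped
to ±45, a 10⁻¹⁰ ridge on the normal equations, deviance-change convergence
at 10⁻⁹.

## Tau specificity

τ = Σ(1 − x̂ᵢ)/(n − 1) on LCPM clipped below at 0 (the τ formula requires
nonnegative input; the −21 sentinel therefore reads as zero expression).
τ is computed over **all** tissues of the taxon (test + controls +
somatic) by default. Thresholds: strict τ ≥ 0.9 with the single argmax
tissue (ties broken lexicographically by tissue name); relaxed τ ≥ 0.75
with assignment to every tissue whose x̂ ≥ `relaxed_assign_frac` (0.75) —
the multi-tissue assignment rule is this package's construction, exposed
in config; the packaged worked-example tables do not depend on it. The
source descriptions mix "τ > 0.9" and "τ ≥ 0.9"; "≥" is used throughout.
Genes assigned (under the applicable rule) to a skin/bone/cartilage
control tissue are flagged `control_specific` and excluded from τ-based
homology.

## Gene-set ranking and regulator overlaps

The competitive test compares the mean signed z statistic of a set
(z = Φ⁻¹ transform of the DE p-value, signed by log₂FC) against the
complement, with the set-mean variance inflated by VIF = 1 + (m−1)ρ̄.
ρ̄ is the mean pairwise correlation of the set genes' model residuals on
the log₂-CPM scale, estimated per set (a fixed-ρ̄ override exists) and
floored at 0 so VIF ≥ 1 (conservative). With ρ̄ = 0 the test reduces to a
plain two-sample location test; under the null the p < 0.05 rate is
0.03–0.07. Sets with fewer than two members in the universe are skipped
with a warning and listed. Direction is reported as
overexpressed/underexpressed ("Up"/"Down"). Regulator overlaps are local
hypergeometric upper tails P(X ≥ k | N, K, n) after intersecting set,
target list and universe, BH-adjusted across all (set, regulator) pairs;
significant regulators are cross-flagged when the regulator gene itself is
DE in a supplied analysis. Gene symbols are matched uppercase (no network
identifier service).

## SOM and k-medoids

Input: genes significantly DE in ≥ 1 test analysis but not in every one,
profiles = concatenated per-taxon tissue LCPM columns over the
intersection of the three taxa's filtered gene universes, standardized per
gene (constant rows dropped and recorded). Training is online Kohonen on a
rectangular grid (topology is configurable; rectangular keeps neighbor
math simple) with sum-of-squares distances: codebooks initialized from
sampled data rows under the run seed; genes sorted lexicographically then
shuffled per epoch by the seeded generator, so input order cannot matter;
learning rate linear 0.05 → 0.01; radius linear from ⌈⅔·grid diagonal⌉ to
1 with a **strict** cutoff, so the final phase updates only the
best-matching unit (k-means-like). Quantization error is measured before
and after training; with realistic clustered profiles and ≳ 10 genes per
unit it decreases. On sparse maps (≈5 genes/unit) the sampled-row
initialization is already a near-optimal quantizer and topological
smoothing can leave the end state slightly above it — the acceptance
measurements therefore use the full-scale density (9433 genes on 20×20,
≈23.6 per unit).

k-medoids is classic PAM (greedy BUILD, exhaustive SWAP) on Euclidean
distances, deterministic, validated against exhaustive search on small
instances. The gap statistic uses Tibshirani's within-dispersion
W_k = Σ_clusters (pairwise squared distances)/(2·size), B uniform
reference draws over each codebook dimension's observed range (the simpler
non-PCA-rotated variant; zero-range dimensions dropped with a warning),
s_k = sd·√(1+1/B), and picks the smallest k with Gap(k) ≥ Gap(k+1) −
s_{k+1}. On raw well-separated blobs it recovers the planted k in ≥ 18/20
seeds; note that on SOM codebooks the interpolating units between
expression programs form bridges that can push the chosen k above the
number of underlying programs — cluster counts chosen on a codebook
describe the map, not directly the genes. Cluster summaries are mean
unclipped LCPM per (cluster, tissue) excluding sentinel entries; empty
cells are missing, never zero.

## Homology calls

Within-species step: an appendage signal (direction ∈ {up, down})
survives iff every within-species control (cattle skin; deer skin *and*
bone — both are required) is ns/absent or significant in the **opposite**
direction. Exclusion is on direction alone, with no magnitude test.
Opposite-direction control significance retains the gene and records a
flag (`opposite_in_<control>`), the pattern of genes underexpressed in
appendages but overexpressed in ordinary bone.

Cross-species step: a gene is homologous iff some ingroup-A analysis and
some ingroup-B analysis share a surviving direction, and **every**
outgroup analysis is ns, absent, or opposite to it. Same-direction
outgroup significance → `excluded_outgroup`; support in only one ingroup →
`not_shared`; no outgroup data → `untestable_missing_outgroup` for every
shared-direction candidate (outgroup conditioning is the point of the
procedure, so its absence is surfaced, never skipped). The decision is a
pure function of the per-gene direction map and is verified against an
exhaustive truth-table oracle over all 4⁹ combinations of three analyses
per taxon. If a gene (rarely) shares both directions, each is checked
against the outgroup and a passing one wins, which preserves the
monotonicity properties: removing the outgroup never creates a homologous
call, and adding an ingroup analysis never flips homologous → not_shared.

τ-based homology mirrors this: specific to ≥ 1 appendage tissue in both
ingroups at the chosen threshold, not control-specific in either ingroup,
and not specific to any outgroup tissue *at the matching threshold* (the
source does not state which threshold applies to the outgroup; matching is
the symmetric choice). Shared proportions: for horn analysis h,
total_h = homologous genes supported by h (a gene supported by both ages
counts toward both), shared(h, t) the subset also supported by antler
tissue t, proportion = shared/total (missing when total = 0); rounded
half-up to 2 decimals only in human-readable summaries.

The combined-age horn analysis participates as its own analysis alongside
the per-age ones; in the one-tissue-per-age layout the per-tissue
appendage fits would duplicate the per-age fits and are therefore not run
separately.

## Synthetic data: what it emulates, and what it does not

Counts are NB(μ, φ), var = μ + φμ², with gene-wise φ log-uniform on
0.05–0.4 (the tagwise-dispersion world the GLM assumes), gene baselines
log₂-uniform on 3–9, and per-sample library factors log-uniform on 0.5–2
so TMM has real work. Planted classes (5% of genes each by default,
counts = floor(n·fraction), remainder null): homologous genes shifted
±2 log₂ units in all appendage tissues of both ingroups; skin-shared genes
shifted in one ingroup's appendage *and* skin; bone-program genes shifted
in ingroup appendages plus every bone-like control of all taxa (deer bone,
pig bone, pig cartilage) — exercising both exclusion routes; taxon-specific
genes shifted in one ingroup only; tissue-specific genes given a low
baseline (non-target tissues just above the LCPM clip point) plus a
single-tissue enrichment calibrated by bisection so that τ computed on
expected LCPM (including the 0.5 prior and replicate count) hits
`target_tau` (default 0.95) — without the low baseline, a τ of 0.95 on the
log scale would require astronomically large fold changes. Directions
alternate deterministically; per-taxon RNG streams are keyed by taxon
name from the master seed, so adding a taxon never perturbs another's
counts. Sample covariates: sex and (for deer) species cycle with an offset
per tissue so they are never mutually collinear; somatic-organ ages cycle
through both horn-bud ages and adult so the combined-age model is
estimable (with disjoint age vocabularies between test and control groups
the age factor would be confounded with the test indicator for *any*
number of levels).

Not emulated: batch effects beyond library size, gene length and GC
composition, read-level error, correlated gene programs in the null
background, ortholog mismatches between annotations, and real inter-species
divergence (the species covariate is a simple additive log-mean shift of
configurable size — its realistic magnitude is not identifiable from the
study design). Passing tests therefore demonstrate that the *procedures*
are correct and calibrated under the declared model, not that the model
captures every property of real cross-species RNA-seq.

## Problem sizes and tolerances used in tests

Type-I calibration at 2000 genes, 3 vs 3, φ = 0.1, band [0.03, 0.07];
effect recovery at μ ≈ 100 within ±0.3; end-to-end recovery pooled over
20 simulated datasets of 2000 genes (sensitivity ≥ 0.8, exclusion of
skin-shared and outgroup-shared classes ≥ 0.95); gap recovery on four
10-σ-separated 5-dim blobs of 12 points, k_max 6, B = 20, ≥ 18/20 seeds;
BH checked against a brute-force step-up oracle on 10,000 random vectors;
TMM against a from-definition oracle at 10⁻⁶; the τ and hypergeometric
formulas against hand-evaluated values at 10⁻¹². The acceptance script
re-runs scaled versions of these (5 end-to-end seeds, the full-density SOM)
in about two minutes.

## Known limitations

- TMM column-scaling invariance is approximate (precision weights), see
  above.
- The quasi-likelihood machinery is not a bit-for-bit reproduction of any
  reference implementation; only its calibration contract is guaranteed.
- camera-style ranking uses the two-group z formulation; no rank-based
  fallback for heavy-tailed statistics.
- PAM is exhaustive-SWAP and scales to a few hundred points (map units),
  not to thousands.
- The homology layer consumes only direction and significance; effect
  magnitudes are reported but never compared across taxa.
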