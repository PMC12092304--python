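# Methods

This note records the models, parameter choices and numerical decisions
behind `plaqniche`, and what the synthetic-data guarantees do and do not
establish about real tissue.

## Raster model

Stain images are single-channel 8-bit rasters with a known μm-per-pixel
scale. Cleaning is strict thresholding (`value > threshold`), optional
median despeckling, `close_rounds` dilate+erode pairs with a 1-px disc
(8-connectivity; the smallest isotropic structuring element), and removal of
connected components outside a size window expressed in μm² so that results
are resolution-independent.

The decayed niche expansion assigns, to every pixel within 100 μm of the
plaque mask, the band intensity floor(255·(1 − k/6)) where
k = ⌈d/20 μm⌉ ∈ {1..5} and d is the exact Euclidean distance (on pixel
centres) to the nearest mask pixel; interior pixels keep 255, pixels beyond
the halo are 0. The linear decrement is a design choice — only the
existence of a stepwise decay, the 100 μm halo and the 20 μm band width are
externally fixed; the chosen band values (212, 170, 127, 85, 42) make spots
dominated by plaque or first-band signal exceed the rich threshold of 183
on the same 0–255 scale. Distances are measured from the mask boundary
(d = 0 inside), and band boundaries agree with an exact distance transform
by construction.

Vascular amyloid arrives as a label raster (a classifier or manual
annotation is assumed upstream); the labels are dilated twice with the same
1-px disc, the overlap with the amyloid mask is vascular, and the residual
is cortical. The two compartments always partition the mask.

## Spot grid and niche

The capture array is a pointy-top hexagonal lattice: row spacing
pitch·√3/2, odd rows offset +pitch/2, so interior spots have six neighbours
at exactly one pitch (100 μm by default, 55 μm spot diameter). Neighbour
*order* is graph distance on the hex lattice, computed via axial
coordinates from the offset (row, col) pair — not a Euclidean radius. For
order 2 this gives twelve spots at √3·pitch and 2·pitch, so the niche
(rich spots plus order-≤2 neighbours) reaches exactly 200 μm
center-to-center at 100 μm pitch.

Spot-level amyloid intensity is the mean raster value over the spot disc
(a max aggregator is available behind a flag); a spot is Aβ-rich iff its
intensity strictly exceeds the threshold (default 183). Vascular spots and
their first-order neighbours are excluded before niche assembly, and
exclusion overrides richness — a rich spot adjacent to vascular amyloid is
dropped and does not seed a niche. Niche neighbours are restricted to gray
and white matter. The four classes (rich, neighbor, outside, excluded)
partition the spot set.

Cell-type enrichment rules operate per sample. In top-quantile mode the
threshold within each region group is the ⌈q·n⌉-th largest abundance and
ties at the boundary are all included (so at least ⌈q·n⌉ spots are
selected); in z-score mode spots must strictly exceed mean + z·s.d. of the
pooled allowed-region abundances (sample s.d.; an all-constant region
selects nothing). The default rule table
(`src/plaqniche/data/enrichment_rules.yaml`) encodes the per-cell-type
region restrictions and quantiles and is editable without code changes.

Nuclei-to-plaque distances use the exact distance transform of the plaque
mask; a nucleus is "near" iff strictly below the 20 μm cutoff. Enrichment
ratios compare near-bin vs far-bin composition per cell type with a
chi-square test on the 2×2 table.

## Differential expression

**Balanced downsampling.** Constraints: no sample holds more than 50% of a
multi-sample group, no group exceeds 3,000 units, groups differ at most
3-fold. The constraint *order* (sample share → group cap → fold cap,
iterated to a fixed point) is a package decision; the share fix trims the
largest sample to floor(0.5 · current group total), which converges to a
state that satisfies the cap exactly (a ceiling-based trim can stall one
unit above it). Single-sample groups are exempt from the share rule, whose
premise is multi-sample composition. All subsampling is uniform without
replacement from one seeded generator.

**Gene filters.** Detection is count > 0. The pseudobulk and
high-definition routes require detection in ≥1% of either group; the
hurdle route requires ≥1% of both groups and ≥10% of either. Symbols
starting with RPS, RPL, MT or HB are excluded case-sensitively.

**Pseudobulk NB route.** Counts are summed by donor; each gene is fitted
with an NB GLM (log link, offset = log donor library size) on the group
effect plus standardized covariates. Dispersion is estimated per gene by
profile maximum likelihood with a Cox–Reid adjustment
(−½ log det X′WX), which removes the substantial downward bias plain ML
shows at ≤12 donors; log-dispersions are then shrunk 50/50 toward a
degree-1 trend on log-mean (near-Poisson ceiling estimates are excluded
from the trend fit, as they carry no dispersion signal). The Wald
statistic for the group coefficient is referred to a t distribution with
2·(n_donors − p) degrees of freedom: the residual df, doubled to credit
the information the trend shrinkage pools across genes. This moderated
reference keeps the null type-I error near nominal both when dispersion is
well determined and when it is replicate-limited; a plain normal reference
is anticonservative at cohort sizes of ~6 donors per group. All filtered
genes receive p-values (no independent filtering); BH across tested genes;
significance at adjusted p < 0.05 and |log2 FC| ≥ log2(1.5). No fold-change
shrinkage is applied; unshrunk estimates are reported.

**Hurdle route.** Expression is log1p of counts scaled to the median
library size (natural log). Per gene, a logistic model of detection and a
Gaussian linear model of positive expression are each compared to their
group-free null by likelihood ratio; the combined statistic is the summed
LR χ² on summed df. A component that is inestimable — all-detected or
never-detected genes, separation, rank deficiency, fewer than 3 detected
units — contributes 0 with 0 df, so a fully detected gene reduces to the
continuous LRT alone. The reported log2 FC is the difference of group
means of normalized expression divided by ln 2, independent of the model
fit. The sample identifier is *not* fitted: in a two-group design where
each donor belongs to one group it is aliased with the group effect, and
the design builder raises a collinearity error naming the aliased columns.
A mixed-model backend would be required to absorb donor identity as a
random intercept; the fixed-covariate surface (`DesignSpec.random_effect`)
is reserved for that and currently dummy-codes the column when it is not
aliased.

**Protein route.** Isotype-normalized counts (rounded with a warning if
non-integer) are fitted per protein with the same NB machinery at the unit
level, with latent covariates (standardized CDR, region) and no
library-size offset — isotype normalization already corrects capture
depth, and a total-count offset would leak composition bias from
responsive proteins into the panel.

**Markers.** Wilcoxon rank-sum one-vs-rest per cluster on genes detected
in strictly more than `min_pct` (default 25%) of the cluster, BH within
cluster, positive-LFC only by default; the niche-cluster contrast profile
uses min_pct 0.1, both signs and the log2(1.5) threshold.

## Trajectories

LOESS is local *linear* regression (degree 1) with tricube weights over
the ⌈span·n⌉ nearest neighbours in density, span 0.75, no robustness
iterations — the defaults of the classical implementation, stated
explicitly because only the span is externally fixed. Predictions are
evaluated on 100 evenly spaced points over the observed density range
(grid size is a package choice) and z-standardized per gene across the
grid; genes with near-zero prediction variance map to the all-zero row, so
standardization also makes the output invariant to affine rescaling of the
input. Clustering is complete-linkage agglomerative on Euclidean distances
between standardized rows; k is a configuration value, and labels are
renumbered by descending cluster size. Standardization is per gene (the
alternative — pooled scaling within a comparison group — changes only a
global scale factor per gene set and not cluster assignments on
standardized rows).

## Ranking

PFC uses log base 10; the base rescales all values by one positive factor,
so every rank-based downstream quantity (percentiles, combination,
enrichment ordering) is base-invariant, which the tests verify by
recomputing with natural log. Percentiles are 100·rank/n with average-rank
ties; genes missing from one table are excluded from combination rather
than imputed. Divergence is pfc_a − pfc_b, ordered by magnitude with
opposite-sign pairs above same-sign ties. Preranked enrichment uses the
weighted KS running sum (weight exponent 1) with a *gene-permutation* null
(uniform random same-size sets), NES = ES / mean |null ES| of matching
sign, and a two-sided tail-count p with +1 smoothing; sets with fewer than
3 mapped genes are skipped, and a set covering the whole ranking is
rejected (its complement, hence the down-step, is undefined).

Covariate-adjusted Spearman rank-transforms x, y and each covariate,
residualizes the x- and y-ranks on the covariate ranks by least squares,
and reports the Pearson correlation of residuals with a t p-value on
n − 2 − c df. Without covariates this is exactly Spearman's ρ. Rank
residualization is linear in rank space, so under very strong confounding
a small residual association can remain — the package's simulations show
correct behaviour for moderate confounders.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
parameters chosen once as plausible for AD cortex; none are fitted to
data, and the generator is a pure function of (params, seed):

| parameter | default | rationale |
|---|---|---|
| plaque rate | 10 / mm² | mid-range cortical plaque density in AD |
| plaque radius | log-normal, median 25 μm, σ=0.3 | typical dense-core plaque sizes |
| vascular fraction | 0.15 | minority CAA component on vessel polylines |
| recruitment near/far | 0.6 / 0.05 | strong myeloid bias within one radius of a plaque boundary |
| genes | 2,000 | desk-scale panel |
| niche program | 100 genes, max LFC 1.5, e-folding 50 μm | effect decays with distance to the plaque boundary |
| group program | 100 genes, |LFC| 1.5 | treatment-responsive program |
| NB dispersion θ | 10 | moderate spot-level overdispersion |
| library size | log-normal, median 8,000, σ=0.3 | spot UMI totals |
| cohort | 6 donors/group × 2,000 spots | the default comparison size |

Counts are NB with mean libsize·baseline·2^(effects) and
Var = μ + μ²/θ, one θ for all genes at the spot level; donor sums then
carry the aggregate overdispersion the pseudobulk route must estimate.
Metadata carries donor-level sex, age and gDNA %, plus the per-spot
cellular detection rate (CDR = fraction of genes with count > 0).
Abundance tables are per-spot Dirichlet draws scaled by a Poisson
total-cell count, with the microglia concentration multiplied by
(1 + boost·e^(−d/50 μm)).

What the generator does *not* emulate: staining artifacts and lipofuscin,
segmentation errors, spatial autocorrelation of expression beyond the
plaque-distance effect, donor-level random expression shifts beyond the
planted programs, mean-dependent dispersion, and the posterior uncertainty
of a real deconvolution model. Passing the calibration and recovery
guarantees therefore shows the machinery is correct under its own
assumptions, not that real-tissue error rates equal the nominal ones.

## Problem sizes and numerical choices

The statistical guarantees are exercised at 2,000 genes, 12 donors and
2,000 spots per donor — a size chosen to make donor-level and spot-level
inference behave as in a full study while keeping the suite quick to run.
Dispersion optimization is bounded on log θ ∈ [log 10⁻³, log 10⁷] with
1e-3 tolerance; GLM fits use statsmodels IRLS with up to 100 iterations;
degenerate LOESS windows (zero x-spread) fall back to the weighted mean;
adjusted p-values of 0 are floored at 10⁻³⁰⁰ before logging with a
warning. Quantile ties, the strict 183 and 20 μm cutoffs, and the
downsampling fixed point are covered above.

## Known limitations

- No mixed-effects backend: donor identity cannot be absorbed as a random
  intercept in the hurdle route (see above).
- No fold-change shrinkage for ranking-stage LFCs.
- The protein route assumes isotype normalization has removed depth
  effects; violations surface as panel-wide composition bias.
- Preranked enrichment reports no leading-edge subsets and uses plain
  permutation p-values (no adaptive refinement), so the smallest
  attainable p is 1/(n_perm + 1).
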