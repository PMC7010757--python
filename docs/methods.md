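# Methods

This note documents the statistical models and procedures implemented in
`macrodiv`, the choices made where the design was genuinely open, and what
the synthetic-data experiments do and do not demonstrate.

## Diversity estimation

**Nucleotide diversity.** For one species' aligned sequences within one
grid cell, Π is the mean over sequence pairs of k_ij/m_ij, where m_ij
counts aligned columns at which both sequences carry a base and k_ij those
among them that differ. A column with a gap in either sequence contributes
to neither count. Pairs whose shared fraction m_ij/L (L the aligned
length) is not strictly greater than 0.5 are discarded — partial barcodes
that barely overlap produce wildly unstable ratios. Two open choices:

- *Overlap denominator.* "Overlap" is measured against the species'
  aligned length, the only extent common to both sequences.
- *Divisor.* When pairs are discarded, dividing by C(n,2) would shrink Π
  toward zero for species with many partial sequences; we divide by the
  number of pairs actually used so Π stays a well-defined mean. The C(n,2)
  variant is available (`divisor="all_pairs"`) for sensitivity checks.

Π is a per-site proportion in [0, 1]; ratios are accumulated in pair order
and the implementation is tested for exact (bit-level) agreement with a
brute-force pair/column enumeration.

**Cell-level genetic diversity.** GD is the unweighted arithmetic mean of
Π across the species sampled in the cell: a species with 50 sequences and
a species with 2 count equally, which keeps GD from being dominated by
heavily sequenced taxa. Cells enter the main analysis with ≥ 2 sequences
and ≥ 2 species; a stringent variant (≥ 5 sequences, ≥ 8 species, ≥ 5%
taxonomic coverage) is exercised by the robustness sweep. Latitude-band
summaries report mean GD with a dispersion of sd/√n_cells per 10° band.

## Grid

All aggregation uses a cylindrical equal-area (Behrmann) projection with
standard parallel 30° and the authalic Earth radius 6 371 007.181 m (the
standard choice for equal-area work; no radius is canonical for this
projection). Cells are 200-km squares in the projected plane, half-open on
the increasing side, with a cell corner anchored at projected (0, 0) — the
anchor is a convention, so absolute cell ids are comparable only within a
configuration, not across tools. Equal cell area is exact by construction;
no land/sea mask is applied at grid level.

## Species richness

A species' range is the convex hull of its occurrences, built separately
in four world quadrants (hemisphere × longitudinal halves split at 20°E
and 160°W, approximating an Atlantic / Indo-Pacific divide) so that, for
example, antitropical distributions do not acquire a cross-equator bridge.
One- and two-point quadrants yield degenerate point/segment ranges that
still occupy their cells. Ranges are rasterized by polygon–cell
intersection in the projected plane directly at grid resolution. Marine
ranges can be clipped by depth: with the strict rule (default) a cell is
removed when its maximum depth falls outside the species' known
[depth_min, depth_max]; a lenient variant keeps cells deeper than the
species' maximum. The quadrant meridians and both depth rules are
configurable because no single convention is canonical.

## Spatial statistics

**Moran's I** uses the standard cross-product form with arbitrary
non-negative zero-diagonal weights; correlograms use equal-width distance
classes with binary membership weights and per-class permutation p-values.

**Modified t-test.** The Pearson correlation r of two co-located fields is
unchanged; only its reference distribution is corrected. Each field's
spatial autocorrelation is estimated per distance class (13 equal-width
classes by default, the common default of the reference implementation)
with the moment estimator ρ̂(h) = mean of centred cross-products within
class h over the field variance. The implied correlation matrices Rx, Ry
(entry = ρ̂ of the pair's class, unit diagonal) combine with the centring
matrix B = I − 11′/n into the effective sample size

    ess = 1 + tr(B Rx) tr(B Ry) / tr(B Rx B Ry),

the reciprocal of the approximate variance of r under independence
(Dutilleul's correction; clamped to [3, n]). F = (ess − 2) r²/(1 − r²) is
referred to F(1, ess − 2). Validation is by type-I-error simulation: on
1000 pairs of independent Gaussian random fields with exponential
covariance (range two cell widths, 100 cells) the corrected test rejects
at ≈ 0.045 at the 5% level while the naive t-test rejects at ≈ 0.29.
A known limitation, reproduced here: under *Gaussian*-covariance
(mean-square differentiable, very smooth) fields the correction remains
somewhat liberal (~0.08–0.13 in the same design); the corrected p-values
for such ultra-smooth fields should be read with that in mind.

**Autocovariate.** The spatial predictor at a cell is the distance-weighted
mean of the response over neighbours within 200 km (inverse-distance
weights by default, equal weights optional); on a 200-km grid this is the
rook neighbourhood. Because the response is autocorrelated partly because
the environment is, the autocovariate is regressed on the full set of
environmental predictors and its OLS residuals — orthogonal to every
environmental column by construction — enter the model as the variable
`autocor`. Cells with no neighbour within the radius are dropped from the
model and counted.

**Residual check.** After model selection, residuals are tested with
Moran's I under symmetrized nearest-neighbour (k = 1) weights and 1000
permutations, one-sided for positive clustering, with the
(1 + extreme)/(1 + n_perm) p estimator. A non-significant result indicates
no major spatially structured driver is missing.

## Regression layer

GD is transformed as log(GD + ε), then centred and scaled to unit variance
(sample sd, matching the R `scale` convention). ε defaults to half the
smallest positive GD — GD can be exactly zero, and this keeps such cells
in the analysis without dominating the log scale; ε is configurable.
Environmental predictors are standardized; the sampling covariates
(numbers of sequences and of genetically sampled species per cell) are
log1p-transformed then standardized, as right-skewed counts.

- **VIF screening** iteratively removes the predictor with the highest
  variance inflation factor while any exceeds 5 (1/(1 − R²) of each
  predictor on the others); perfect collinearity surfaces as infinite VIF
  and is removed first; ties break by column order.
- **OLS fits** report 95% t-based confidence intervals, adjusted R², and
  AIC computed with the Gaussian log-likelihood counting the error
  variance as an estimated parameter (the R convention; the constant
  offset is irrelevant to model comparison).
- **Stepwise selection** is backward-forward on whole terms (categorical
  factors move as blocks), minimizing AIC, deterministic with ties broken
  toward the earlier candidate; the sampling covariates are forced and can
  never be dropped, since they encode observation effort rather than
  hypotheses.
- **Hierarchical partitioning** fits all 2^k predictor subsets and assigns
  each predictor the average R² increase over all orderings (subset-
  weighted form); relative variance re-expresses independent contributions
  as percentages of their sum, which equals the full-model R². Limited to
  k ≤ 12; exactness is tested against an explicit all-orderings oracle.
- **Habitat comparison.** Pooled cells from two habitats are compared by
  regressing transformed diversity on latitude (continuous, in degrees;
  an absolute-latitude variant is a one-line change at call site) and a
  0/1 habitat indicator, with the habitat factor's partial variance from
  hierarchical partitioning. A one-region-versus-rest Wilcoxon rank-sum
  helper covers region-level contrasts.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes,
with every parameter recorded as ground truth:

- **Environment**: zero-mean unit-variance Gaussian random fields
  (white noise smoothed with a Gaussian kernel; correlation length 600 km
  on a 200-km grid by default) for temperature, chlorophyll and slope; two
  regions split the world east/west.
- **Diversity link**: per-cell log expected diversity is
  α + β·env + region offset, with α = log 0.008 (a realistic per-site
  baseline for mitochondrial barcodes), β = (0.25, 0, 0) and an
  Indo-Pacific offset of 0.25 by default. Species (sd 0.4) and
  species-by-cell (sd 0.2) lognormal noise model unexplained variation —
  the error structure of real per-cell diversity estimates is unknown, so
  this is a modelling choice, flagged as such.
- **Sampling**: each species occupies a disc of cells (radius 4 cells)
  around a centre drawn with weight exp(0.75 × temperature), so warm cells
  host more species and genetic and species diversity share a weak common
  driver; ~8 cells per species are genetically sampled with 2 + Poisson(2)
  sequences per species-cell. 70% of species are labelled marine.
- **Sequences**: star genealogy — tips descend independently from a common
  random ancestor, substituting per site with probability p solved from
  2p(1 − p) + (2/3)p² = θ so the *expected pairwise* difference fraction
  equals θ exactly (p ≈ θ/2 only to first order; the exact solution
  matters at θ ≈ 0.05). Sequences are 650 bp, gap-free A/C/G/T, marker
  "COI-5P" — every emitted record passes the filter chain by construction,
  and the generator refuses lengths ≤ 500 that the strict length filter
  would silently erase.
- An exact Cholesky-based field generator (`correlated_field`, exponential
  or Gaussian covariance) backs the test-size simulations at a few hundred
  points.

**What passing tests show — and don't.** The synthetic worlds have
correctly specified models (log-linear effects, independent lognormal
noise, no sequencing error, no taxonomic mistakes, star genealogies
without demographic history or selection). Parameter recovery and test
calibration on them validate the *machinery* — estimator exactness,
effective-sample-size corrections, selection behaviour with forced terms —
not the biological adequacy of any of those assumptions for real barcode
compilations, where misidentification, range-edge sampling, uneven effort
and coalescent variance all add structure the generator omits.

## Problem sizes and numerics

Default validation sizes: 336-cell worlds with 200 species (~6000
sequences) for end-to-end runs; 50 replicates for recovery experiments;
1000 replicates for test-size estimates; 100-point fields for the exact
GRF simulations — sizes at which each experiment's Monte-Carlo error is
small relative to the bands being checked, while a full validation run
stays in the minutes range on one core. Degenerate inputs fail loudly and
early: constant fields (undefined correlation), all-zero GD (no log
scale), rank-deficient design matrices (named collinear columns),
species-cells with no usable pair (excluded and logged). Distance ties in
nearest-neighbour graphs break by point order; permutation p-values never
return zero by construction.

## Known limitations

- The modified t-test's size degrades for ultra-smooth fields (above).
- Richness is rasterized directly at grid resolution from hull polygons;
  no occupancy modelling, synonym resolution or database cleaning.
- No coalescent realism in the sequence model; Π calibration holds in
  expectation, but the variance of Π across replicates is smaller than a
  coalescent model would produce (star genealogies share no drift).
- The autocovariate radius equals the grid pitch, so isolated cells drop
  out of the model rather than borrowing strength from farther neighbours.
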