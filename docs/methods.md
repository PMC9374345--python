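# Methods

This note records the models, conventions, and numerical choices behind
`dielfd`, in the order the pipeline runs them.

## Data model and extinction scenarios

A species table carries one row per species: diel niche, IUCN status, a
`dd_threatened` flag, and five traits (body mass in grams, litter size,
habitat breadth as a count of suitable habitats, foraging stratum on the
ordinal scale ground = 1 / scansorial = 2 / arboreal = 3 / aerial = 4, and a
continuous diet score).  All traits must be present — imputation is out of
scope, inputs are expected pre-imputed.  Enum parsing is case-insensitive;
unknown niche or status labels are errors, never silent drops.

Scenarios are nested removals named after the lowest status removed:
CR ⊂ CR+EN ⊂ CR+EN+VU ⊂ CR+EN+VU+NT+threatened-DD.  Data Deficient species
are removed only in the NT scenario and only when a published trait-based
classifier predicts them threatened (`dd_threatened`); DD species without a
prediction are conservatively treated as non-threatened and never removed.
Removal depends only on (status, flag), so scenario application is idempotent
on survivors and removal sets are monotone along the gradient.

Risk summaries report raw per-niche proportions and the log-odds contrast
`logit(p_niche) − logit(p_nocturnal)` with the two-proportion standard error
√(Σ 1/cell).  Mixed models with taxonomic random effects are deliberately not
reimplemented; the raw counts let users fit those externally, and the raw
contrast is expected to differ somewhat from estimates that absorb genus
effects.

## Diet ordination

The continuous diet trait is axis 1 of a classical principal-coordinates
decomposition (double-centered −½D², symmetric eigendecomposition) of Gower
distances over 10 semi-quantitative diet categories.  Three conventions:

* **No eigenvalue correction** (Cailliez/Lingoes) is applied to the
  non-Euclidean Gower matrix; negative eigenvalues are simply excluded, and
  percent variation uses the positive-eigenvalue sum as denominator, keeping
  percentages ≤ 100 and non-increasing.
* **Sign**: axis 1 is flipped, when needed, so species relying on plant
  material and seeds (categories 7–10) score negative — a reproducible
  invertivore → herbivore gradient.
* **Range normalization** uses the observed per-category range of the input
  table, not a fixed scale.

An L1-type Gower matrix on k informative categories is not a rank-k Euclidean
configuration, so the number of positive eigenvalues can exceed k; what holds
(and is tested) is that variation concentrates on ~k leading axes.  For
tables above 500 species the leading eigenvectors come from a Lanczos solver
and the eigenvalue spectrum from a values-only solver; results agree with the
dense path to numerical precision.

## Trait transforms

Body mass and litter size are log₁₀-transformed, habitat breadth
square-root-transformed, foraging stratum kept as an interval-scaled ordinal,
diet score passed through.  Columns are then z-standardized with the sample
SD (n − 1).  Means and SDs are stored so the transform is invertible (tested
to 1e−9).

## Trait spectra

For each diel niche a 2-D basis comes from covariance PCA of the standardized
traits (equal to correlation PCA of the raw transforms).  The basis is fit
once per niche on *all* its species — threatened included — and held fixed
across scenarios, so all scenario spectra live in one ordination.  Component
signs are fixed by requiring a non-negative body-mass loading.

**KDE.** Occurrence probability is a bivariate Gaussian KDE with a full
(unconstrained) bandwidth matrix, evaluated on a regular grid of 151 × 151
cells (default) spanning the full-species score range expanded by 10% per
side, which guarantees coverage of every survivor subset.  The estimator is
the exact kernel sum (no binning), so the grid equals a brute-force double
loop to 1e−10 and integrates to 1 within 2% on all fixtures.

**Bandwidth.** The default selector is a 2-stage unconstrained plug-in of
the Wand–Jones family: data are sphered; sixth-order density functionals are
taken at their normal-scale values; a single scalar pilot minimizing the
summed asymptotic MSE of the five fourth-order functional estimators (the
SAMSE pilot) is chosen numerically; the fourth-order functionals ψ_r are
estimated by the O(n²) kernel double sum; and the asymptotic MISE surrogate
n⁻¹(4π)⁻¹|H|^(−1/2) + ¼·vech(H)ᵀΨ̂₄vech(H) is minimized over SPD matrices
via a Cholesky parametrization started at the normal-reference matrix.
Exact agreement with any particular legacy implementation of this selector
is version-sensitive; the selector is instead validated against theory — for
Gaussian data the optimum is H = n^(−1/3)Σ at d = 2, and the plug-in's
determinant matches it within 0.03% at n = 5000.  A closed-form
`normal_scale` selector (H = n^(−1/3)Σ̂) is available where speed matters
(inside large resampling loops).

**HDR levels.** The contour level for mass q is the (1 − q) empirical
quantile of the density evaluated at the sample points, so the q-region
encloses a fraction q of species ("hotspots" = the 0.5 region).  This
sample-point convention, rather than integrating grid mass, is what makes
"the region contains 50% of species" exact by construction.

**Change statistics.** Both the full-set and survivor KDEs (each with its own
bandwidth, on the shared grid) are divided by their own maximum; within the
cells of the *full* spectrum's 0.99 region the statistics are (i) the mean
absolute difference of the normalized surfaces and (ii) the fraction of
full-0.99 cells below the survivors' 0.99 level (volume loss).  Whether the
per-cell change should instead be a ratio to the full-spectrum proportion is
ambiguous; the difference of max-normalized proportions is the default and a
`relative="ratio"` flag exposes the alternative.  Volume loss is empirically
monotone along the nested scenarios on all fixtures (with the grid and
reference region fixed); a tight cluster of near-duplicates buffers it, so a
single redundant removal moves it by < 0.01.

**Spectrum null.** 100 repetitions (default) remove the observed number of
species uniformly without replacement within the niche and recompute both
statistics against the same full-spectrum reference; the 2.5th/97.5th
percentiles of the null draws give the 95% interval.  A master seed spawns
per-repetition substreams, so runs are bit-reproducible and adding
repetitions never perturbs earlier ones.

## Functional dendrogram and FD

Gower distances over the five transformed traits (equal weights, observed
ranges; zero-range traits dropped with a warning) feed average-linkage
(UPGMA) clustering.  Conventions:

* Merge heights follow hclust: a pair joining at average dissimilarity h sits
  at height h; leaves sit at height 0.  Cophenetic distance = first-join
  height (not the leaf-to-leaf path length, which is twice that).
* FD = total branch length = Σ over merges of (2h − h_left − h_right); a
  single leaf has FD 0, so a pixel reduced to one survivor loses 100% of its
  FD by convention.
* Clustering is delegated to scipy's nearest-neighbor-chain implementation;
  tie-breaking therefore follows scipy's deterministic order rather than a
  lexicographic rule.  Ties have measure zero on continuous Gower distances;
  the suite cross-checks merge heights against a naive lexicographic UPGMA.
* One global dendrogram is built over all species; every subset FD comes from
  pruning, implemented structurally (drop leaves, collapse single-child
  nodes) so kept-leaf cophenetic distances are preserved bit-exactly.  Note
  that re-running UPGMA on a pixel's raw Gower submatrix would generally give
  a different tree; the pruning identity is the invariant, refit equality is
  only a diagnostic.

Congruence between Gower and cophenetic distances is summarized over the
strict upper triangle by the mean absolute deviation, mean squared deviation
(both are reported side by side since either may be the diagnostic of
interest) and Pearson correlation.

## Biogeography

Geographic inputs are an abstract equal-area grid: a boolean pixels × species
matrix, optionally with row/col coordinates.  Projection and polygon
rasterization are out of scope; range-polygon metadata can be pre-filtered
with `filter_range_records` (keep presence "extant"; origin "native",
"reintroduced", "origin uncertain"; seasonality "resident", "breeding
season", "nonbreeding season", "seasonal occurrence uncertain"; unknown codes
are dropped with a warning).

Per pixel and niche: FD prunes the global dendrogram to the niche species
present; proportional loss is 1 − FD(survivors)/FD(all); pixels with ≤ 5
niche species (configurable) are flagged excluded — in practice this removes
nearly all crepuscular pixels, which are produced but flagged sparse.  The
pixel null redraws the observed number of removals uniformly from the
pixel's niche pool, independently across pixels (no spatial coherence of the
randomized labels), and reports observed − mean null: positive where
functionally dispersed species are threatened, negative where they are
redundant.  The UIQ ("upper interquartile") summary is read as the 75th
percentile with linear interpolation.

## Synthetic data

The generator emulates a global terrestrial-mammal dataset; its defaults are
the study conditions of every test:

| parameter | default | rationale |
|---|---|---|
| niche proportions | 0.695 / 0.022 / 0.105 / 0.178 | observed diel shares |
| body mass | log₁₀-normal, niche means 1.6/2.6/2.8/2.4, SD 0.8–1.2 | right-skewed; nocturnal small (rodents, bats), cathemeral includes megafauna |
| litter size | log-normal, slope −0.45 per log₁₀ g of mass | fast–slow life-history axis |
| habitat breadth | 1 + Poisson(3) | count of suitable habitats |
| foraging stratum | niche-specific categorical; aerial only night/twilight | bats |
| diet | Dirichlet around 4 guild archetypes, rounded to 0–100 in steps of 10 | semi-quantitative category scores |
| threat | logistic on standardized traits: logit p = logit(0.33) + β·z | trait-clustered threat is tunable |
| status split | CR/EN/VU/NT/DD-threatened = .15/.25/.30/.22/.08 | plus 3% unflagged DD among non-threatened |
| ranges | nearest-s pixels around a jittered center, log-normal s | contiguous, ≥ 1 pixel each |
| richness gradient | center weight ∝ exp(g·row/rows), g = 1 | latitudinal richness |

The `global_mammals` preset pins niche counts to 3498/113/526/896 and per-niche
NT-threat rates to 0.316/0.348/0.349/0.413, selecting exactly the rounded
count of threatened species per niche by Gumbel-top-k weighted sampling, so
the marginal rates hold exactly while β's still cluster threat in trait
space.  Separate substreams per component mean adding range generation never
perturbs the trait draws.

What the generator does *not* emulate: phylogenetic trait autocorrelation,
real range-shape complexity, spatial autocorrelation of threat, and the real
diet-category covariance — so passing tests demonstrate correctness of the
machinery and calibration of the nulls under known conditions, not agreement
with real-world trait data.  In particular the diet-ordination percentages
and Gower-vs-cophenetic congruence computed on synthetic tables land in the
right range but should not be read as reproductions of values derived from
real trait databases.

## Null-model validation conditions

The resampling properties are checked at fixed study conditions chosen once:
one niche of 300 species, 30% baseline threat, 51 × 51 grid, normal-scale
bandwidth, 100 null repetitions.  With trait-independent threat (β = 0) the
observed removal is exchangeable with the null draws, so its density-change
statistic falls inside the 95% interval in ≈ 95% of 100 generator
replicates; with β_mass = 1.5 the observed change exceeds the null's 97.5th
percentile in ≥ 90 of 100 replicates.  The acceptance script scales the
spectrum stage to 1500 species and the map stage to 900 species on a 12 × 12
grid, sizes at which every stage (including the plug-in bandwidth in the
100-repetition spectrum null) runs in minutes on one CPU.

## Known limitations

* The plug-in bandwidth is validated against theory, not bit-compatible with
  any particular legacy selector; spectra statistics that sit close to a
  contour threshold can differ at the margin between selectors.
* Volume-loss monotonicity along nested scenarios is an empirical regularity
  of the estimator on realistic data, not a theorem; pathological survivor
  configurations could in principle violate it.
* The per-pixel null treats pixels independently; it answers "are this
  pixel's threatened species dispersed?", not a spatially coherent
  field-level question.
* Crepuscular analyses are almost always excluded by the ≤ 5-species rule;
  they are emitted with flags rather than silently dropped.
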