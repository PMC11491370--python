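# Methods

This note records the statistical conventions, generator assumptions and
design choices behind `strepniche`, in the order the pipeline applies
them.

## The design model

The hierarchy is richness whole plot → fungicide subplot → plant →
{composite soil sample, isolate}. Every sample and isolate resolves to
exactly one (richness, fungicide, plant) triple; a plant may not appear in
two treatment cells. Cells with a single plant validate with an
"unreplicated" warning rather than an error, because degenerate designs
are still useful for smoke tests. One caveat is inherited from the field
layout the package mirrors: each richness level exists as a single whole
plot, so plants (and isolates) are replicates *within* one plot and the
richness term of every ANOVA carries plot-level pseudo-replication. The
package documents this rather than "correcting" it; interpretation is the
analyst's responsibility.

## Resource use

- **Blank correction** subtracts the water-control absorbance and clamps
  negatives to zero. Negative corrected growth is unphysical, and the
  overlap formula's min/ratio terms require od ≥ 0.
- **Use calls** are strict: od > threshold, default 0.01 AU590. The
  threshold is configurable for sensitivity analysis.
- **Growth efficiency** over an empty used set is NaN ("undefined"), not
  0; a zero would drag group means down for narrow-niche isolates.
- **Overlap summation domain.** The ω̄ sum runs over the sources used by
  the focal isolate a only, with n = |U(a)|. Summing over all 95 wells
  would divide by od_a(i) = 0 on unused wells; restricting to U(a) avoids
  0/0, preserves the intended asymmetry, and makes ω̄(a→a) = 1. The
  alternative all-95 convention with a 0/0 → 0 rule would scale every
  value by width/95; it is not implemented.
- **Group summaries** average ω̄ over all ordered pairs of isolates from
  the same plant, excluding self-pairs; singleton plants yield NaN with a
  log entry.
- **Substrate profiles** normalize each isolate's od vector to shares
  summing to 1, then average shares within a group (SE = sd/√n). A pooled
  alternative (summing od across the group before normalizing) is exposed
  via `pooled=True`; per-isolate normalization is the default because it
  weights isolates equally regardless of overall growth.

## Plate counts and zones

CFU/g = (count / (plated volume × dilution)) × (suspension volume / soil
mass), with the suspension defaulting to 5 g soil in 25 mL water. Plates
are converted to CFU/g individually before averaging, so mixed dilutions
are handled correctly. Inhibitor proportions above 1 are reported with a
warning, not clipped: total and inhibitor counts come from separate plate
sets and sampling noise can invert them. Zone sizes are radii (colony/disk
edge to clearing edge), the mean of two right-angle measurements;
diameters are not used anywhere. Per-sample inhibitor summaries are
emitted both per indicator overlay and pooled ("all"), since either may be
the quantity of interest.

## Phylogenetic metrics

- **Faith's PD** includes the path from the tip set's common ancestor to
  the root by default (the convention of the classical R implementation);
  `include_root=False` restricts to the minimal spanning subtree. Input
  trees must be rooted and fully branch-length annotated; an unrooted file
  is rejected rather than midpoint-rooted silently, precisely because the
  root-path convention depends on the root.
- **Unweighted UniFrac** is branch length observed in exactly one of the
  two tip sets over branch length observed in either, on presence/absence
  of tips.
- **PERMANOVA** uses the Gower-centered trace formulation: sequential
  model terms (main effects and a nested fungicide-within-richness term)
  are projected with QR bases, each term tested against the residual mean
  square of the full model. Permutations shuffle observation labels
  freely by default (the permutation scheme for the nested term is not
  canonical; a `strata` option restricts shuffling to within whole plots
  when a restricted scheme is wanted). p-values use the add-one
  convention (1 + #{F* ≥ F})/(1 + B), so p = 1/(B+1) is the attainable
  floor. Negative between-group sums of squares (possible for
  non-Euclidean distance matrices) are reported as-is, matching reference
  implementations.

## Univariate statistics

- **Nested ANOVA** uses sequential (Type I) sums of squares with richness
  entered first, both terms tested against the residual MS (plants or
  isolates as replicates — see the pseudo-replication caveat above). The
  implementation projects responses onto cumulative design bases, which
  vectorizes across the 95-substrate screen; it is checked against an
  independent projection oracle and against statsmodels' sequential ANOVA.
  When a term's SS is exactly zero (no variation) it reports F = 0,
  p = 1 rather than 0/0.
- **Tukey HSD** uses the studentized-range distribution (Tukey–Kramer for
  unequal n) via scipy, with the compact letter display assigned by the
  insert-and-absorb algorithm; ties in letter ordering are broken by
  first appearance of the group in the input.
- **Per-substrate screen.** For each carbon source: a two-sample
  fungicide comparison within each richness level, a richness comparison
  pooling fungicide, and the nested ANOVA (both terms). The two-sample
  test defaults to Welch's unequal-variance t (configurable: student,
  mann-whitney). Each family of 95 p-values is FDR-adjusted separately
  (BH by default, BY available); substrates with undefined p (zero
  variance everywhere) are excluded from their family with a log entry.
- **Correlations** are squared Pearson coefficients with the t-transform
  p-value (n − 2 df), computed per richness level across that level's 12
  samples (both fungicide subplots pooled), pairing each sample's
  nutrient value with its density metric.

## The synthetic generator

The generator draws a complete experiment from per-cell parameters, with
all randomness derived from one seed through named substreams. Defaults
describe a sandy, nutrient-poor grassland soil (C ≈ 0.6–1 %, N ≈
0.05–0.08 %, P ≈ 25 ppm, K ≈ 50–75 ppm, OM ≈ 1.3–2 %, pH ≈ 5.7–6.3;
*Streptomyces* densities around 10^6.5–10^7 CFU/g) and inject qualitative
treatment contrasts: richer polyculture soils, more inhibitory and
broader-niche monoculture communities, and opposite-sign fungicide
effects on niche width in the two richness levels. Magnitudes are chosen
to be plausible for this kind of survey; they are not fitted to any field
data set.

Specifics worth knowing:

- **Truncation, not rejection.** Bounded quantities (percent, ppm, pH,
  zone radii) are drawn normal and clipped at their physical bounds.
- **Use-call consistency by construction.** "Used" wells get corrected
  od = threshold + margin + |Normal(μ_od, σ_od)|; "unused" wells are
  truncated at threshold − margin. The margin (10⁻⁵) plus rounding of
  written absorbances to six decimals guarantees that recomputed use
  calls equal the stored truth exactly, including after a CSV round trip.
- **Counts** are Poisson around cell density × plating factor with
  Binomial(total, inhibitor fraction) inhibitory counts, at a default
  dilution (10⁻³) placing expected counts near 100–200 colonies/plate.
- **The tree** is a sequential random-attachment process in shuffled
  isolate order: each new tip joins as sister to a uniformly chosen leaf,
  or with probability `tree_clustering` to a leaf of its own richness
  group; edge lengths are exponential. This produces exchangeable tips at
  clustering 0 (the null for PERMANOVA calibration) and group-level
  clades as clustering → 1. It is deliberately not a birth–death model:
  only the presence/absence group signal matters to unweighted UniFrac.
- **`null_config`** makes all four cells identical with clustering 0 and
  is the basis of every calibration test; `apply_richness_effect` offsets
  a nutrient's cell means by ±k within-cell SDs (first richness level up,
  second down) for power checks — "a 1-SD cell effect" therefore means
  each cell sits one SD from the grand mean, i.e. a 2-SD separation
  between richness levels.

What passing the synthetic tests does *not* show: real Biolog plates have
correlated substrate responses and plate-position effects, real colony
counts are overdispersed relative to Poisson, real phylogenies carry far
deeper structure than the attachment process, and real treatment effects
are not additive shifts. The generator validates the machinery and its
statistical calibration, not any field conclusion.

## Problem sizes and numerics

Calibration tests use the study-sized layout (24 samples, 80 isolates):
400 null replicates for nested-ANOVA type-I error, 200 replicates for
power and for PERMANOVA p-uniformity (199 permutations per run), and 5
null replicates plus 3 injection replicates for the FDR screen. Oracle
agreements are asserted at 10⁻⁹ (sum-of-squares, UniFrac vs. reference
library) or 10⁻¹² (overlap vs. naive loop); SS/df conservation at 10⁻⁹.
Tiny negative sums of squares from floating-point cancellation are
clamped to zero in the ANOVA; the PERMANOVA does not clamp (see above).

## Known limitations

- Exact reproduction of any field study's numbers requires the deposited
  field tables; the package consumes such tables via the documented CSV
  schemas but ships only synthetic data.
- No 16S processing, alignment or tree inference; the tree is an input.
- No weighted UniFrac, NRI/NTI, or mixed-effects models; the single
  permutation-based multivariate test is PERMANOVA.
- The per-substrate screen's discovery count depends on the chosen
  two-sample test; Welch is the default and the choice is exposed.
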