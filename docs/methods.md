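# Methods

This note documents the models, defaults and numerical choices behind
`mycogeo`, in the spirit of a statistical-software methods appendix: what
each stage assumes, which knobs matter, and what passing tests do and do
not demonstrate.

## Sampling design and data model

The pipeline targets a paired-habitat grid design: `n_transects`
rectangular transects, each with `grid_rows × grid_cols` locations
(default 12 × 3 = 36 inside a 10 m × 40 m rectangle; spacing 5 m across
and 40/11 ≈ 3.64 m along). At every location two communities are
collected — topsoil and phylloplane — so the two habitats share an
identical spatial frame; with the defaults the study comprises
36 × 2 × 6 = 432 samples. The exact geometry of a 36-location grid is
not unique (4 × 9 and other factorizations exist); it is configurable
because it changes the lag structure available to variograms.
Coordinates are within-transect local meters; distances are never
computed across transects — the whole-study test needs only the pairing
structure, not between-transect geography.

`SpatialOtuTable` couples a samples × OTUs abundance matrix (integer
counts or normalized reals, flagged) to per-sample metadata
(transect, habitat, location index, x, y). Validation enforces
non-negative abundances, habitat labels in {soil, phylloplane}, at most
one sample per (transect, location, habitat), and identical coordinates
within a location pair. Presence means abundance strictly greater than
zero. Files are tab-separated UTF-8 with a header row; integer tables
round-trip bit-exactly and coordinates survive to at least nine
significant digits.

Singleton OTUs (present in exactly one sample study-wide) are removed
before occupancy, classification and variography, but retained for all
community-dissimilarity work (the paired-habitat test), where rare taxa
legitimately contribute to dissimilarity.

## Synthetic generator

The generator exists so that every inference stage can be exercised
against known truth. Each OTU's latent log-abundance over a transect is
a zero-mean Gaussian random field with exponential covariance
C(h) = sill·exp(−h/a). The field is drawn via Cholesky factorization
with a relative diagonal jitter of 1e−10·sill for numerical stability on
near-co-located points. Throughout the package the *effective range* —
the lag 3a at which the corresponding semivariogram reaches 95% of its
sill (1 − e⁻³ ≈ 0.9502) — is the reported "range size", and
`SyntheticParams.true_range` is specified on that scale.

Habitat coupling: for generalists the phylloplane field is
Z_p = ρ·Z_s + √(1−ρ²)·Z_ind with Z_ind an independent copy, giving
cross-habitat correlation exactly ρ (ρ = 1 duplicates the soil field,
ρ = 0 decouples the habitats). Specialists have a field in their home
habitat and structural zeros elsewhere — which is why a true specialist
can be mis-labelled at worst as unclassified, never as a generalist.

Counts are Poisson around λ = exp(base + b_j + Z − offset) by default
(negative-binomial with dispersion k available for overdispersion);
b_j is an optional per-OTU offset (`abundance_sd`, default 0) that adds
the between-taxon abundance heterogeneity real OTU tables show, drawn
once per OTU and shared across transects as a species-level trait.
Defaults: sill 1, effective range 6 m, ρ 0.8, base 2.0, offset 1.0,
20 OTUs per class. These are stated modelling choices, not inferences
from any dataset: field metabarcoding tables are far sparser and more
heterogeneous than the default synthetic table, contain compositional
artifacts, contamination and taxon-specific amplification biases, none
of which the generator emulates. Passing tests therefore demonstrate
the correctness and calibration of the *machinery* under a known
spatial model, not the field behaviour of real mycobiomes.

Normalization for downstream variography of synthetic counts is
log(1 + count), flagged as normalized; users supplying their own
variance-stabilized matrix bypass this.

## Statistical kernel

All tests are implemented directly so their conventions are contractual:

- **Permutation p-values** use the add-one convention
  p = (1 + #{T_perm ≥ T_obs}) / (n_perm + 1). When n! ≤ n_perm + 1 the
  tests instead enumerate *all* n! label orderings and report
  p = #{T_perm ≥ T_obs}/n! (the identity ordering counts itself, so the
  convention is consistent); with the default 999 permutations this
  makes every p-value at n ≤ 6 exact. Tie comparisons use an absolute
  tolerance of 1e−12.
- **permanova** uses the squared-distance decomposition
  SS_total = (1/n)Σ_{i<j} d²; SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²;
  pseudo-F = (SS_between/(g−1))/(SS_within/(n−g)); R² attached.
  All-zero distance matrices are flagged degenerate rather than tested.
- **Mantel** correlates upper triangles, permuting rows/columns of one
  matrix jointly; one-sided ("greater") by default because the
  screening question is whether similarity decays with distance;
  two-sided available. Zero-variance triangles are degenerate.
- **Wilcoxon rank-sum** is exact by enumeration of rank assignments when
  n_a + n_b ≤ 12 without ties, otherwise the normal approximation with
  midranks, tie correction and continuity correction.
- **t-test** defaults to Welch (the observed and randomized
  dissimilarity pools have no reason to share a variance); pooled
  variant available. Equal constant samples give t = 0, p = 1, flagged
  degenerate.
- **Benjamini–Hochberg** is the step-up adjustment with monotonicity
  enforced from the largest rank down; it never lowers a p-value and is
  idempotent.

## Paired-habitat test

Observed values are BC(soil_i, phyllo_i) over all complete location
pairs; the null draws seeded uniform derangements π (rejection-sampled
permutations with no fixed point) and emits BC(soil_i, phyllo_π(i)).
Derangements, not free permutations, guarantee no same-location pair
contaminates the null. The default pools 99 derangements (stabilizing
the null mean); a single-draw mode mirrors reporting styles that use
one randomization. At the whole-study scale the derangement runs over
all locations of all transects; at the transect scale it is confined
within each transect. The reported t-test is two-sided; the
"autocorrelated" call additionally requires observed < randomized.

A calibration caveat, measured and documented rather than hidden: the
observed and randomized pools share the same underlying samples, so the
comparison is effectively paired, and the unpaired two-sample t-test
the procedure specifies overstates the variance of the mean difference.
Under a decoupled null (ρ = 0) the test's empirical size is therefore
conservative (≈ 0.005–0.01 at nominal 0.05, in both randomization
modes); a control in which the null pool is drawn from an independent
replicate study restores size to 0.05 exactly, confirming the mechanism.
The test never over-rejects, and its power against genuine coupling
(ρ = 0.9, field-design geometry) is essentially 1.

## Classification and occupancy

Within a transect: generalist ⇔ occupancy ≥ 2 in *both* habitats;
specialist ⇔ occupancy ≥ 2 in exactly one habitat and 0 in the other;
anything else (including 2 soil + 1 phylloplane) is unclassified. The
rule set is evaluated per transect by default, matching the
within-transect definition; a study-wide mode pools occupancies first,
which changes what "exclusively" means — both are exposed because
aggregate summaries (e.g. study-wide specialist/generalist tallies) need
the pooled variant. Occupancy comparisons run pairwise Wilcoxon tests
over the four class–habitat pools (generalists contribute one occupancy
per habitat), six pairs, BH-corrected.

Occupancy–abundance points use local abundance = (summed normalized
abundance over occupied samples)/occupancy, one point per
(OTU, transect, habitat) with occupancy ≥ 1. The smoother is a
hand-rolled loess: tricube weights over the ⌈span·n⌉ nearest points,
local polynomial of degree 2 (span 0.75) by weighted least squares, and
a pointwise interval from the local weighted residual variance
propagated through the smoother weights. Degree 1 reproduces
`statsmodels`' lowess closely; degree 2 and the interval are the reason
it is implemented here.

## Variography

The Mantel screen works on *relative* abundance (per-sample
proportions) with the single-OTU Bray–Curtis distance
|xᵢ−xⱼ|/(xᵢ+xⱼ), defined as 0 when both values are 0 — the limit of the
community formula restricted to one taxon; candidates need ≥ 5 samples
and a non-constant vector, and are flagged at one-sided p ≤ α = 0.05.
Model fitting then uses the normalized (log1p or user-supplied) matrix —
screening on proportions, fitting on stabilized abundances.

Empirical semivariograms use the method-of-moments estimator over 12
equal-width bins on (0, max_lag] with max_lag defaulting to half the
maximum pairwise distance; bins with fewer than 10 pairs are dropped
and lag centers are mean pair distances. The exponential model with
nugget 0 is fitted by bounded nonlinear least squares with weights
√(N_k/h_k²) (emphasizing short, well-populated lags), initial sill from
the sample variance when available (otherwise the largest empirical
semivariance), initial a = max_lag/3, and a ∈ (0, 10·max_lag] — the
upper bound deliberately exceeds the transect extent because weakly
decaying variograms legitimately fit ranges far beyond the sampled
domain. Noiseless inputs are recovered to SSE < 1e−10; on a dense
20 × 20 m grid the median recovered effective range is within a few
percent of truth for true ranges 2–8 m, degrading on the sparse
36-point field grid (medians remain usable; single fits are noisy).

Culling: fits with range below 1 m are culled as unresolvable by the
sampling scheme. Among survivors, ranges beyond the transect diagonal
(≈ 41.23 m for 10 × 40 m) are flagged as outliers; an optional Tukey
fence (Q3 + 1.5·IQR on log range) catches extreme survivors. These
codified rules replace manual model inspection — they are stated
replacements, not reconstructions of anyone's judgment — and the audit
(total, culled, outliers, remaining) is always reported. Group
comparisons of range size mirror the occupancy comparisons (pairwise
Wilcoxon over class–habitat groups, BH-corrected, medians and IQRs).

## Kriging

Ordinary kriging solves, per prediction point, the (n+1)-system with
the unbiasedness constraint Σw = 1 via a Lagrange multiplier, using a
single LU factorization per surface; kriging variance is
Σ wᵢγ(hᵢ₀) + μ. With nugget 0 the predictor interpolates the data
exactly with zero variance at data points. A global neighborhood (all
data in every system) is used: per-transect n is at most 36 and a
search neighborhood would only introduce artifacts. Duplicate
coordinates are averaged (logged) to keep the system nonsingular. The
grid covers the transect bounding box at 0.5 m resolution by default.
Coupled maps are produced for generalists holding surviving, converged
fits in both habitats of a transect; the Pearson correlation of the two
prediction rasters summarizes cross-habitat synchrony. Rendering uses a
perceptually uniform dark-to-light colormap (dark = low abundance).

## Pipeline and reproducibility

`run_pipeline` chains ingest/simulate → paired test → singleton filter
→ classification → occupancy comparison → Mantel screen → range
estimation → culling → range comparison → coupled maps → OA curves,
writing TSVs plus a JSON manifest (config snapshot, per-stage timings,
output inventory, culling audit). One master seed deterministically
spawns per-stage seeds through `SeedSequence`, so stages are
reproducible in isolation and identical configs produce byte-identical
TSV outputs. All thresholds (α = 0.05, 999 permutations, 99
randomizations, 1 m cull, BH) live in `PipelineConfig` with YAML
round-trip.

## Problem sizes used in validation

The test-suite Monte-Carlo studies use: 2,000 draws for the
single-point field variance check; 30 seeds for variogram-shape
averaging; 50 seeds per true range for recovery; 200/100 replicates for
the paired-test size/power study at full 432-sample geometry; 400
replicates for t-test calibration; 100–200 simulated OTUs for screening
false-positive rates. These sizes hold Monte-Carlo standard errors
comfortably inside the asserted tolerances.

## Known limitations

- The generator's equal-abundance, single-range, two-class world is a
  deliberately minimal model; see the generator section for what it
  does not emulate.
- The unpaired t-test of the paired-habitat procedure is conservative
  (see above); a paired analysis of the per-location differences would
  be better calibrated but is a different procedure than the one this
  package reproduces.
- Variogram fits on 36-point transects are individually noisy; the
  package's comparisons operate on medians across many OTUs for that
  reason.
- Anisotropy, non-exponential variogram families, cross-variograms and
  universal kriging are out of scope; the exponential family with zero
  nugget is fixed to keep ranges comparable across taxa.
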