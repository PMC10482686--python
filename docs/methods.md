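# Methods

This note documents the models and procedures implemented in `abyssal`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Survey design: rarefied replicate samples

Seabed-imagery occurrence data are spatially clumped (thousands of
specimens per dive) and unevenly identified. Community metrics are
therefore computed on equally sized replicate samples drawn within
geographical and bathymetric constraints:

* **Gridding.** Records are projected with a local equirectangular
  projection about the dataset centroid (x = R cos φ₀ Δλ, y = R Δφ,
  R = 6,371 km) and partitioned by floor division into 10 × 10 km cells,
  with the grid origin at projected (0, 0); cells never merge records
  from different study sites. At abyssal-Pacific latitudes the projection
  distortion over 10 km is far below the cell size, so a full geodetic
  projection would change no assignment in practice. A cluster of records
  that happens to sit on a cell edge is split between two locations —
  an inherent property of grid methods, visible in tests as an occasional
  location count one above the number of programmed clusters.
* **Depth bins.** Within a location, records are constrained to half-open
  bins [200k, 200(k+1)) m aligned to multiples of the 200 m bin width.
  Alignment to multiples is a convention choice; only the bin width is
  scientifically meaningful.
* **BD samples** (biodiversity): morphotype-level records only. Each
  location × bin pool is shuffled once with the run's seeded generator
  and cut into consecutive chunks of exactly 200 specimens;
  the remainder (n mod 200) is discarded, never pooled across bins or
  locations, because pooling would undo the spatial constraint that
  motivates the design.
* **SS samples** (standing stocks): records of all identification levels,
  but only from still images with a measured seabed area. Whole images
  are accumulated in shuffled order until the specimen count reaches
  450–500; an image whose addition would overshoot 500 is skipped, and a
  trailing accumulation that cannot reach 450 is discarded. Images are
  never split, so each sample's specimen count and seabed area refer to
  the same collection of images — zero-specimen images contribute area,
  which matters: dropping them would bias densities upward by
  1/(1 − e^(−λ)) at per-image specimen mean λ. Frames are assigned to
  grid cells by their own coordinates and to depth bins by their own
  depth.

One integer seed in `SamplingPlan` drives a single generator stream for
the whole sampling pass, making sample sets bit-reproducible.

## Diversity and standing stocks

Hill numbers of order 0 and 1 per BD sample: richness S (count of
morphotypes present) and exp H′ with H′ = −Σ pᵢ ln pᵢ in nats (the base
cancels after exponentiation; intermediate entropies are natural-log).
Because all BD samples hold exactly 200 specimens, values are comparable
without further rarefaction. Density is n/area (ind m⁻²) per SS sample,
with a ×10⁴ helper for ind ha⁻¹.

Province summaries use the arithmetic mean and a two-sided 95 % t
interval, mean ± t₀.₉₇₅,ₙ₋₁ s/√n; provinces with fewer than two samples
get an undefined interval. A t interval was chosen over a bootstrap for
determinism and because province sample counts are modest (tens); the
summary function accepts any confidence level.

Accumulation curves are sample-based rarefaction estimated by Monte
Carlo: 100 seeded permutations of sample order, cumulative pooled
richness per step, and per-step mean with a t-based 95 % envelope across
permutations. The Monte-Carlo estimator was chosen over the closed-form
expectation because it also yields the permutation spread; the final
point equals pooled richness for every permutation by construction,
which the tests exploit as a set-union oracle.

## Beta-diversity: Bray–Curtis and NMDS

Dissimilarity is Bray–Curtis on square-root transformed abundances; the
transform damps the influence of the few numerically dominant
morphotypes. All-zero abundance vectors are rejected (the dissimilarity
is undefined for them).

The ordination is Kruskal-style non-metric MDS, written from scratch:

* **Stress.** stress-1 = √(Σ(d̂ᵢⱼ − d*ᵢⱼ)² / Σ d̂ᵢⱼ²), where d̂ are
  configuration distances and d* the least-squares non-decreasing
  (isotonic) regression of d̂ on the ranked input dissimilarities,
  computed by pool-adjacent-violators.
* **Ties** follow Kruskal's primary approach: within a block of tied
  dissimilarities, pairs are ordered by their current configuration
  distance before the monotone fit, so ties impose no within-block
  constraint. A consequence worth knowing: a configuration can reach
  stress 0 on heavily tied inputs (e.g. four points with only two
  distinct distances) while looking quite unlike the generating shape —
  only the between-block order is constrained.
* **Optimisation.** Steepest descent on stress-1 (analytic gradient with
  disparities held fixed) with step halving; a step is only accepted if
  the fully recomputed stress (including a fresh monotone fit) decreases,
  so the stress sequence is non-increasing by construction. Iteration
  stops when the improvement falls below 1e−6 or after `max_iter` steps.
  The best of `n_restarts` random starts (seeds seed+0 … seed+r−1) is
  returned, centred and rotated to principal axes with a deterministic
  sign convention. Defaults (20 restarts, 300 iterations) are
  conservative for ≤ a few hundred samples; the pipeline uses 8 restarts
  × 200 iterations, which on the default synthetic region changes stress
  only in the third decimal.
* **Degenerate input** (all dissimilarities equal) yields a warning and
  an arbitrary centred configuration with its stress recorded.

## Gradient regressions

Each metric y is regressed on one predictor x (depth or POC flux — the
other environmental variables are excluded because depth–longitude and
flux–latitude are strongly collinear across the region, which the
`correlation_screen` quantifies) under three families: linear (y ~ x),
log (y ~ ln x) and exp (ln y ~ x). "exp" transforming the response — an
exponential response model — is the reading consistent with fitting "a
linear regression across data transformation types"; the choice is
explicit in the family definitions. F, p and R² are reported on the
transformed scale.

Families are compared with AICc computed on a common response scale: for
the exp family the Gaussian log-likelihood of ln y is adjusted by the
log-Jacobian Σ ln(1/yᵢ), without which likelihoods of y and ln y are not
comparable. AICc uses k = 3 (intercept, slope, residual variance); it is
undefined for n ≤ 4, in which case the ranking falls back to plain AIC
ordering (the small-sample correction is identical across families of
equal k, so the order is unchanged whenever both are defined).
Constant-response fits report slope 0 and F = 0 by convention rather
than 0/0.

## Zonation

Provinces are half-open depth intervals: shallow [0, 4300), transition
[4300, 4800), deep [4800, ∞) m, configurable. A morphotype's province
set is derived from the rarefied BD samples (not raw occurrences), so
counts refer to the same sampling universe as the diversity metrics;
"rare" means fewer than 5 specimens in total across all BD samples.
Shallow–deep sharing ignores transition membership. Ridgeline depth
distributions are plain normalized histograms (100 m bins, groups with
more than 50 occurrences); any smoothing is display-only. Dominance
tables rank taxa by pooled abundance (BD) or pooled density (SS) with
ties broken by label, and report the top-k cumulative share.

**Boundary sweep.** The replacement-depth diagnostic is a moving
split-window analysis: for each candidate boundary, the samples within
300 m above and below form two groups, and the score is their mean
between-group Bray–Curtis minus the mean within-group value. Smooth
gradient turnover raises the between and within terms together, while an
abrupt replacement raises only the between term, so the score peaks at
the discontinuity. A whole-dataset split (all samples above vs below)
was tried first and rejected: with smooth exponential turnover the most
extreme splits always look most distinct, and the estimate stuck to the
gradient ends on some seeds. Windows need at least 5 samples per side.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with programmed truth for recovery tests:

* **Region.** 14 sites from deep north-west (5,300 m) to shallow
  south-east (3,900 m) with the real study's per-site location counts
  (28 locations); locations within a site are ≥ 30 km apart; 4 locations
  are "video" platforms without image areas and hence excluded from
  densities.
* **Food supply.** Export flux at 100 m ramps linearly with latitude
  (42 → 6 gC m⁻² yr⁻¹ south → north) and attenuates with depth as a
  Martin curve with the canonical open-ocean exponent b = 0.858, giving
  seabed fluxes of ~0.2–1.8 gC m⁻² yr⁻¹.
* **Standing stocks.** Per-image specimen counts are Poisson with mean
  area × 0.75 × flux, so density scales linearly with food supply and
  spans ~0.14–1.4 ind m⁻² across locations — the order-of-magnitude
  shallow-to-deep decline observed in the abyssal north-east Pacific.
  Poisson (rather than negative binomial) keeps test expectations
  analytic; overdispersion is a known omission. Survey effort per
  location is flux-adaptive (targeting ~2,000 specimens), emulating the
  very unequal per-site areas of real compilations; a fixed
  `images_per_location` override exists, and is what the Poisson
  mean-linearity test uses.
* **Community.** 400 morphotypes with Fisher log-series weights raised
  to a concentration exponent of 2, calibrated (analytically, via
  E[S] = Σ(1 − (1 − pᵢ)²⁰⁰) and top-10 weight shares) so that
  200-specimen samples hold roughly 35–65 morphotypes and the ten most
  abundant taxa hold ~60 % of shallow abundance. Depth responses are
  monotone or flat: calcifiers (`ccd_restricted`, 12 % of taxa —
  mollusc/bryozoan analogues) are abundant up to the CCD (default
  4,600 m, the middle of the region's 4,400–4,800 m CCD band) and absent
  below it — a hard cliff, because a taper made the programmed
  discontinuity too weak to dominate sampling noise; soft-coral
  analogues decline and anemone/holothurian analogues increase with
  250 m e-folding (matching order-of-magnitude declines over ~1,000 m);
  the rest are flat. With only monotone/flat profiles no taxon is
  *programmed* to be transition-exclusive, though rare taxa can realise
  transition-only occurrences by chance, as in real data.
* **Evenness gradient.** SAD weights are raised to an exponent falling
  linearly from 1 (3,900 m) to 0.45 (5,300 m), flattening deep
  communities: deep samples are more even and slightly richer per 200
  specimens, and the deep top-10 share drops to ~0.48 — the
  deeper-is-more-even pattern reported for this region.
* **Identification noise.** 30 % of specimens are relabelled to
  higher-taxon level only (usable for densities, excluded from
  morphotype-level analyses).
* **Simplifications.** Frame depths are drawn on a 20 m grid around the
  location depth so morphotype-assignment probability vectors can be
  computed per depth group; frames of one location share one latitude
  ramp value for effort adaptation. No nodule-cover microhabitat,
  seamounts, spatial autocorrelation beyond the site/location layout, or
  satellite flux fields.

**What passing tests show — and don't.** Recovery tests demonstrate that
the pipeline correctly extracts structure that is present: exact
rarefaction arithmetic, unbiased resampling, the programmed CCD cut-off,
province-level turnover exceeding within-province variation, the
replacement depth within ±100 m, and the sign of the density–depth
relation. They do not show that real occurrence data satisfy the
generator's assumptions (Poisson counts, monotone responses, a single
discontinuity), nor do they validate taxonomic standardization — the
hard part of real compilations, and out of scope here.

## Problem sizes and determinism

Default test and acceptance runs use the default synthetic region
(~28 locations, ~55,000 records, ~170 BD and ~90 SS samples), chosen to
mirror the scale of the real compiled dataset while keeping a full
pipeline pass at a few tens of seconds. All randomness flows from
explicit integer seeds (generator, sampling plan, accumulation
permutations, NMDS restarts); fixed seeds reproduce every output file
byte for byte, and run manifests record SHA-256 digests of all
artifacts.
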