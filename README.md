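# abyssal

Specimen-rarefied community analysis of abyssal seabed-imagery occurrence
data: from raw megafauna specimen detections to rarefied community samples,
Hill diversity and standing stocks, Bray–Curtis/NMDS beta-diversity,
environmental gradient regressions, and depth-province zonation statistics —
plus a synthetic occurrence generator that emulates the abyssal northeast
Pacific (Clarion–Clipperton Zone), so the full pipeline is testable and
reproducible without any data download.

## The scientific problem

Abyssal plains (3,000–6,000 m) are Earth's largest habitat, yet regional
biogeographic structure in their benthic megafauna is largely unmapped.
Seabed-imagery surveys yield occurrence tables — one row per detected
specimen >10 mm, with position, depth, source image and a morphotype
identification from a standardized catalogue. Turning those tables into
comparable community metrics requires careful survey design: specimens are
spatially clumped along dives, survey effort is wildly unequal between
sites, and ~30 % of specimens cannot be identified to morphotype.

This package implements the bottom-up workflow used to detect depth-zoned
biogeographic provinces in such data, for community ecologists working with
imagery-derived occurrence tables:

1. **Survey design** — specimens are gridded into 10 × 10 km geographical
   locations (never merged across sites), constrained to 200 m depth bins,
   and resampled without replacement into equally sized replicates:
   *BD samples* of exactly 200 morphotype-level specimens (diversity,
   beta-diversity) and *SS samples* of 450–500 specimens built from whole
   still images so each carries a coherent seabed area (densities).
2. **Diversity** — Hill numbers per BD sample: richness *S* (q = 0) and
   exp *H′* (q = 1), with exp *H′* = exp(−Σ pᵢ ln pᵢ); density *N*/area
   (ind m⁻²) per SS sample; province means with 95 % t-based confidence
   intervals; sample-based morphotype accumulation curves (100 seeded
   permutations of sample order).
3. **Beta-diversity** — Bray–Curtis dissimilarity on square-root
   transformed abundances, BC(x, y) = Σ|x′ᵢ − y′ᵢ| / Σ(x′ᵢ + y′ᵢ), and a
   from-scratch Kruskal non-metric MDS (stress-1, pool-adjacent-violators
   monotone regression, primary tie treatment, multi-restart steepest
   descent).
4. **Gradients** — OLS of each metric on depth or POC flux under three
   response families (linear: y~x, log: y~ln x, exp: ln y~x), compared on
   one scale by Jacobian-adjusted AICc; plus a Pearson collinearity screen
   of the environmental variables.
5. **Zonation** — province classification (shallow < 4,300 m, transition
   4,300–4,800 m, deep > 4,800 m), ridgeline depth distributions of
   dominant higher taxa, morphotype overlap/exclusivity counts (with a
   "rare = fewer than 5 occurrences" flag), top-k dominance shares, and a
   moving split-window boundary sweep that estimates the community
   replacement depth from the dissimilarity structure alone.
6. **Synthetic data** — a generator with programmed ground truth: Martin
   POC-flux attenuation F(z) = F_export · (z/z₀)^−0.858 over a latitudinal
   export ramp, Poisson specimen counts proportional to local flux,
   log-series (long-tailed) morphotype abundances, monotone depth
   responses, and a hard carbonate-compensation-depth (CCD) cut-off for
   calcifying taxa — the basis of the recovery tests.

## Worked example

```python
from abyssal import (SamplingPlan, SyntheticConfig, boundary_sweep, bray_curtis,
                     filter_subset, generate_occurrences, make_samples, overlap_counts)

config = SyntheticConfig(seed=1)
table, truth = generate_occurrences(config)          # 55,202 specimen records
bd = make_samples(filter_subset(table, "BD"), "BD", SamplingPlan(seed=1))

oc = overlap_counts(bd)
sweep = boundary_sweep(bd, bray_curtis(bd))
print(len(bd), oc.per_province["deep"]["exclusive"],
      sweep.loc[sweep.score.idxmax(), "boundary_m"])
```

prints `167 63 4600.0`: the survey design yields 167 BD samples, 63
morphotypes are found exclusively in the deep province, and the boundary
sweep places the community replacement at 4,600 m — exactly the CCD depth
programmed into the generator (`truth.ccd_depth`). The narrative scripts in
`examples/` walk through each capability and print, for the same seed,
province richness of 43.1 / 46.3 / 61.8 morphotypes per 200 specimens
(shallow / transition / deep), densities falling from 1.03 to 0.35 ind m⁻²,
and an NMDS stress of 0.101 with provinces separated along the first axis.

A thin CLI mirrors the library (`abyssal generate`, `abyssal make-samples`,
`abyssal nmds`, `abyssal run --config run.yaml`, ...); run `abyssal --help`.

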