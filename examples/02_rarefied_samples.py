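"""Build specimen-rarefied community samples from an occurrence table.

Specimens are gridded into 10 x 10 km locations, constrained to 200 m
depth bins, and resampled without replacement into equally sized
replicates: BD samples of exactly 200 morphotype-level specimens
(biodiversity analyses) and SS samples of 450-500 specimens from whole
still images (density analyses).
"""

import numpy as np

from abyssal import (
    SamplingPlan,
    SyntheticConfig,
    filter_subset,
    generate_occurrences,
    make_samples,
)

table, _ = generate_occurrences(SyntheticConfig(seed=1))
plan = SamplingPlan(seed=1)

bd = make_samples(filter_subset(table, "BD"), "BD", plan)
ss = make_samples(filter_subset(table, "SS"), "SS", plan)

print(f"BD samples: {len(bd)} (all of exactly "
      f"{set(s.n_specimens for s in bd)} specimens)")
sizes = [s.n_specimens for s in ss]
print(f"SS samples: {len(ss)} ({min(sizes)}-{max(sizes)} specimens each)")

areas = [s.area for s in ss]
dens = [s.n_specimens / s.area for s in ss]
print(f"SS seabed area per sample: {min(areas):.0f}-{max(areas):.0f} m2")
print(f"faunal density: {min(dens):.2f}-{max(dens):.2f} ind m-2")
# Each specimen is used in at most one sample; leftovers below the sample
# size are discarded rather than pooled across locations or depth bins.
used = sum(s.n_specimens for s in bd)
pool = len(filter_subset(table, "BD").records)
print(f"BD specimens used: {used:,} of {pool:,} eligible")
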