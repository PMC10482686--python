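"""Hill diversity, standing stocks, province summaries and gradient fits.

Richness (Hill q=0) and exp-Shannon (Hill q=1) are computed per
200-specimen BD sample; density per SS sample. Means with 95% t-based
confidence intervals summarise the three depth provinces, and each
metric is regressed on depth with AICc selection among linear / log /
exponential response families.
"""

import numpy as np

from abyssal import (
    SamplingPlan,
    SyntheticConfig,
    filter_subset,
    generate_occurrences,
    make_samples,
    province_summary,
    select_model,
)
from abyssal.diversity import density, hill_richness, hill_shannon
from abyssal.zonation import classify_province

table, _ = generate_occurrences(SyntheticConfig(seed=1))
plan = SamplingPlan(seed=1)
bd = make_samples(filter_subset(table, "BD"), "BD", plan)
ss = make_samples(filter_subset(table, "SS"), "SS", plan)

richness = np.array([hill_richness(s) for s in bd])
provs = [classify_province(s.mean_depth) for s in bd]
print("morphotype richness per 200 specimens (mean [95% CI], by province):")
for summ in province_summary(richness, provs, metric="richness_s"):
    print(f"  {summ.province:10s} n={summ.n_samples:3d}  "
          f"{summ.mean:5.1f}  [{summ.ci_low:5.1f}, {summ.ci_high:5.1f}]")

dens = np.array([density(s) for s in ss])
dprov = [classify_province(s.mean_depth) for s in ss]
print("faunal density, ind m-2 (mean [95% CI], by province):")
for summ in province_summary(dens, dprov, metric="density"):
    print(f"  {summ.province:10s} n={summ.n_samples:3d}  "
          f"{summ.mean:5.2f}  [{summ.ci_low:5.2f}, {summ.ci_high:5.2f}]")

depth_bd = np.array([s.mean_depth for s in bd])
best, ranking = select_model(richness, depth_bd, metric="richness_s")
print(f"richness ~ depth: best family '{best.family}', "
      f"F(1,{best.df[1]}) = {best.f_statistic:.1f}, R2 = {best.r_squared:.2f}")

depth_ss = np.array([s.mean_depth for s in ss])
best, ranking = select_model(dens, depth_ss, metric="density")
print(f"density ~ depth:  best family '{best.family}', "
      f"slope = {best.slope:.3g}, R2 = {best.r_squared:.2f}")
print(ranking[["family", "delta_aicc"]].to_string(index=False))
# Densities fall several-fold with depth (food starvation), while richness
# per 200 specimens is maintained or rises: the deep community is more even.
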