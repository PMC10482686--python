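"""Standing stocks, Hill diversity numbers, province summaries and
sample-based accumulation curves.

Hill numbers of order q unify diversity indices: q=0 is morphotype
richness S and q=1 is the exponential of Shannon entropy, exp(H'), the
"effective number" of equally common morphotypes. Both are computed per
specimen-rarefied BD sample (exactly 200 specimens), so values are
directly comparable across locations without further rarefaction.

Standing stocks are densities (individuals m^-2): specimen counts in an
SS sample divided by the summed seabed area of its contributing images.

Accumulation curves follow the sample-based rarefaction convention:
sample order is permuted (default 100 seeded permutations) and pooled
richness is accumulated, reporting per-step mean and a t-based 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CommunitySample

__all__ = [
    "DiversityEstimate",
    "ProvinceSummary",
    "AccumulationCurve",
    "hill_richness",
    "hill_shannon",
    "density",
    "per_hectare",
    "diversity_table",
    "province_summary",
    "accumulation_curve",
]


@dataclass(frozen=True)
class DiversityEstimate:
    sample_id: str
    richness_s: int
    exp_shannon: float


@dataclass(frozen=True)
class ProvinceSummary:
    province: str
    metric: str
    n_samples: int
    mean: float
    ci_low: float   # NaN when n_samples < 2
    ci_high: float


@dataclass(frozen=True)
class AccumulationCurve:
    n_samples: np.ndarray
    mean_richness: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_randomizations: int


def _require_bd(sample: CommunitySample) -> None:
    if sample.mode != "BD":
        raise ValueError(
            f"sample {sample.sample_id} is {sample.mode}-mode; Hill numbers "
            "are defined on morphotype-level (BD) samples only"
        )


def hill_richness(sample: CommunitySample) -> int:
    """Hill number of order 0: count of morphotypes with abundance > 0."""
    _require_bd(sample)
    return sum(1 for v in sample.abundances.values() if v > 0)


def hill_shannon(sample: CommunitySample) -> float:
    """Hill number of order 1: exp(H') with H' the Shannon entropy in nats."""
    _require_bd(sample)
    counts = np.array([v for v in sample.abundances.values() if v > 0], dtype=float)
    if counts.size == 0:
        raise ValueError(f"sample {sample.sample_id} is empty")
    p = counts / counts.sum()
    return float(np.exp(-np.sum(p * np.log(p))))


def density(
    sample: CommunitySample, taxa: Iterable[str] | None = None
) -> float:
    """Individuals per m^2 of surveyed seabed (optionally for a taxon subset)."""
    if sample.mode != "SS":
        raise ValueError("density requires an SS-mode sample with a measured area")
    if not sample.area or sample.area <= 0:
        raise ValueError(f"sample {sample.sample_id} has no positive area")
    if taxa is None:
        n = sample.n_specimens
    else:
        sel = set(taxa)
        n = sum(v for t, v in sample.abundances.items() if t in sel)
    return n / sample.area


def per_hectare(density_m2: float) -> float:
    """Convert individuals m^-2 to individuals ha^-1 (x 10,000)."""
    return density_m2 * 1.0e4


def diversity_table(samples: Sequence[CommunitySample]) -> pd.DataFrame:
    """Per-sample metric table (richness/expH' for BD, density for SS)."""
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "site": s.site,
            "mode": s.mode,
            "mean_depth": s.mean_depth,
            "mean_latitude": s.mean_latitude,
            "mean_longitude": s.mean_longitude,
            "poc_flux": np.nan if s.poc_flux is None else s.poc_flux,
        }
        if s.mode == "BD":
            row["richness_s"] = hill_richness(s)
            row["exp_shannon"] = hill_shannon(s)
        else:
            row["density"] = density(s)
        rows.append(row)
    return pd.DataFrame(rows)


def province_summary(
    values: Sequence[float],
    provinces: Sequence[str],
    metric: str = "metric",
    confidence: float = 0.95,
) -> list[ProvinceSummary]:
    """Arithmetic mean and two-sided t-based CI of a metric per province.

    CI = mean +/- t_{1-alpha/2, n-1} * s / sqrt(n); provinces with fewer
    than two samples get an undefined (NaN) interval.
    """
    values = np.asarray(values, dtype=float)
    provinces = np.asarray(provinces)
    if values.shape != provinces.shape:
        raise ValueError("values and provinces must align")
    out = []
    for prov in pd.unique(provinces):
        v = values[provinces == prov]
        n = v.size
        mean = float(v.mean())
        if n < 2:
            lo = hi = float("nan")
        else:
            half = stats.t.ppf(0.5 + confidence / 2, n - 1) * v.std(ddof=1) / np.sqrt(n)
            lo, hi = mean - half, mean + half
        out.append(ProvinceSummary(str(prov), metric, n, mean, lo, hi))
    return out


def accumulation_curve(
    samples: Sequence[CommunitySample],
    n_randomizations: int = 100,
    seed: int = 0,
    confidence: float = 0.95,
) -> AccumulationCurve:
    """Sample-based morphotype accumulation curve by order permutation.

    For each of ``n_randomizations`` seeded permutations of sample order,
    pooled richness is accumulated step by step; the per-step mean and
    t-based CI across permutations are reported. The final step equals the
    pooled richness of all samples for every permutation.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    taxa = sorted({t for s in samples for t in s.abundances})
    index = {t: j for j, t in enumerate(taxa)}
    P = np.zeros((len(samples), len(taxa)), dtype=bool)
    for i, s in enumerate(samples):
        for t, v in s.abundances.items():
            if v > 0:
                P[i, index[t]] = True
    rng = np.random.default_rng(seed)
    n = len(samples)
    curves = np.empty((n_randomizations, n), dtype=float)
    for r in range(n_randomizations):
        perm = rng.permutation(n)
        curves[r] = np.maximum.accumulate(P[perm], axis=0).sum(axis=1)
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1) if n_randomizations > 1 else np.zeros(n)
    if n_randomizations > 1:
        tq = stats.t.ppf(0.5 + confidence / 2, n_randomizations - 1)
        half = tq * sd / np.sqrt(n_randomizations)
    else:
        half = np.zeros(n)
    return AccumulationCurve(
        n_samples=np.arange(1, n + 1),
        mean_richness=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        n_randomizations=n_randomizations,
    )
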