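"""Depth-structured community description: provinces, ridgelines,
overlap/exclusivity counts, dominance tables and a boundary-sweep
diagnostic.

The working hypothesis is a three-way depth zonation of the abyssal
megabenthos: a shallow-abyssal province (< 4,300 m), a deep province
(> 4,800 m) and a transition band between them, with the carbonate
compensation depth (CCD) as the candidate driver of the faunal
replacement. The functions here quantify that structure from rarefied
community samples: which morphotypes are exclusive to a province, how
concentrated the abundance is in the top-ranked taxa, and where a single
depth boundary would maximise between-group compositional dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CommunitySample, OccurrenceTable

__all__ = [
    "ProvinceScheme",
    "RidgelineDistribution",
    "OverlapCounts",
    "DominanceTable",
    "classify_province",
    "ridgeline",
    "overlap_counts",
    "dominance",
    "boundary_sweep",
]

PROVINCES = ("shallow", "transition", "deep")


@dataclass(frozen=True)
class ProvinceScheme:
    """Depth boundaries of the tentative biogeographic provinces (metres).

    shallow [0, b1), transition [b1, b2), deep [b2, inf); half-open.
    """

    b1: float = 4300.0
    b2: float = 4800.0

    def __post_init__(self) -> None:
        if not (0 < self.b1 < self.b2):
            raise ValueError("require 0 < b1 < b2")


def classify_province(depth: float, scheme: ProvinceScheme = ProvinceScheme()) -> str:
    if depth <= 0:
        raise ValueError("depth must be positive")
    if depth < scheme.b1:
        return "shallow"
    if depth < scheme.b2:
        return "transition"
    return "deep"


@dataclass(frozen=True)
class RidgelineDistribution:
    """Normalized depth histogram of one higher taxon's specimen occurrences."""

    group: str
    bin_edges: np.ndarray
    frequencies: np.ndarray  # sums to 1 over the group's occurrences


def ridgeline(
    table: OccurrenceTable,
    min_occurrences: int = 50,
    bin_width_m: float = 100.0,
) -> list[RidgelineDistribution]:
    """Depth distribution of total abundance per dominant higher taxon.

    Only groups with strictly more than ``min_occurrences`` specimen
    occurrences qualify. Bin edges are aligned to multiples of the bin
    width and shared across groups; frequencies are relative to each
    group's own occurrence total.
    """
    rec = table.records
    if len(rec) == 0:
        return []
    lo = np.floor(rec["depth"].min() / bin_width_m) * bin_width_m
    hi = np.floor(rec["depth"].max() / bin_width_m + 1) * bin_width_m
    edges = np.arange(lo, hi + 0.5 * bin_width_m, bin_width_m)
    out = []
    for group, grp in rec.groupby("higher_taxon", sort=True):
        if len(grp) <= min_occurrences:
            continue
        counts, _ = np.histogram(grp["depth"], bins=edges)
        out.append(
            RidgelineDistribution(
                group=str(group),
                bin_edges=edges.copy(),
                frequencies=counts / counts.sum(),
            )
        )
    return out


@dataclass(frozen=True)
class OverlapCounts:
    """Morphotype presence/exclusivity structure across provinces.

    ``per_province`` maps province -> dict with ``total``, ``exclusive`` and
    ``rare_exclusive`` (exclusive with < rare_threshold total occurrences);
    shallow-deep sharing ignores transition membership.
    """

    per_province: dict[str, dict[str, int]]
    shared_shallow_deep: int
    shared_shallow_deep_rare: int
    rare_threshold: int = 5


def overlap_counts(
    samples: Sequence[CommunitySample],
    scheme: ProvinceScheme = ProvinceScheme(),
    rare_threshold: int = 5,
) -> OverlapCounts:
    """Province totals, exclusives and shallow-deep sharing from BD samples.

    A morphotype's province set is the set of provinces (by sample mean
    depth) of the samples in which its abundance is positive; 'rare' means
    fewer than ``rare_threshold`` specimens in total across all samples.
    """
    presence: dict[str, set[str]] = {}
    totals: dict[str, int] = {}
    for s in samples:
        prov = classify_province(s.mean_depth, scheme)
        for t, v in s.abundances.items():
            if v > 0:
                presence.setdefault(t, set()).add(prov)
                totals[t] = totals.get(t, 0) + v
    per_province = {
        p: {"total": 0, "exclusive": 0, "rare_exclusive": 0} for p in PROVINCES
    }
    shared = shared_rare = 0
    for t, provs in presence.items():
        rare = totals[t] < rare_threshold
        for p in provs:
            per_province[p]["total"] += 1
        if len(provs) == 1:
            (p,) = provs
            per_province[p]["exclusive"] += 1
            if rare:
                per_province[p]["rare_exclusive"] += 1
        if "shallow" in provs and "deep" in provs:
            shared += 1
            if rare:
                shared_rare += 1
    return OverlapCounts(
        per_province=per_province,
        shared_shallow_deep=shared,
        shared_shallow_deep_rare=shared_rare,
        rare_threshold=rare_threshold,
    )


@dataclass(frozen=True)
class DominanceTable:
    """Top-k ranked taxa and their cumulative abundance share per province."""

    level: str  # 'morphotype' | 'group'
    k: int
    tables: dict[str, pd.DataFrame]  # province -> ranked table
    topk_share: dict[str, float]  # province -> cumulative share of top k


def dominance(
    samples: Sequence[CommunitySample],
    level: str = "morphotype",
    k: int | None = None,
    scheme: ProvinceScheme = ProvinceScheme(),
    groups: Mapping[str, str] | None = None,
) -> DominanceTable:
    """Rank taxa by pooled abundance (BD) or pooled density (SS) per province.

    ``level='group'`` aggregates taxa through the ``groups`` mapping
    (taxon label -> higher taxon). Ties are broken by label order so the
    ranking is deterministic. ``k`` defaults to 10 for morphotypes and 4
    for groups.
    """
    if level not in ("morphotype", "group"):
        raise ValueError("level must be 'morphotype' or 'group'")
    if level == "group" and groups is None:
        raise ValueError("level='group' requires a taxon->group mapping")
    if k is None:
        k = 10 if level == "morphotype" else 4
    pooled: dict[str, dict[str, float]] = {}
    areas: dict[str, float] = {}
    for s in samples:
        prov = classify_province(s.mean_depth, scheme)
        d = pooled.setdefault(prov, {})
        for t, v in s.abundances.items():
            key = groups.get(t, t) if level == "group" else t
            d[key] = d.get(key, 0.0) + v
        if s.mode == "SS" and s.area:
            areas[prov] = areas.get(prov, 0.0) + s.area
    tables: dict[str, pd.DataFrame] = {}
    shares: dict[str, float] = {}
    for prov, d in pooled.items():
        items = sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))
        total = sum(d.values())
        df = pd.DataFrame(items, columns=["taxon", "abundance"])
        df["share"] = df["abundance"] / total
        if prov in areas:
            df["density"] = df["abundance"] / areas[prov]
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        tables[prov] = df.head(k).reset_index(drop=True)
        shares[prov] = float(df["share"].head(k).sum())
    return DominanceTable(level=level, k=k, tables=tables, topk_share=shares)


def boundary_sweep(
    samples: Sequence[CommunitySample],
    dissimilarity: "np.ndarray | object" = None,
    candidates: Sequence[float] | None = None,
    window_m: float = 300.0,
    min_per_side: int = 5,
) -> pd.DataFrame:
    """Moving split-window estimate of the community replacement depth.

    For each candidate boundary b, the samples within ``window_m`` metres
    above and below b form two groups; the score is their mean pairwise
    Bray-Curtis dissimilarity *between* groups minus the mean *within*
    them. Smooth gradient turnover contributes a near-constant baseline
    to both terms, while an abrupt compositional replacement at b raises
    only the between term, so the score peaks at the replacement depth.
    Returns a tidy frame (boundary_m, score, between_mean, within_mean,
    n_above, n_below) over candidates with at least ``min_per_side``
    samples on each side of the window.
    """
    from .beta_diversity import DissimilarityMatrix, bray_curtis

    if dissimilarity is None:
        dissimilarity = bray_curtis(samples)
    D = (
        dissimilarity.values
        if isinstance(dissimilarity, DissimilarityMatrix)
        else np.asarray(dissimilarity)
    )
    depths = np.array([s.mean_depth for s in samples])
    if candidates is None:
        lo = np.floor(depths.min() / 50) * 50 + 100
        hi = np.ceil(depths.max() / 50) * 50 - 100
        candidates = np.arange(lo, hi + 1, 50.0)
    rows = []
    for b in candidates:
        above = (depths >= b - window_m) & (depths < b)
        below = (depths >= b) & (depths < b + window_m)
        na, nb = int(above.sum()), int(below.sum())
        if min(na, nb) < min_per_side:
            continue
        between = float(D[np.ix_(above, below)].mean())
        wa = D[np.ix_(above, above)].sum() / (na * (na - 1)) if na > 1 else 0.0
        wb = D[np.ix_(below, below)].sum() / (nb * (nb - 1)) if nb > 1 else 0.0
        within = 0.5 * (wa + wb)
        rows.append(
            {
                "boundary_m": float(b),
                "score": between - within,
                "between_mean": between,
                "within_mean": within,
                "n_above": na,
                "n_below": nb,
            }
        )
    return pd.DataFrame(rows)
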