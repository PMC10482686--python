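"""Synthetic occurrence generator emulating the abyssal north-east Pacific.

The generator produces occurrence tables with the statistical structure
the analysis pipeline assumes, plus the programmed ground truth needed
for recovery tests:

* **Site layout.** 14 sites on a joint depth/latitude/longitude gradient
  (shallow seabed in the productive south-east, deep seabed in the
  north-west), each holding 1-6 clustered survey locations spaced >= 25 km
  apart, spanning 3,900-5,300 m.
* **Food supply.** A Martin-type particulate-organic-carbon flux field:
  satellite-style export flux at a 100 m reference depth, ramped linearly
  with latitude, attenuated vertically as F(z) = F_exp * (z/z_ref)^-b with
  the canonical open-ocean exponent b = 0.858.
* **Standing stocks.** Per-image specimen counts are Poisson with mean
  proportional to image area and local POC flux, so density scales
  linearly with food supply.
* **Community structure.** 400 morphotypes with log-series (long-tailed)
  abundance weights; each morphotype carries a monotone or flat depth
  response: calcifiers (``ccd_restricted``) have a hard occurrence cut-off
  below the carbonate compensation depth, soft corals and their like
  decline with depth, anemone/holothurian analogues increase, the rest
  are depth-neutral. With only monotone/flat profiles, no morphotype can
  be exclusive to the transition band, by construction.
* **Identification noise.** ~30% of specimens are relabelled to
  higher-taxon level only, emulating records unidentifiable to morphotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    FRAME_COLUMNS,
    INDET_SUFFIX,
    RECORD_COLUMNS,
    OccurrenceTable,
)

__all__ = [
    "SyntheticConfig",
    "TaxonResponse",
    "SyntheticTruth",
    "PocModel",
    "poc_flux_model",
    "generate_community",
    "generate_occurrences",
]

RESPONSES = ("ccd_restricted", "declining", "increasing", "ubiquitous", "transition_free")

#: taxon pools per response class: (higher_taxon, phylum, guild)
_CLASS_TAXA: dict[str, list[tuple[str, str, str]]] = {
    "ccd_restricted": [
        ("Bivalvia", "Mollusca", "suspension"),
        ("Gastropoda", "Mollusca", "scavenger_predator"),
        ("Polyplacophora", "Mollusca", "deposit"),
        ("Bryozoa", "Bryozoa", "suspension"),
    ],
    "declining": [
        ("Alcyonacea", "Cnidaria", "suspension"),
        ("Ophiuroidea", "Echinodermata", "deposit"),
        ("Demospongiae", "Porifera", "suspension"),
    ],
    "increasing": [
        ("Actiniaria", "Cnidaria", "scavenger_predator"),
        ("Holothuroidea", "Echinodermata", "deposit"),
        ("Antipatharia", "Cnidaria", "suspension"),
    ],
    "ubiquitous": [
        ("Hexactinellida", "Porifera", "suspension"),
        ("Decapoda", "Arthropoda", "scavenger_predator"),
        ("Echiura", "Annelida", "deposit"),
    ],
    "transition_free": [
        ("Hemichordata", "Hemichordata", "deposit"),
        ("Ascidiacea", "Chordata", "suspension"),
    ],
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate the study region's structure."""

    n_sites: int = 14
    #: survey locations per site (sums to 28 by default)
    locations_per_site: tuple[int, ...] = (1, 1, 1, 2, 2, 2, 1, 3, 1, 3, 6, 3, 1, 1)
    depth_range: tuple[float, float] = (3900.0, 5300.0)
    ccd_depth: float = 4600.0  # within the region's 4,400-4,800 m CCD band
    province_boundaries: tuple[float, float] = (4300.0, 4800.0)
    lat_range: tuple[float, float] = (10.5, 16.5)  # south (shallow) to north (deep)
    lon_range: tuple[float, float] = (-117.0, -154.0)  # east (shallow) to west (deep)
    #: export flux at z_ref, gC m-2 yr-1, at the south and north latitude ends
    export_flux_south: float = 42.0
    export_flux_north: float = 6.0
    martin_b: float = 0.858
    z_ref_m: float = 100.0
    n_morphotypes: int = 400
    logseries_p: float = 0.999  # Fisher log-series shape of abundance weights
    sad_concentration: float = 2.0  # weight exponent: >1 sharpens dominance
    #: evenness increases with depth: SAD weights are raised to an exponent
    #: falling linearly from 1 (shallowest) to this value (deepest), so deep
    #: communities are flatter (higher evenness) at equal richness pool
    evenness_exponent_deep: float = 0.45
    #: response-class mixture over morphotypes
    mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "ccd_restricted": 0.12,
            "declining": 0.24,
            "increasing": 0.24,
            "ubiquitous": 0.30,
            "transition_free": 0.10,
        }
    )
    response_efold_m: float = 250.0  # e-folding of declining/increasing profiles
    density_scale: float = 0.75  # expected ind m-2 at reference seabed flux 1 gC m-2 yr-1
    area_per_image_m2: float = 3.0
    #: when None, survey effort adapts to local density toward this specimen target
    images_per_location: int | None = None
    target_specimens_per_location: int = 2000
    max_images_per_location: int = 4000
    min_images_per_location: int = 150
    n_video_locations: int = 4  # locations lacking image areas (density-excluded)
    frac_higher_only: float = 0.30
    location_spacing_km: float = 30.0
    depth_jitter_m: float = 120.0
    frame_depth_step_m: float = 20.0
    frame_depth_halfwidth_m: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.locations_per_site) != self.n_sites:
            raise ValueError("locations_per_site must have n_sites entries")
        if not (self.depth_range[0] < self.ccd_depth < self.depth_range[1]):
            raise ValueError("ccd_depth must lie within depth_range")
        if abs(sum(self.mix.values()) - 1.0) > 1e-9:
            raise ValueError("response mix must sum to 1")


@dataclass(frozen=True)
class TaxonResponse:
    """One morphotype's programmed identity and depth response."""

    morphotype: str
    higher_taxon: str
    phylum: str
    guild: str
    response: str
    base_weight: float  # log-series abundance weight (relative)


@dataclass
class SyntheticTruth:
    """The generator's programmed parameters, for recovery tests."""

    ccd_depth: float
    density_scale: float
    martin_b: float
    density_flux_slope: float  # d density / d flux (ind m-2 per gC m-2 yr-1)
    province_boundaries: tuple[float, float]
    community: pd.DataFrame  # morphotype, class, weights, expected totals
    expected_total_specimens: float


class PocModel:
    """Martin-curve POC flux field: F(lat, z) = F_export(lat) * (z/z_ref)^-b."""

    def __init__(self, config: SyntheticConfig):
        self.config = config

    def export_flux(self, latitude) -> np.ndarray:
        c = self.config
        lo, hi = c.lat_range
        t = (np.asarray(latitude, dtype=float) - lo) / (hi - lo)
        f = c.export_flux_south + t * (c.export_flux_north - c.export_flux_south)
        return np.maximum(f, 0.1)

    def __call__(self, latitude, longitude, depth) -> float | np.ndarray:
        z = np.asarray(depth, dtype=float)
        if np.any(z <= 0):
            raise ValueError("depth must be positive")
        out = self.export_flux(latitude) * (z / self.config.z_ref_m) ** (
            -self.config.martin_b
        )
        return float(out) if np.isscalar(depth) else out


def poc_flux_model(config: SyntheticConfig = SyntheticConfig()) -> PocModel:
    """Build the POC flux field (callable over latitude, longitude, depth)."""
    return PocModel(config)


def _logseries_weights(rng, n: int, p: float, concentration: float = 1.0) -> np.ndarray:
    """Long-tailed relative abundance weights from a Fisher log-series.

    ``concentration`` > 1 raises the draws to a power, sharpening the
    dominance of the commonest taxa (calibrates per-sample evenness).
    """
    draws = rng.logseries(p, size=n).astype(float) ** concentration
    return draws / draws.sum()


def generate_community(
    config: SyntheticConfig = SyntheticConfig(), seed: int | None = None
) -> list[TaxonResponse]:
    """Draw the morphotype pool: SAD weights, response classes, taxonomy."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_morphotypes
    weights = _logseries_weights(rng, n, config.logseries_p, config.sad_concentration)
    classes = list(config.mix)
    probs = np.array([config.mix[c] for c in classes], dtype=float)
    assigned = rng.choice(len(classes), size=n, p=probs)
    out: list[TaxonResponse] = []
    for i in range(n):
        cls = classes[assigned[i]]
        taxa = _CLASS_TAXA[cls]
        higher, phylum, guild = taxa[rng.integers(len(taxa))]
        out.append(
            TaxonResponse(
                morphotype=f"M{i + 1:04d}",
                higher_taxon=higher,
                phylum=phylum,
                guild=guild,
                response=cls,
                base_weight=float(weights[i]),
            )
        )
    return out


def _depth_profile(response: str, depth, config: SyntheticConfig) -> np.ndarray:
    """Relative occurrence-probability multiplier at a given depth."""
    z = np.asarray(depth, dtype=float)
    zmin, zmax = config.depth_range
    tau = config.response_efold_m
    if response == "declining":
        return np.exp(-(z - zmin) / tau)
    if response == "increasing":
        return np.exp((z - zmax) / tau)
    if response == "ccd_restricted":
        # abundant right up to the CCD, absent below: a hard cliff, matching
        # the abrupt disappearance of shelled calcifiers
        return np.where(z <= config.ccd_depth, 1.0, 0.0)
    # ubiquitous / transition_free: flat
    return np.ones_like(z)


def generate_occurrences(
    config: SyntheticConfig = SyntheticConfig(),
    community: list[TaxonResponse] | None = None,
    seed: int | None = None,
) -> tuple[OccurrenceTable, SyntheticTruth]:
    """Generate a full occurrence table plus its programmed ground truth.

    Deterministic given (config, seed): the same inputs reproduce the
    table byte for byte.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if community is None:
        community = generate_community(config, seed=seed)
    flux = PocModel(config)

    n_sites = config.n_sites
    # site index runs west to east (deep/north first), matching the order in
    # which locations_per_site is specified
    t = np.linspace(1.0, 0.0, n_sites)  # 1 = deep/north-west, 0 = shallow/south-east
    site_depth = config.depth_range[0] + t * (
        config.depth_range[1] - config.depth_range[0]
    )
    site_lat = config.lat_range[0] + t * (config.lat_range[1] - config.lat_range[0])
    site_lon = config.lon_range[1] + (1 - t) * (
        config.lon_range[0] - config.lon_range[1]
    )
    sites = [f"SITE{j + 1:02d}" for j in range(n_sites)]

    # choose which locations are video platforms (no usable area)
    n_loc_total = int(sum(config.locations_per_site))
    video_locs = set(
        rng.choice(n_loc_total, size=min(config.n_video_locations, n_loc_total), replace=False)
    )

    base_w = np.array([c.base_weight for c in community])
    responses = [c.response for c in community]

    rec_rows: list[dict] = []
    frame_rows: list[dict] = []
    expected_by_taxon = np.zeros(len(community))
    expected_total = 0.0
    loc_counter = 0
    spec_counter = 0
    km_per_deg_lat = 111.19
    for j in range(n_sites):
        km_per_deg_lon = 111.19 * np.cos(np.radians(site_lat[j]))
        for l in range(config.locations_per_site[j]):
            loc_depth = float(
                np.clip(
                    site_depth[j] + rng.uniform(-1, 1) * config.depth_jitter_m,
                    config.depth_range[0] + config.frame_depth_halfwidth_m,
                    config.depth_range[1] - config.frame_depth_halfwidth_m,
                )
            )
            # offset locations along latitude so within-site clusters stay >= spacing apart
            lat_c = site_lat[j] + l * config.location_spacing_km / km_per_deg_lat
            lon_c = site_lon[j]
            f_here = float(flux(lat_c, lon_c, loc_depth))
            dens = config.density_scale * f_here  # expected ind m-2
            if config.images_per_location is not None:
                n_img = config.images_per_location
            else:
                n_img = int(
                    np.clip(
                        round(
                            config.target_specimens_per_location
                            / max(dens * config.area_per_image_m2, 1e-9)
                        ),
                        config.min_images_per_location,
                        config.max_images_per_location,
                    )
                )
            is_video = loc_counter in video_locs
            # frame depths on a coarse grid around the location depth
            nsteps = int(config.frame_depth_halfwidth_m // config.frame_depth_step_m)
            steps = rng.integers(-nsteps, nsteps + 1, size=n_img)
            fdepth = loc_depth + steps * config.frame_depth_step_m
            flat = lat_c + rng.normal(0.0, 0.05, size=n_img) / km_per_deg_lat
            flon = lon_c + rng.normal(0.0, 0.05, size=n_img) / km_per_deg_lon
            f_img = flux.export_flux(lat_c) * (fdepth / config.z_ref_m) ** (
                -config.martin_b
            )
            lam = config.density_scale * f_img * config.area_per_image_m2
            counts = rng.poisson(lam)
            image_ids = [f"IMG{loc_counter:03d}_{i:05d}" for i in range(n_img)]
            for i in range(n_img):
                frame_rows.append(
                    {
                        "image_id": image_ids[i],
                        "site": sites[j],
                        "latitude": float(flat[i]),
                        "longitude": float(flon[i]),
                        "depth": float(fdepth[i]),
                        "area": np.nan if is_video else config.area_per_image_m2,
                    }
                )
            # assign morphotypes per unique frame depth (shared probability vector)
            for z in np.unique(fdepth):
                sel = fdepth == z
                n_here = int(counts[sel].sum())
                prof = np.array(
                    [_depth_profile(r, z, config) for r in responses], dtype=float
                ).ravel()
                # evenness rises with depth: flatten the SAD weights
                zmin, zmax = config.depth_range
                frac = np.clip((z - zmin) / (zmax - zmin), 0.0, 1.0)
                gamma = 1.0 + frac * (config.evenness_exponent_deep - 1.0)
                w = base_w**gamma * prof
                wsum = w.sum()
                if wsum <= 0 or n_here == 0:
                    lam_here = float(lam[sel].sum())
                    expected_total += lam_here
                    continue
                p = w / wsum
                picks = rng.choice(len(community), size=n_here, p=p)
                lam_here = float(lam[sel].sum())
                expected_total += lam_here
                expected_by_taxon += lam_here * p
                # distribute picks across this depth group's frames in order
                frame_idx = np.repeat(np.flatnonzero(sel), counts[sel])
                for pick, fi in zip(picks, frame_idx):
                    c = community[pick]
                    rec_rows.append(
                        {
                            "specimen_id": f"SP{spec_counter:06d}",
                            "image_id": image_ids[fi],
                            "site": sites[j],
                            "latitude": float(flat[fi]),
                            "longitude": float(flon[fi]),
                            "depth": float(fdepth[fi]),
                            "morphotype": c.morphotype,
                            "higher_taxon": c.higher_taxon,
                            "phylum": c.phylum,
                            "guild": c.guild,
                        }
                    )
                    spec_counter += 1
            loc_counter += 1

    records = pd.DataFrame(rec_rows)
    frames = pd.DataFrame(frame_rows, columns=FRAME_COLUMNS)
    # relabel ~frac_higher_only of specimens to higher-taxon level only
    n_rec = len(records)
    n_drop = int(round(config.frac_higher_only * n_rec))
    drop_idx = rng.choice(n_rec, size=n_drop, replace=False)
    records["id_level"] = "morphotype"
    records.loc[drop_idx, "morphotype"] = np.nan
    records.loc[drop_idx, "id_level"] = "higher_only"
    records["taxon"] = records["morphotype"].where(
        records["morphotype"].notna(), records["higher_taxon"] + INDET_SUFFIX
    )
    table = OccurrenceTable(
        records=records[RECORD_COLUMNS],
        frames=frames,
        provenance=f"synthetic(seed={seed})",
    ).validate()

    comm_df = pd.DataFrame(
        {
            "morphotype": [c.morphotype for c in community],
            "higher_taxon": [c.higher_taxon for c in community],
            "phylum": [c.phylum for c in community],
            "guild": [c.guild for c in community],
            "response": responses,
            "base_weight": base_w,
            "expected_total": expected_by_taxon,
        }
    )
    truth = SyntheticTruth(
        ccd_depth=config.ccd_depth,
        density_scale=config.density_scale,
        martin_b=config.martin_b,
        density_flux_slope=config.density_scale,
        province_boundaries=config.province_boundaries,
        community=comm_df,
        expected_total_specimens=expected_total,
    )
    return table, truth
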