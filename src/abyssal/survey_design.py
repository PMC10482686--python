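"""Geographic gridding and specimen-rarefied replicate sample construction.

Occurrence data from seabed-imagery surveys are spatially clumped: each
dive or transect yields thousands of specimens within a few kilometres.
To characterise communities while limiting spatial autocorrelation, the
survey design (i) partitions specimens into geographical *locations* by a
10 x 10 km regional grid (never merging across study sites), (ii)
constrains each location's data to 200 m depth bins, and (iii) resamples
specimens without replacement within each location x depth-bin pool into
equally sized replicate community samples:

* BD samples: exactly 200 morphotype-level specimens each (leftovers below
  200 are discarded, never pooled across bins or locations);
* SS samples: whole still images accumulated until 450-500 specimens, so
  each sample carries a coherent specimen count / seabed area pairing.

The grid lives in a local equirectangular projection about the dataset
centroid (x = R cos(phi0) dlambda, y = R dphi); at abyssal-Pacific
latitudes the distortion over a 10 km cell is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import CommunitySample, OccurrenceTable

__all__ = [
    "EARTH_RADIUS_KM",
    "SamplingPlan",
    "GridLocation",
    "CommunitySample",
    "project_local",
    "assign_grid_locations",
    "bin_by_depth",
    "make_samples",
    "attach_environment",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class SamplingPlan:
    """Parameters of the gridding / rarefaction design."""

    cell_size_km: float = 10.0
    depth_bin_width_m: float = 200.0
    bd_size: int = 200
    ss_min: int = 450
    ss_max: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cell_size_km, self.depth_bin_width_m, self.bd_size) <= 0:
            raise ValueError("cell size, bin width and bd_size must be positive")
        if not (0 < self.ss_min <= self.ss_max):
            raise ValueError("require 0 < ss_min <= ss_max")


@dataclass
class GridLocation:
    """One 100 km^2 grid cell's worth of records within a single site."""

    location_id: str
    site: str
    cell_indices: tuple[int, int]
    mean_latitude: float
    mean_longitude: float
    records: pd.DataFrame


def project_local(
    latitude, longitude, lat0: float, lon0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection (km) about (lat0, lon0)."""
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    x = EARTH_RADIUS_KM * np.cos(np.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_KM * np.radians(lat - lat0)
    return x, y


def assign_grid_locations(
    table: OccurrenceTable, plan: SamplingPlan = SamplingPlan()
) -> list[GridLocation]:
    """Partition records into grid-cell locations (cells never span sites).

    Records are projected about the dataset centroid and floor-divided into
    ``cell_size_km`` cells with origin at projected (0, 0). Location mean
    lat/lon is the arithmetic mean over member records.
    """
    rec = table.records
    if len(rec) == 0:
        return []
    if (rec["latitude"].abs() > 85).any():
        raise ValueError("record latitude beyond |85| deg: projection invalid")
    lat0 = float(rec["latitude"].mean())
    lon0 = float(rec["longitude"].mean())
    x, y = project_local(rec["latitude"], rec["longitude"], lat0, lon0)
    cx = np.floor(x / plan.cell_size_km).astype(int)
    cy = np.floor(y / plan.cell_size_km).astype(int)
    keyed = rec.assign(_cx=cx, _cy=cy)
    out: list[GridLocation] = []
    for (site, i, j), grp in keyed.groupby(["site", "_cx", "_cy"], sort=True):
        grp = grp.drop(columns=["_cx", "_cy"]).reset_index(drop=True)
        out.append(
            GridLocation(
                location_id=f"{site}({i},{j})",
                site=str(site),
                cell_indices=(int(i), int(j)),
                mean_latitude=float(grp["latitude"].mean()),
                mean_longitude=float(grp["longitude"].mean()),
                records=grp,
            )
        )
    return out


def bin_by_depth(
    location: GridLocation, plan: SamplingPlan = SamplingPlan()
) -> list[tuple[tuple[float, float], pd.DataFrame]]:
    """Split a location's records into half-open depth bins [200k, 200(k+1)).

    Bins are aligned to multiples of the bin width; empty bins are omitted.
    """
    w = plan.depth_bin_width_m
    k = np.floor(location.records["depth"] / w).astype(int)
    out = []
    for kk, grp in location.records.groupby(k, sort=True):
        out.append(((kk * w, (kk + 1) * w), grp.reset_index(drop=True)))
    return out


def _sample_meta(depths, lats, lons) -> tuple[float, float, float]:
    return float(np.mean(depths)), float(np.mean(lats)), float(np.mean(lons))


def make_samples(
    table: OccurrenceTable, mode: str, plan: SamplingPlan = SamplingPlan()
) -> list[CommunitySample]:
    """Build equally sized replicate community samples per location x depth bin.

    The table must already be restricted with
    :func:`abyssal.data_model.filter_subset` to the matching subset. A single
    seeded generator (``plan.seed``) drives all shuffling, so a fixed plan and
    input reproduce the sample set exactly.
    """
    if mode == "BD":
        if (table.records["id_level"] != "morphotype").any():
            raise ValueError(
                "BD sampling requires morphotype-level records only; "
                "apply filter_subset(table, 'BD') first"
            )
    elif mode == "SS":
        frame_area = table.frames.set_index("image_id")["area"]
        if frame_area.isna().any():
            raise ValueError(
                "SS sampling requires a measured area for every frame; "
                "apply filter_subset(table, 'SS') first"
            )
    else:
        raise ValueError(f"mode must be 'BD' or 'SS', got {mode!r}")

    rng = np.random.default_rng(plan.seed)
    samples: list[CommunitySample] = []
    frame_cells = None
    if mode == "SS":
        # frames are assigned to grid cells by their own coordinates so that
        # zero-specimen images still contribute seabed area to densities
        rec = table.records
        lat0 = float(rec["latitude"].mean())
        lon0 = float(rec["longitude"].mean())
        fx, fy = project_local(
            table.frames["latitude"], table.frames["longitude"], lat0, lon0
        )
        frame_cells = table.frames.assign(
            _cx=np.floor(fx / plan.cell_size_km).astype(int),
            _cy=np.floor(fy / plan.cell_size_km).astype(int),
        )
    for loc in assign_grid_locations(table, plan):
        if mode == "BD":
            for (low, high), pool in bin_by_depth(loc, plan):
                samples.extend(_bd_samples(loc, (low, high), pool, plan, rng))
        else:
            cx, cy = loc.cell_indices
            loc_frames = frame_cells[
                (frame_cells["site"] == loc.site)
                & (frame_cells["_cx"] == cx)
                & (frame_cells["_cy"] == cy)
            ]
            pool_all = loc.records
            w = plan.depth_bin_width_m
            kf = np.floor(loc_frames["depth"] / w).astype(int)
            for kk, fsub in loc_frames.groupby(kf, sort=True):
                low, high = kk * w, (kk + 1) * w
                pool = pool_all[pool_all["image_id"].isin(set(fsub["image_id"]))]
                samples.extend(
                    _ss_samples(loc, (low, high), pool, fsub, plan, rng)
                )
    return samples


def _bd_samples(loc, depth_bin, pool, plan, rng) -> list[CommunitySample]:
    low, high = depth_bin
    n = len(pool)
    perm = rng.permutation(n)
    out = []
    for i in range(n // plan.bd_size):
        chunk = pool.iloc[perm[i * plan.bd_size : (i + 1) * plan.bd_size]]
        md, mla, mlo = _sample_meta(chunk["depth"], chunk["latitude"], chunk["longitude"])
        ab = chunk["taxon"].value_counts().to_dict()
        out.append(
            CommunitySample(
                sample_id=f"{loc.location_id}|{int(low)}|BD{i:02d}",
                location_id=loc.location_id,
                site=loc.site,
                depth_bin=(float(low), float(high)),
                mean_depth=md,
                mean_latitude=mla,
                mean_longitude=mlo,
                mode="BD",
                abundances={str(k): int(v) for k, v in sorted(ab.items())},
                n_specimens=plan.bd_size,
            )
        )
    return out


def _ss_samples(loc, depth_bin, pool, fsub, plan, rng) -> list[CommunitySample]:
    """Accumulate whole (shuffled) images until the specimen window is hit.

    Frames are assigned to the depth bin of their own frame depth; frames
    with zero specimens in the pool still contribute seabed area. A frame
    whose addition would push the count beyond ``ss_max`` is skipped; a
    trailing accumulation that cannot reach ``ss_min`` is discarded.
    """
    low, high = depth_bin
    fsub = fsub.sort_values("image_id").reset_index(drop=True)
    counts = pool.groupby("image_id").size()
    order = rng.permutation(len(fsub))
    out: list[CommunitySample] = []
    cur_frames: list[int] = []
    cur_n = 0
    idx = 0
    for fi in order:
        c = int(counts.get(fsub.at[fi, "image_id"], 0))
        if cur_n + c > plan.ss_max:
            continue  # skipping keeps the sample inside the window
        cur_frames.append(fi)
        cur_n += c
        if cur_n >= plan.ss_min:
            fsel = fsub.iloc[cur_frames]
            members = pool[pool["image_id"].isin(set(fsel["image_id"]))]
            md, mla, mlo = _sample_meta(
                fsel["depth"], fsel["latitude"], fsel["longitude"]
            )
            ab = members["taxon"].value_counts().to_dict()
            out.append(
                CommunitySample(
                    sample_id=f"{loc.location_id}|{int(low)}|SS{idx:02d}",
                    location_id=loc.location_id,
                    site=loc.site,
                    depth_bin=(float(low), float(high)),
                    mean_depth=md,
                    mean_latitude=mla,
                    mean_longitude=mlo,
                    mode="SS",
                    abundances={str(k): int(v) for k, v in sorted(ab.items())},
                    n_specimens=cur_n,
                    area=float(fsel["area"].sum()),
                )
            )
            idx += 1
            cur_frames, cur_n = [], 0
    return out


def attach_environment(
    samples: Sequence[CommunitySample],
    poc_model: Callable[[float, float, float], float],
) -> Sequence[CommunitySample]:
    """Evaluate a POC-flux model at each sample's mean position and depth.

    Sets ``poc_flux`` (gC m^-2 yr^-1) in place and returns the samples.
    Idempotent: re-attaching the same model reproduces the same values.
    """
    for s in samples:
        v = float(poc_model(s.mean_latitude, s.mean_longitude, s.mean_depth))
        if not np.isfinite(v):
            raise ValueError(
                f"POC model undefined at sample {s.sample_id} "
                f"(lat={s.mean_latitude}, lon={s.mean_longitude}, depth={s.mean_depth})"
            )
        s.poc_flux = v
    return samples
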