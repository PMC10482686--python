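"""Domain types, occurrence-table I/O, validation and subset filters.

The pipeline's raw input is a flat table of megafauna specimen detections
from seabed imagery: one row per specimen, carrying its source image, site,
position, depth and taxonomic identification. Specimens identified to a
catalogue morphotype (treated as species-level units) carry
``id_level='morphotype'``; specimens only identifiable to a higher taxon
(e.g. class or order) carry ``id_level='higher_only'`` and are used for
standing-stock (density) analyses only.

Two analysis subsets mirror the survey design:

* **BD** (biodiversity): morphotype-level records from any platform
  (stills or video).
* **SS** (standing stocks): records at any identification level, but only
  from scalable still images with a measured seabed area, so that
  densities (ind m^-2) are well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GUILDS",
    "OccurrenceFormatError",
    "OccurrenceTable",
    "CatalogueEntry",
    "CommunitySample",
    "read_occurrences",
    "write_occurrences",
    "read_catalogue",
    "filter_subset",
    "write_samples",
    "read_samples",
    "taxon_groups",
]

GUILDS = ("suspension", "deposit", "scavenger_predator", "unknown")

#: canonical record columns; `morphotype`, `guild`, `area` are optional on input
RECORD_COLUMNS = [
    "specimen_id",
    "image_id",
    "site",
    "latitude",
    "longitude",
    "depth",
    "morphotype",
    "higher_taxon",
    "phylum",
    "guild",
    "id_level",
    "taxon",
]

FRAME_COLUMNS = ["image_id", "site", "latitude", "longitude", "depth", "area"]

MANDATORY = ["specimen_id", "image_id", "site", "latitude", "longitude", "depth"]

#: indeterminate-taxon suffix used to key higher_only records in SS abundance vectors
INDET_SUFFIX = " indet."


class OccurrenceFormatError(ValueError):
    """Raised for malformed occurrence tables (missing columns, bad rows)."""


@dataclass(frozen=True)
class CatalogueEntry:
    """One morphotype of the standardized image-based catalogue.

    Open-nomenclature qualifiers (e.g. ``sp. indet.``) are carried as
    metadata only; every catalogue morphotype is a distinct species-level
    unit for all analyses.
    """

    morphotype: str
    open_nomenclature_qualifier: str = ""
    phylum: str = ""
    higher_taxon: str = ""
    guild: str = "unknown"


@dataclass
class OccurrenceTable:
    """A validated set of specimen records plus their source image frames.

    ``records`` has the columns of :data:`RECORD_COLUMNS`; ``frames`` the
    columns of :data:`FRAME_COLUMNS` (``area`` is NaN for video-derived
    imagery). Every record's ``image_id`` resolves to exactly one frame.
    """

    records: pd.DataFrame
    frames: pd.DataFrame
    provenance: str = ""
    unknown_morphotypes: list[str] = field(default_factory=list)

    def __len__(self) -> int:  # number of specimen records
        return len(self.records)

    def validate(self) -> "OccurrenceTable":
        r = self.records
        if r["specimen_id"].duplicated().any():
            dup = r.loc[r["specimen_id"].duplicated(), "specimen_id"].iloc[0]
            raise OccurrenceFormatError(f"duplicate specimen_id {dup!r}")
        if self.frames["image_id"].duplicated().any():
            raise OccurrenceFormatError("duplicate image_id in frames")
        missing = set(r["image_id"]) - set(self.frames["image_id"])
        if missing:
            raise OccurrenceFormatError(
                f"records reference unknown image_id(s): {sorted(missing)[:5]}"
            )
        bad_depth = ~r["depth"].between(0, 11000, inclusive="neither")
        if bad_depth.any():
            raise OccurrenceFormatError(
                f"depth outside (0, 11000) m for specimen "
                f"{r.loc[bad_depth, 'specimen_id'].iloc[0]!r}"
            )
        if (r["latitude"].abs() > 90).any() or (r["longitude"].abs() > 180).any():
            raise OccurrenceFormatError("coordinates outside valid ranges")
        morpho = r["id_level"] == "morphotype"
        if (morpho != r["morphotype"].notna()).any():
            raise OccurrenceFormatError("id_level inconsistent with morphotype presence")
        area = self.frames["area"]
        if (area.dropna() <= 0).any():
            raise OccurrenceFormatError("frame area must be positive when present")
        return self


@dataclass
class CommunitySample:
    """An equally sized, location- and depth-bin-constrained specimen set.

    BD samples hold exactly ``plan.bd_size`` morphotype-level specimens;
    SS samples hold 450-500 specimens (any id level) from whole still
    images, with the summed seabed ``area`` of those images. ``abundances``
    maps taxon label to count and only stores non-zero entries.
    """

    sample_id: str
    location_id: str
    site: str
    depth_bin: tuple[float, float]
    mean_depth: float
    mean_latitude: float
    mean_longitude: float
    mode: str  # 'BD' | 'SS'
    abundances: dict[str, int]
    n_specimens: int
    area: float | None = None
    poc_flux: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("BD", "SS"):
            raise ValueError(f"mode must be 'BD' or 'SS', got {self.mode!r}")
        if self.n_specimens != sum(self.abundances.values()):
            raise ValueError(
                f"sample {self.sample_id}: n_specimens != sum of abundances"
            )
        low, high = self.depth_bin
        if not (low <= self.mean_depth < high):
            raise ValueError(
                f"sample {self.sample_id}: mean depth {self.mean_depth} outside "
                f"bin [{low}, {high})"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _parse_numeric(df: pd.DataFrame, col: str) -> pd.Series:
    """Parse a numeric column, raising a row-level error with the file line.

    Line numbers are 1-based and count the header, so the first data row is
    line 2 (matching what a user sees in a text editor).
    """
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise OccurrenceFormatError(
            f"unparsable value {raw.iloc[i]!r} in column '{col}' on line {i + 2}"
        )
    return out


def read_occurrences(
    path,
    catalogue: Sequence[CatalogueEntry] | None = None,
    aliases: Mapping[str, str] | None = None,
) -> OccurrenceTable:
    """Read a delimited occurrence table (one row per specimen).

    Parameters
    ----------
    path
        CSV file with a header naming at least ``specimen_id``, ``image_id``,
        ``site``, ``latitude``, ``longitude``, ``depth``. Optional columns:
        ``morphotype``, ``higher_taxon``, ``phylum``, ``guild``, ``area``.
    catalogue
        Optional morphotype catalogue; morphotype labels absent from it are
        reported in ``table.unknown_morphotypes`` (and as a warning) and used
        to fill missing phylum/higher-taxon/guild metadata.
    aliases
        Mapping from the file's column names to the canonical ones, to absorb
        unknown data dialects (e.g. ``{"Lat": "latitude"}``).
    """
    df = pd.read_csv(path, dtype=str)
    if aliases:
        df = df.rename(columns=dict(aliases))
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise OccurrenceFormatError(f"missing mandatory column(s): {missing}")

    for col in ("latitude", "longitude", "depth"):
        df[col] = _parse_numeric(df, col)
    incomplete = df[["latitude", "longitude", "depth"]].isna().any(axis=1)
    if incomplete.any():
        i = int(np.flatnonzero(incomplete.to_numpy())[0])
        raise OccurrenceFormatError(
            f"missing coordinate/depth on line {i + 2}; records without position "
            "are rejected, not imputed"
        )
    if "area" in df.columns:
        df["area"] = _parse_numeric(df, "area")
    else:
        df["area"] = np.nan

    for col in ("morphotype", "higher_taxon", "phylum", "guild"):
        if col not in df.columns:
            df[col] = np.nan
    blank = df["morphotype"].astype(str).str.strip() == ""
    df.loc[blank, "morphotype"] = np.nan
    df["guild"] = df["guild"].fillna("unknown")
    bad_guild = ~df["guild"].isin(GUILDS)
    if bad_guild.any():
        raise OccurrenceFormatError(
            f"unknown guild {df.loc[bad_guild, 'guild'].iloc[0]!r}; "
            f"expected one of {GUILDS}"
        )
    df["id_level"] = np.where(df["morphotype"].notna(), "morphotype", "higher_only")

    unknown: list[str] = []
    if catalogue is not None:
        cat = {e.morphotype: e for e in catalogue}
        labels = df.loc[df["morphotype"].notna(), "morphotype"]
        unknown = sorted(set(labels) - set(cat))
        if unknown:
            warnings.warn(
                f"{len(unknown)} morphotype label(s) absent from catalogue: "
                f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}",
                stacklevel=2,
            )
        for colname, attr in (
            ("higher_taxon", "higher_taxon"),
            ("phylum", "phylum"),
            ("guild", "guild"),
        ):
            fill = df["morphotype"].map(
                {m: getattr(e, attr) for m, e in cat.items()}
            )
            df[colname] = df[colname].where(
                df[colname].notna() & (df[colname] != "unknown"), fill
            )
    df["guild"] = df["guild"].fillna("unknown")
    df["taxon"] = df["morphotype"].where(
        df["morphotype"].notna(),
        df["higher_taxon"].fillna("Unassigned").astype(str) + INDET_SUFFIX,
    )

    frames = (
        df.groupby("image_id", sort=True)
        .agg(
            site=("site", "first"),
            latitude=("latitude", "first"),
            longitude=("longitude", "first"),
            depth=("depth", "first"),
            area=("area", "first"),
        )
        .reset_index()
    )
    records = df[RECORD_COLUMNS].reset_index(drop=True)
    table = OccurrenceTable(
        records=records,
        frames=frames[FRAME_COLUMNS],
        provenance=str(path),
        unknown_morphotypes=unknown,
    )
    return table.validate()


def write_occurrences(table: OccurrenceTable, path) -> None:
    """Write an occurrence table back to flat CSV (area column included)."""
    area = table.frames.set_index("image_id")["area"]
    out = table.records.drop(columns=["id_level", "taxon"]).copy()
    out["area"] = out["image_id"].map(area)
    out.to_csv(path, index=False)


def read_catalogue(path) -> list[CatalogueEntry]:
    """Read a morphotype catalogue CSV (morphotype, qualifier, phylum, higher_taxon, guild)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    if "morphotype" not in df.columns:
        raise OccurrenceFormatError("catalogue must have a 'morphotype' column")
    if df["morphotype"].duplicated().any():
        raise OccurrenceFormatError("catalogue morphotypes must be unique")
    return [
        CatalogueEntry(
            morphotype=row["morphotype"],
            open_nomenclature_qualifier=row.get("qualifier", ""),
            phylum=row.get("phylum", ""),
            higher_taxon=row.get("higher_taxon", ""),
            guild=row.get("guild", "unknown") or "unknown",
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# subset filters


def filter_subset(table: OccurrenceTable, mode: str) -> OccurrenceTable:
    """Restrict an occurrence table to the BD or SS analysis subset.

    ``BD`` keeps only morphotype-level records (any frame type); ``SS`` keeps
    records at all id levels but only those whose frame has a measured seabed
    area (scalable still images). Idempotent.
    """
    if mode == "BD":
        rec = table.records[table.records["id_level"] == "morphotype"]
        frames = table.frames
    elif mode == "SS":
        with_area = table.frames.loc[table.frames["area"].notna(), "image_id"]
        rec = table.records[table.records["image_id"].isin(set(with_area))]
        frames = table.frames[table.frames["area"].notna()]
    else:
        raise ValueError(f"mode must be 'BD' or 'SS', got {mode!r}")
    return OccurrenceTable(
        records=rec.reset_index(drop=True),
        frames=frames.reset_index(drop=True),
        provenance=table.provenance,
    )


def taxon_groups(table: OccurrenceTable) -> pd.DataFrame:
    """Map each abundance-vector taxon label to higher_taxon, phylum and guild."""
    g = (
        table.records.groupby("taxon", sort=True)
        .agg(
            higher_taxon=("higher_taxon", "first"),
            phylum=("phylum", "first"),
            guild=("guild", "first"),
        )
        .reset_index()
    )
    return g


# ---------------------------------------------------------------------------
# sample matrix I/O

_SAMPLE_META = [
    "sample_id",
    "location_id",
    "site",
    "mode",
    "bin_low",
    "bin_high",
    "mean_depth",
    "mean_latitude",
    "mean_longitude",
    "n_specimens",
    "area",
    "poc_flux",
]


def write_samples(samples: Sequence[CommunitySample], path) -> None:
    """Write samples as a wide CSV (samples x taxa, plus metadata columns)."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_id collision in write_samples")
    taxa = sorted({t for s in samples for t in s.abundances})
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "location_id": s.location_id,
            "site": s.site,
            "mode": s.mode,
            "bin_low": s.depth_bin[0],
            "bin_high": s.depth_bin[1],
            "mean_depth": s.mean_depth,
            "mean_latitude": s.mean_latitude,
            "mean_longitude": s.mean_longitude,
            "n_specimens": s.n_specimens,
            "area": np.nan if s.area is None else s.area,
            "poc_flux": np.nan if s.poc_flux is None else s.poc_flux,
        }
        row.update({t: s.abundances.get(t, 0) for t in taxa})
        rows.append(row)
    pd.DataFrame(rows, columns=_SAMPLE_META + taxa).to_csv(path, index=False)


def read_samples(path) -> list[CommunitySample]:
    """Read back a wide sample CSV written by :func:`write_samples`."""
    df = pd.read_csv(path)
    taxa = [c for c in df.columns if c not in _SAMPLE_META]
    out: list[CommunitySample] = []
    for _, row in df.iterrows():
        ab = {t: int(row[t]) for t in taxa if row[t] > 0}
        out.append(
            CommunitySample(
                sample_id=str(row["sample_id"]),
                location_id=str(row["location_id"]),
                site=str(row["site"]),
                depth_bin=(float(row["bin_low"]), float(row["bin_high"])),
                mean_depth=float(row["mean_depth"]),
                mean_latitude=float(row["mean_latitude"]),
                mean_longitude=float(row["mean_longitude"]),
                mode=str(row["mode"]),
                abundances=ab,
                n_specimens=int(row["n_specimens"]),
                area=None if pd.isna(row["area"]) else float(row["area"]),
                poc_flux=None if pd.isna(row["poc_flux"]) else float(row["poc_flux"]),
            )
        )
    return out
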