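import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from abyssal.data_model import (
    FRAME_COLUMNS,
    RECORD_COLUMNS,
    CommunitySample,
    OccurrenceTable,
)


def make_table(rows, areas=None) -> OccurrenceTable:
    """Build a small validated occurrence table from compact row tuples.

    rows: (specimen_id, image_id, site, lat, lon, depth, morphotype_or_None,
    higher_taxon); areas: optional {image_id: area} (missing -> video frame).
    """
    rec = pd.DataFrame(
        rows,
        columns=[
            "specimen_id",
            "image_id",
            "site",
            "latitude",
            "longitude",
            "depth",
            "morphotype",
            "higher_taxon",
        ],
    )
    rec["morphotype"] = np.where(
        pd.isna(rec["morphotype"]), np.nan, rec["morphotype"]
    )
    rec["phylum"] = "Testa"
    rec["guild"] = "unknown"
    rec["id_level"] = np.where(rec["morphotype"].notna(), "morphotype", "higher_only")
    rec["taxon"] = rec["morphotype"].where(
        rec["morphotype"].notna(), rec["higher_taxon"] + " indet."
    )
    frames = (
        rec.groupby("image_id", sort=True)
        .agg(
            site=("site", "first"),
            latitude=("latitude", "first"),
            longitude=("longitude", "first"),
            depth=("depth", "first"),
        )
        .reset_index()
    )
    frames["area"] = frames["image_id"].map(areas or {})
    return OccurrenceTable(
        records=rec[RECORD_COLUMNS], frames=frames[FRAME_COLUMNS]
    ).validate()


def bd_sample(abundances, sample_id="s", depth=4100.0, **kw) -> CommunitySample:
    n = sum(abundances.values())
    defaults = dict(
        sample_id=sample_id,
        location_id="L",
        site="SITE",
        depth_bin=(np.floor(depth / 200) * 200, np.floor(depth / 200) * 200 + 200),
        mean_depth=depth,
        mean_latitude=12.0,
        mean_longitude=-140.0,
        mode="BD",
        abundances=abundances,
        n_specimens=n,
    )
    defaults.update(kw)
    return CommunitySample(**defaults)


def ss_sample(abundances, area, sample_id="s", depth=4100.0, **kw) -> CommunitySample:
    return bd_sample(abundances, sample_id=sample_id, depth=depth, mode="SS", area=area, **kw)


@pytest.fixture(scope="session")
def default_run():
    """One full default synthetic pipeline pass, shared across tests."""
    from abyssal.data_model import filter_subset
    from abyssal.survey_design import SamplingPlan, attach_environment, make_samples
    from abyssal.synthetic_data import (
        SyntheticConfig,
        generate_occurrences,
        poc_flux_model,
    )

    config = SyntheticConfig(seed=7)
    table, truth = generate_occurrences(config)
    plan = SamplingPlan(seed=7)
    bd = make_samples(filter_subset(table, "BD"), "BD", plan)
    ss = make_samples(filter_subset(table, "SS"), "SS", plan)
    poc = poc_flux_model(config)
    attach_environment(bd, poc)
    attach_environment(ss, poc)
    return {"config": config, "table": table, "truth": truth, "bd": bd, "ss": ss}
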