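"""End-to-end orchestration: occurrences -> samples -> metrics -> reports.

A single :func:`run` executes the full analysis chain on either a user
occurrence CSV or a synthetic dataset: subset filtering, grid/bin
rarefaction into BD and SS samples, POC-flux attachment, diversity and
density metrics, Bray-Curtis + NMDS ordination, AICc gradient fits,
and the zonation reports. All artifacts are plain CSV/JSON under one
output directory, listed (with SHA-256 digests) in a run manifest so a
fixed seed reproduces identical content.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beta_diversity import bray_curtis, nmds, ordination_report
from .data_model import (
    filter_subset,
    read_occurrences,
    taxon_groups,
    write_samples,
)
from .diversity import accumulation_curve, diversity_table, province_summary
from .gradients import correlation_screen, select_model
from .survey_design import SamplingPlan, attach_environment, make_samples
from .synthetic_data import SyntheticConfig, generate_occurrences, poc_flux_model
from .zonation import (
    ProvinceScheme,
    boundary_sweep,
    classify_province,
    dominance,
    overlap_counts,
    ridgeline,
)

__all__ = ["RunConfig", "run"]

log = logging.getLogger("abyssal")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (exactly one input source)."""

    input_path: str | None = None
    synth: SyntheticConfig | None = None
    plan: SamplingPlan = field(default_factory=SamplingPlan)
    scheme: ProvinceScheme = field(default_factory=ProvinceScheme)
    out_dir: str = "abyssal_run"
    seed: int = 0
    nmds_restarts: int = 8
    nmds_max_iter: int = 200
    n_randomizations: int = 100
    run_diversity: bool = True
    run_beta: bool = True
    run_gradients: bool = True
    run_zonation: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synth is None):
            raise ValueError("exactly one of input_path / synth must be set")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "zonation").mkdir(exist_ok=True)
    artifacts: list[Path] = []
    counts: dict[str, int] = {}

    def stage(name):
        log.info("stage %-14s +%.1fs", name, time.time() - t0)

    stage("input")
    if config.synth is not None:
        table, truth = generate_occurrences(config.synth, seed=config.seed)
        poc = poc_flux_model(config.synth)
    else:
        p = Path(config.input_path)
        if not p.exists():
            raise FileNotFoundError(f"input occurrence file not found: {p}")
        table = read_occurrences(p)
        truth = None
        poc = None
    counts["records"] = len(table)

    stage("survey")
    plan = SamplingPlan(
        cell_size_km=config.plan.cell_size_km,
        depth_bin_width_m=config.plan.depth_bin_width_m,
        bd_size=config.plan.bd_size,
        ss_min=config.plan.ss_min,
        ss_max=config.plan.ss_max,
        seed=config.seed,
    )
    bd = make_samples(filter_subset(table, "BD"), "BD", plan)
    ss = make_samples(filter_subset(table, "SS"), "SS", plan)
    if poc is not None:
        attach_environment(bd, poc)
        attach_environment(ss, poc)
    counts["bd_samples"] = len(bd)
    counts["ss_samples"] = len(ss)
    write_samples(bd, out / "samples_bd.csv")
    write_samples(ss, out / "samples_ss.csv")
    artifacts += [out / "samples_bd.csv", out / "samples_ss.csv"]

    metrics = None
    if config.run_diversity:
        stage("diversity")
        metrics = pd.concat(
            [diversity_table(bd), diversity_table(ss)], ignore_index=True
        )
        metrics["province"] = [
            classify_province(d, config.scheme) for d in metrics["mean_depth"]
        ]
        metrics.to_csv(out / "metrics.csv", index=False)
        artifacts.append(out / "metrics.csv")

        summaries = []
        bdm = metrics[metrics["mode"] == "BD"]
        ssm = metrics[metrics["mode"] == "SS"]
        for name, sub in (
            ("richness_s", bdm),
            ("exp_shannon", bdm),
            ("density", ssm),
        ):
            if len(sub):
                summaries += province_summary(
                    sub[name].to_numpy(), sub["province"].to_numpy(), metric=name
                )
        pd.DataFrame([vars(s) for s in summaries]).to_csv(
            out / "province_summaries.csv", index=False
        )
        artifacts.append(out / "province_summaries.csv")

        rows = []
        for prov in ("shallow", "transition", "deep"):
            subset = [
                s for s in bd if classify_province(s.mean_depth, config.scheme) == prov
            ]
            if not subset:
                continue
            curve = accumulation_curve(
                subset, n_randomizations=config.n_randomizations, seed=config.seed
            )
            for i in range(len(curve.n_samples)):
                rows.append(
                    {
                        "province": prov,
                        "n_samples": int(curve.n_samples[i]),
                        "mean_richness": curve.mean_richness[i],
                        "ci_low": curve.ci_low[i],
                        "ci_high": curve.ci_high[i],
                    }
                )
        pd.DataFrame(rows).to_csv(out / "accumulation.csv", index=False)
        artifacts.append(out / "accumulation.csv")

    dmat = None
    if config.run_beta and len(bd) >= 3:
        stage("beta")
        dmat = bray_curtis(bd, transform="sqrt")
        pd.DataFrame(
            dmat.values, index=dmat.sample_ids, columns=dmat.sample_ids
        ).to_csv(out / "bray_curtis.csv")
        artifacts.append(out / "bray_curtis.csv")
        ordination = nmds(
            dmat,
            k=2,
            n_restarts=config.nmds_restarts,
            max_iter=config.nmds_max_iter,
            seed=config.seed,
        )
        report = ordination_report(ordination, bd, config.scheme)
        report.insert(1, "stress", ordination.stress)
        report.to_csv(out / "ordination.csv", index=False)
        artifacts.append(out / "ordination.csv")
        counts["nmds_restarts"] = ordination.n_restarts

    if config.run_gradients and metrics is not None:
        stage("gradients")
        fits = []
        predictors = ["mean_depth"] + (
            ["poc_flux"] if metrics["poc_flux"].notna().all() else []
        )
        for name, mode in (
            ("richness_s", "BD"),
            ("exp_shannon", "BD"),
            ("density", "SS"),
        ):
            sub = metrics[metrics["mode"] == mode]
            if name not in sub or len(sub) < 3:
                continue
            for pred in predictors:
                best, ranking = select_model(
                    sub[name].to_numpy(),
                    sub[pred].to_numpy(),
                    metric=name,
                    predictor=pred,
                )
                for _, r in ranking.iterrows():
                    fits.append(
                        {
                            "metric": name,
                            "predictor": pred,
                            "family": r["family"],
                            "aicc": r["aicc"],
                            "delta_aicc": r["delta_aicc"],
                            "selected": r["family"] == best.family,
                            "slope": best.slope if r["family"] == best.family else np.nan,
                            "intercept": best.intercept
                            if r["family"] == best.family
                            else np.nan,
                            "f_statistic": best.f_statistic
                            if r["family"] == best.family
                            else np.nan,
                            "p_value": best.p_value
                            if r["family"] == best.family
                            else np.nan,
                            "r_squared": best.r_squared
                            if r["family"] == best.family
                            else np.nan,
                            "n": best.n,
                        }
                    )
        pd.DataFrame(fits).to_csv(out / "fits.csv", index=False)
        artifacts.append(out / "fits.csv")
        env = metrics.rename(columns={"mean_depth": "depth", "mean_latitude": "latitude", "mean_longitude": "longitude"})
        screen = correlation_screen(env)
        screen.matrix.to_csv(out / "correlation_screen.csv")
        artifacts.append(out / "correlation_screen.csv")

    if config.run_zonation:
        stage("zonation")
        over = overlap_counts(bd, config.scheme)
        rows = [
            {"province": p, **v} for p, v in over.per_province.items()
        ]
        rows.append(
            {
                "province": "shallow&deep",
                "total": over.shared_shallow_deep,
                "exclusive": np.nan,
                "rare_exclusive": over.shared_shallow_deep_rare,
            }
        )
        pd.DataFrame(rows).to_csv(out / "zonation" / "overlap.csv", index=False)
        artifacts.append(out / "zonation" / "overlap.csv")

        groups = taxon_groups(table).set_index("taxon")["higher_taxon"].to_dict()
        dom_rows = []
        for level, k in (("morphotype", 10), ("group", 4)):
            dom = dominance(bd, level=level, k=k, scheme=config.scheme, groups=groups)
            for prov, tab in dom.tables.items():
                t = tab.copy()
                t.insert(0, "province", prov)
                t.insert(0, "level", level)
                t["topk_share"] = dom.topk_share[prov]
                dom_rows.append(t)
        pd.concat(dom_rows, ignore_index=True).to_csv(
            out / "zonation" / "dominance.csv", index=False
        )
        artifacts.append(out / "zonation" / "dominance.csv")

        ridge_rows = []
        for r in ridgeline(table):
            for e, f in zip(r.bin_edges[:-1], r.frequencies):
                ridge_rows.append(
                    {"group": r.group, "bin_low": e, "frequency": f}
                )
        pd.DataFrame(ridge_rows).to_csv(out / "zonation" / "ridgeline.csv", index=False)
        artifacts.append(out / "zonation" / "ridgeline.csv")

        if dmat is not None:
            sweep = boundary_sweep(bd, dmat)
            sweep.to_csv(out / "zonation" / "boundary_sweep.csv", index=False)
            artifacts.append(out / "zonation" / "boundary_sweep.csv")

    stage("manifest")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "input": config.input_path or f"synthetic(seed={config.seed})",
        "counts": counts,
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in artifacts
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
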