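"""End-to-end orchestration: cohort -> connectomes -> measures -> contrasts.

The pipeline runs the complete analysis on a synthetic (or precomputed)
cohort: estimate per subject/run connectomes, compute the five network
statistics and Compression Flow, detect modules, contrast runs with
non-parametric tests, and filter significantly changed edges.  Every stage
writes a delimited-text table to the output directory and a manifest records
the seed, the configuration echo and per-stage row counts so each table is
re-derivable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .compression_flow import compression_flow
from .connectome import build_connectome, read_connectome, write_connectome
from .edge_filtering import edge_anova, percentile_filter, report_frame
from .group_stats import run_contrast_suite, wilcoxon_paired
from .metrics import MEASURES, compute_statistics, statistics_table
from .modularity import cohort_module_counts
from .synthetic import CohortSpec, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    input_mode: str = "synthetic"  # synthetic | precomputed_timeseries
    cohort_spec: Optional[CohortSpec] = None
    input_dir: Optional[str] = None
    atlas_name: Optional[str] = None
    fdr_q: float = 0.05
    pivot_percentile: float = 10.0
    modularity_backend: str = "greedy_modularity"
    out_dir: str = "results/pipeline"
    seed: int = 0
    make_plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.input_mode not in ("synthetic", "precomputed_timeseries"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "synthetic" and self.cohort_spec is None:
            self.cohort_spec = CohortSpec(seed=self.seed)


def _load_series(config: RunConfig):
    if config.input_mode == "synthetic":
        return generate_cohort(config.cohort_spec)
    directory = Path(config.input_dir or "")
    if not directory.is_dir():
        raise FileNotFoundError(f"input directory not found: {directory}")
    return read_cohort(directory)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return the manifest dictionary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": {},
        "warnings": [],
    }
    rng = np.random.default_rng(config.seed)

    t0 = time.perf_counter()
    cohort = _load_series(config)
    manifest["stages"]["cohort"] = {"n_series": len(cohort), "seconds": round(time.perf_counter() - t0, 3)}

    t0 = time.perf_counter()
    connectomes = []
    for ts in cohort:
        conn = build_connectome(ts, q=config.fdr_q, atlas_name=config.atlas_name)
        connectomes.append(conn)
    manifest["stages"]["connectomes"] = {
        "n": len(connectomes), "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = time.perf_counter()
    records = [compute_statistics(c) for c in connectomes]
    stats_df = statistics_table(records)
    stats_df.to_csv(out / "statistics.csv", index=False)
    manifest["stages"]["statistics"] = {
        "rows": len(stats_df), "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = time.perf_counter()
    cf_rows = []
    for conn in connectomes:
        cf_seed = int(rng.integers(0, 2**31 - 1))
        res = compression_flow(conn, pivot_percentile=config.pivot_percentile, seed=cf_seed)
        cf_rows.append(
            {
                "subject_id": conn.meta.get("subject_id"),
                "run": conn.meta.get("run"),
                "condition": conn.meta.get("condition"),
                "cf": res.cf,
                "k": len(res.peripheral_set),
                "seed": cf_seed,
            }
        )
    cf_df = pd.DataFrame(cf_rows)
    cf_df.to_csv(out / "cf.csv", index=False)
    manifest["stages"]["compression_flow"] = {
        "rows": len(cf_df), "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = time.perf_counter()
    modules_df = cohort_module_counts(connectomes, backend=config.modularity_backend, seed=config.seed)
    modules_df.to_csv(out / "modules.csv", index=False)
    manifest["stages"]["modularity"] = {
        "rows": len(modules_df), "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = time.perf_counter()
    contrasts = run_contrast_suite(stats_df)
    extra = []
    for name, df, col in (("compression_flow", cf_df, "cf"), ("n_modules", modules_df, "n_modules")):
        wide = df.pivot_table(index="subject_id", columns="run", values=col).dropna()
        rep = wilcoxon_paired(wide[1].to_numpy(), wide[2].to_numpy(), n_hypotheses=1, measure=name)
        extra.append(
            {
                "measure": name, "n_pairs": rep.n, "statistic": rep.statistic,
                "p_raw": rep.p_raw, "p_corrected": rep.p_corrected,
                "direction": rep.direction, "significant": rep.significant,
                "excluded_subjects": "",
            }
        )
    contrasts = pd.concat([contrasts, pd.DataFrame(extra)], ignore_index=True)
    contrasts.to_csv(out / "contrasts.csv", index=False)
    manifest["stages"]["contrasts"] = {
        "rows": len(contrasts), "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = time.perf_counter()
    run1 = [c for c in connectomes if c.meta.get("run") == 1]
    run2 = [c for c in connectomes if c.meta.get("run") == 2]
    edge_report = percentile_filter(edge_anova(run1, run2))
    report_frame(edge_report).to_csv(out / "edge_report.csv", index=False)
    manifest["stages"]["edge_filtering"] = {
        "rows": len(edge_report.table),
        "selected_positive": len(edge_report.selected_positive),
        "selected_negative": len(edge_report.selected_negative),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    if config.make_plots:
        from .plots import box_whisker

        for measure in MEASURES:
            sub = stats_df[stats_df["measure"] == measure]
            groups = [sub[sub["run"] == r]["value"].to_numpy() for r in (1, 2)]
            box_whisker(groups, ["run 1", "run 2"], out / "plots" / f"{measure}.png", title=measure)
        groups = [cf_df[cf_df["run"] == r]["cf"].to_numpy() for r in (1, 2)]
        box_whisker(groups, ["run 1", "run 2"], out / "plots" / "compression_flow.png",
                    title="compression flow")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    spec = echo.get("cohort_spec")
    if spec is not None:
        echo["cohort_spec"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in spec.items()}
    return echo
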