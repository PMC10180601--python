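"""End-to-end pipeline: chronologies -> climate indices -> stress years
-> climate-growth correlations -> resilience indices.

Each stage writes its outputs (CSV/JSON) into the configured directory
and a run log records package versions, the seed and every analysis
parameter, so a run is reproducible from the log alone.
"""

from __future__ import annotations

import json
import logging
import platform
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .climate import ClimateIndexTable, climate_index_table, detect_stress_years
from .climgrowth import correlation_function, results_to_frame
from .config import RunConfig
from .detrend import GrowthIndexChronology, build_gic
from .resilience import (
    StressEvent,
    anova_tukey,
    indices_for_forest,
    kruskal_dunn,
    species_summary,
)
from .ringwidth import RawChronology, TreeSeries, average_cores, build_rgc
from .rwl import read_daily_climate, read_rwl

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "build_trees"]


@dataclass
class PipelineResult:
    trees: dict[str, list[TreeSeries]]
    rgc: dict[str, RawChronology]
    gic: dict[str, GrowthIndexChronology]
    climate_table: ClimateIndexTable
    stress_years: list
    correlations: dict[str, pd.DataFrame]
    resilience_tables: dict[int, pd.DataFrame]
    group_tests: dict = field(default_factory=dict)
    output_dir: Path | None = None


def build_trees(cores, species: list[str] | None = None) -> dict[str, list[TreeSeries]]:
    """Group cores by tree, average them, and bucket trees by species."""
    by_tree = defaultdict(list)
    for core in cores:
        by_tree[core.tree_id].append(core)
    forests: dict[str, list[TreeSeries]] = defaultdict(list)
    for tree_cores in by_tree.values():
        tree = average_cores(tree_cores)
        if species is None or tree.species in species:
            forests[tree.species].append(tree)
    return dict(forests)


def _auto_stress_events(reports) -> list[int]:
    """Years flagged by both primary criteria or by the SPEI confirmation."""
    return sorted(
        r.year for r in reports
        if (r.primary_hot and r.primary_dry) or r.confirmations.get("spei3", False)
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("pipeline stage: %s", name)

    # --- chronology stage -------------------------------------------------
    stage("chronology")
    try:
        cores = read_rwl(config.rwl_path)
        forests = build_trees(cores, config.species)
        if not forests:
            raise ValueError("no trees after species filtering")
        rgcs, gics = {}, {}
        for species, trees in sorted(forests.items()):
            rgc = build_rgc(trees, min_depth=config.min_depth)
            gic = build_gic(
                trees,
                cutoff_fraction=config.spline_cutoff_fraction,
                amplitude=config.spline_amplitude,
                min_depth=config.min_depth,
                biweight_c=config.biweight_c,
            )
            rgcs[species], gics[species] = rgc, gic
            rgc.to_frame().to_csv(out / f"rgc_{species}.csv", index_label="year")
            gic.to_frame().to_csv(out / f"gic_{species}.csv", index_label="year")
            with open(out / f"stats_{species}.json", "w") as fh:
                json.dump({
                    "species": species,
                    "n_trees": len(trees),
                    "span": [int(gic.values.index.min()), int(gic.values.index.max())],
                    "ar1": rgc.ar1,
                    "rbar": gic.rbar,
                    "eps": gic.eps,
                    "mean_depth": gic.mean_depth,
                }, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'chronology' failed: {exc}") from exc

    # --- climate stage ----------------------------------------------------
    stage("climate")
    try:
        daily = read_daily_climate(config.climate_path)
        data_years = np.unique(daily.index.year)
        start = config.study_start or int(data_years.min())
        end = config.study_end or int(data_years.max())
        years = np.arange(start, end + 1)
        calibration = tuple(config.spei_calibration) if config.spei_calibration else None
        table = climate_index_table(
            daily, years,
            latitude=config.latitude,
            spei_scale=config.spei_scale,
            spei_calibration=calibration,
            tolerance=config.missing_tolerance,
        )
        table.to_long().to_csv(out / "climate_indices.csv", index=False)
        if table.spei_series is not None:
            spei_df = table.spei_series.data.copy()
            spei_df["class"] = [
                "none" if not np.isfinite(v) else
                ("extreme" if v <= -2 else "severe" if v <= -1.5 else
                 "moderate" if v <= -1 else "none")
                for v in spei_df["spei"]
            ]
            spei_df.to_csv(out / "spei.csv", index_label="month")
        reports = detect_stress_years(table, years)
        with open(out / "stress_years.json", "w") as fh:
            json.dump([{
                "year": r.year, "is_stress": r.is_stress,
                "primary_hot": r.primary_hot, "primary_dry": r.primary_dry,
                "tmean_vp": r.tmean_vp, "ppt_vp": r.ppt_vp,
                "spei_vp": None if not np.isfinite(r.spei_vp) else r.spei_vp,
                "confirmations": r.confirmations,
                "drought_class_by_month": r.drought_class_by_month,
            } for r in reports], fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'climate' failed: {exc}") from exc

    # --- correlation stage --------------------------------------------------
    stage("correlate")
    try:
        correlations = {}
        for species, gic in sorted(gics.items()):
            results = correlation_function(
                gic, table, n_boot=config.n_boot, ci=config.ci, seed=config.seed,
            )
            frame = results_to_frame(results)
            frame.insert(0, "species", species)
            correlations[species] = frame
        pd.concat(correlations.values()).to_csv(out / "correlations.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'correlate' failed: {exc}") from exc

    # --- resilience stage ---------------------------------------------------
    stage("resilience")
    try:
        if config.stress_events == "auto":
            event_years = _auto_stress_events(reports)
        else:
            event_years = list(config.stress_events)
        events = [StressEvent(year=y, window=w)
                  for w in config.window_widths for y in event_years]
        all_trees = [t for trees in forests.values() for t in trees]
        indices = indices_for_forest(all_trees, events)
        resilience_tables = {}
        for w in config.window_widths:
            summaries = species_summary([r for r in indices if r.window == w])
            rows = []
            for s in summaries:
                for index_name in ("Rs", "Rc", "Rl"):
                    row = {"species": s.species, "index": index_name, "window": w}
                    row.update({int(y): v for y, v in s.per_event[index_name].items()})
                    row["avg_of_event_medians"] = s.average_of_medians[index_name]
                    row["pooled_median"] = s.pooled_median[index_name]
                    rows.append(row)
            frame = pd.DataFrame(rows)
            frame.to_csv(out / f"resilience_w{w}.csv", index=False)
            resilience_tables[w] = frame

        group_tests = {"kruskal_dunn": {}, "anova_tukey": {}}
        for w in config.window_widths:
            for index_name, attr in (("Rs", "resistance"), ("Rc", "recovery"),
                                     ("Rl", "resilience")):
                grouped = defaultdict(list)
                for r in indices:
                    if r.window == w:
                        grouped[r.species].append(getattr(r, attr))
                if len(grouped) >= 2 and all(len(v) >= 2 for v in grouped.values()):
                    group_tests["kruskal_dunn"][f"{index_name}_w{w}"] = kruskal_dunn(
                        {k: np.array(v) for k, v in grouped.items()}, alpha=config.alpha
                    )
        growth_groups = {
            species: np.array([t.widths.mean() for t in trees])
            for species, trees in forests.items()
        }
        if len(growth_groups) >= 2:
            group_tests["anova_tukey"]["mean_radial_growth"] = anova_tukey(
                growth_groups, alpha=config.alpha
            )
        with open(out / "group_tests.json", "w") as fh:
            json.dump(group_tests, fh, indent=2, default=str)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'resilience' failed: {exc}") from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump({
            "dendrostress_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "stress_event_years": event_years,
            "config": config.to_dict(),
        }, fh, indent=2)

    return PipelineResult(
        trees=forests, rgc=rgcs, gic=gics, climate_table=table,
        stress_years=reports, correlations=correlations,
        resilience_tables=resilience_tables, group_tests=group_tests,
        output_dir=out,
    )
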