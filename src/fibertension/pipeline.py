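"""Config-driven orchestration from images to tables, statistics and manifests.

``run_sample`` executes the full per-field chain — positive-pixel metrics,
fiber coherency, nucleus detection and phenotyping, proximity statistics —
and ``run_cohort`` aggregates samples into group comparisons (normality-gated
tests), the FnBPA5/TNC Pearson correlation, and a machine-readable manifest
that makes the run reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cellquant import (PhenotypeRule, auto_marker_thresholds, classify_cells,
                        detect_nuclei, measure_cells, summarize_phenotypes)
from .fiberorient import default_fiber_mask, mean_coherency, structure_tensor_field
from .groupstats import GroupSample, TestResult, compare_groups, pearson_correlation
from .io_core import AnalysisConfig, BinaryMask, MultiplexImage, full_region, write_table
from .pixelquant import ThresholdPolicy, make_mask, pixel_density, pixel_ratio, ratiometric_map
from .proximity import (cell_nearest_distances, fraction_within, proximity_profile,
                        two_stage_proximity)
from .synthgen import SyntheticSample, generate_cohort

__all__ = ["DEFAULT_RULES", "run_sample", "run_cohort", "write_cohort_outputs"]

logger = logging.getLogger("fibertension")

#: Composite phenotypes evaluated when their markers are present.
DEFAULT_RULES: dict[str, list[tuple[str, str]]] = {
    "Ki67+panCK+": [("Ki67", "+"), ("panCK", "+")],
    "GATA3+panCK+": [("GATA3", "+"), ("panCK", "+")],
    "aSMA+": [("aSMA", "+")],
    "CD45+CD8+": [("CD45", "+"), ("CD8", "+")],
    "CD4+FoxP3+": [("CD4", "+"), ("FoxP3", "+")],
}

MARKER_MIN_CONTRAST = 50.0  # a.u.; guards Otsu on all-negative markers


def run_sample(
    image: MultiplexImage,
    config: AnalysisConfig,
    region: BinaryMask | None = None,
    rules: dict[str, list[tuple[str, str]]] | None = None,
) -> dict:
    """Run the full analysis chain on one sample.

    FN + FnBPA5 (for the tension ratio) and DAPI (for cell analyses) are
    mandatory; analyses whose other channels are missing are skipped with a
    logged notice. Deterministic given the image and config.
    """
    for mandatory in ("FN", "FnBPA5", "DAPI"):
        if mandatory not in image:
            raise ValueError(f"missing mandatory channel {mandatory!r}")
    region = region or full_region(image.shape)
    rules = DEFAULT_RULES if rules is None else rules
    policy = ThresholdPolicy(mode="otsu")
    result: dict = {"sample_id": image.sample_id, "condition": image.condition_label,
                    "thresholds": {}, "parameters": config.to_dict()}

    # --- pixel metrics ------------------------------------------------------
    masks: dict[str, BinaryMask] = {}
    for marker in ("FN", "FnBPA5", "TNC", "CD34"):
        if marker not in image:
            logger.info("sample %s: channel %s absent, skipping its pixel metrics",
                        image.sample_id, marker)
            continue
        masks[marker] = make_mask(image[marker], policy, region, marker)
        from .pixelquant import otsu_threshold
        result["thresholds"][marker] = otsu_threshold(image[marker], region)
    result["fnbpa5_ratio_pct"] = pixel_ratio(masks["FnBPA5"], masks["FN"])
    result["fn_density_pct"] = pixel_density(masks["FN"], region)
    if "TNC" in masks:
        result["tnc_density_pct"] = pixel_density(masks["TNC"], region)
    if "CD34" in masks:
        result["cd34_density_pct"] = pixel_density(masks["CD34"], region)
    rmap = ratiometric_map(image["FnBPA5"], image["FN"], region, policy)
    result["ratiometric_mean"] = rmap.mean

    # --- fiber coherency ----------------------------------------------------
    if "SHG" in image:
        fiber_mask = default_fiber_mask(image["SHG"], region)
        field = structure_tensor_field(image["SHG"], window_sigma=4.0)
        result["mean_coherency"] = mean_coherency(field, fiber_mask)
        result["fiber_mask_density_pct"] = pixel_density(fiber_mask, region)
    else:
        logger.info("sample %s: SHG absent, skipping coherency", image.sample_id)

    # --- cells --------------------------------------------------------------
    table = detect_nuclei(image["DAPI"], region, config.pixel_size,
                          min_area_um2=12.0, max_area_um2=400.0)
    result["total_cells"] = table.total_cells
    if table.total_cells:
        table = measure_cells(table, image, ring_width_um=config.ring_width)
        usable_rules = {name: req for name, req in rules.items()
                        if all(m in image for m, _ in req)}
        markers_needed = sorted({m for req in usable_rules.values() for m, _ in req})
        thresholds = auto_marker_thresholds(table, markers_needed,
                                            min_contrast=MARKER_MIN_CONTRAST)
        thresholds.update({m: float(v) for m, v in config.thresholds.items()
                           if isinstance(v, (int, float))})
        result["thresholds"].update({f"cell_{m}": thresholds[m] for m in markers_needed})
        rule_objs = [PhenotypeRule(name, [(m, thresholds[m], s) for m, s in req])
                     for name, req in usable_rules.items()]
        table = classify_cells(table, rule_objs)
        summary = summarize_phenotypes(table)
        result["phenotypes"] = {
            row["phenotype"]: {"percentage": row["percentage"], "n_cells": int(row["n_cells"]),
                               "mean_area_um2": row["mean_area_um2"]}
            for _, row in summary.iterrows()}
        result["mean_nucleus_area_um2"] = float(table.areas_um2().mean())

        # --- proximity to untensed fibers ----------------------------------
        if masks["FnBPA5"].positive_count:
            distances = cell_nearest_distances(table, masks["FnBPA5"], config.pixel_size)
            result["proximity"] = {}
            for name, flags in table.phenotype_flags.items():
                if not flags.any():
                    continue
                prof = proximity_profile(distances, flags, config.bin_width,
                                         config.max_profile_distance)
                result["proximity"][name] = {
                    "n_cells": prof.n_cells,
                    "fraction_within_pct": fraction_within(distances, flags,
                                                           config.within_radius),
                    "bins_pct": prof.fraction_per_bin.tolist(),
                    "overflow_pct": prof.overflow_fraction,
                }
            if "CD34" in masks and masks["CD34"].positive_count \
                    and "aSMA+" in table.phenotype_flags:
                mean_d, d_list = two_stage_proximity(
                    table, masks["FnBPA5"], masks["CD34"], config.pixel_size,
                    flags=table.phenotype_flags["aSMA+"], radius=config.within_radius)
                result["two_stage"] = {"n_selected": int(d_list.size),
                                       "mean_distance_um": mean_d}
    result["cell_table"] = table
    return result


def _sample_row(result: dict) -> dict:
    row = {k: result.get(k) for k in
           ("sample_id", "condition", "fnbpa5_ratio_pct", "tnc_density_pct",
            "cd34_density_pct", "fn_density_pct", "mean_coherency",
            "total_cells", "mean_nucleus_area_um2", "ratiometric_mean")}
    for name, ph in result.get("phenotypes", {}).items():
        row[f"pct_{name}"] = ph["percentage"]
    for name, pr in result.get("proximity", {}).items():
        row[f"within10_{name}"] = pr["fraction_within_pct"]
    if "two_stage" in result:
        row["two_stage_mean_um"] = result["two_stage"]["mean_distance_um"]
    return row


def run_cohort(
    samples: list[SyntheticSample | MultiplexImage] | dict[str, int],
    config: AnalysisConfig,
    base_seed: int | None = None,
    shape: tuple[int, int] = (1024, 1024),
) -> dict:
    """Analyze a cohort and compare conditions.

    ``samples`` may be pre-generated samples/images or a generate-spec
    ``{condition: n}`` (then ``base_seed`` seeds the generator). Returns a
    dict with the per-sample table, per-metric group comparisons, the
    FnBPA5-vs-TNC Pearson correlation, and a run manifest.
    """
    if isinstance(samples, dict):
        seed = config.seed if base_seed is None else base_seed
        samples = generate_cohort(samples, base_seed=seed, shape=shape,
                                  pixel_size=config.pixel_size)
    results = []
    for s in samples:
        image = s.image if isinstance(s, SyntheticSample) else s
        results.append(run_sample(image, config))
    table = pd.DataFrame([_sample_row(r) for r in results])

    comparisons: dict[str, TestResult] = {}
    groups_present = [g for g in table["condition"].unique()]
    if len(groups_present) >= 2:
        for metric in ("fnbpa5_ratio_pct", "tnc_density_pct", "mean_coherency"):
            if metric not in table or table[metric].isna().all():
                continue
            groups = [GroupSample(g, table.loc[table["condition"] == g, metric].dropna().values)
                      for g in groups_present]
            groups = [g for g in groups if g.values.size >= 2]
            if len(groups) >= 2:
                comparisons[metric] = compare_groups(groups)
    else:
        logger.info("cohort has <2 groups; group statistics skipped")

    correlation = None
    if "tnc_density_pct" in table and table["tnc_density_pct"].notna().sum() >= 3:
        sub = table.dropna(subset=["fnbpa5_ratio_pct", "tnc_density_pct"])
        if len(sub) >= 3 and sub["fnbpa5_ratio_pct"].nunique() > 1 \
                and sub["tnc_density_pct"].nunique() > 1:
            correlation = pearson_correlation(sub["fnbpa5_ratio_pct"].values,
                                              sub["tnc_density_pct"].values)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_samples": len(results),
        "sample_ids": [r["sample_id"] for r in results],
        "conditions": table["condition"].tolist(),
    }
    return {"samples": results, "table": table, "comparisons": comparisons,
            "correlation": correlation, "manifest": manifest}


def write_cohort_outputs(cohort: dict, out_dir: str | Path) -> None:
    """Write per-sample CSV, stats CSV and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(cohort["table"], out / "samples.csv")
    rows = []
    for metric, res in cohort["comparisons"].items():
        rows.append({"comparison": metric, "test": res.test_name,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "posthoc": json.dumps([[list(pair), p] for pair, p in res.posthoc])
                     if res.posthoc else ""})
    if cohort["correlation"] is not None:
        c = cohort["correlation"]
        rows.append({"comparison": "fnbpa5_vs_tnc", "test": c.test_name,
                     "statistic": c.r, "p_value": c.p_value, "posthoc": ""})
    write_table(pd.DataFrame(rows), out / "stats.csv")
    (out / "manifest.json").write_text(json.dumps(cohort["manifest"], indent=2, sort_keys=True))
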