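"""End-to-end orchestration: simulate -> landmarks -> measure -> growth -> stats.

Every stage is a pure function of its inputs plus the config, so a rerun
with the same config produces byte-identical CSV outputs. The report
bundle records the seed, a config hash and per-stage timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .growth import (
    group_summary,
    rm_anova_orientation,
    subject_group_means,
    summarize_study,
)
from .landmarks import detect_all, load_manual_landmarks
from .morphometry import default_catalog, measure_all
from .synthetic import StudyDataset, default_growth_model, generate_study

log = logging.getLogger("mandigrow")

_FLOAT_FMT = "%.9f"


def _config_hash(config: PipelineConfig) -> str:
    as_dict = dataclasses.asdict(config)
    blob = json.dumps(as_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def detect_study_landmarks(dataset: StudyDataset) -> tuple[dict, pd.DataFrame]:
    """Auto-detect landmarks on every study mesh and merge the manual channel.

    Manual-channel rows (AMF, MMF, PMF, NO with measurement noise) are
    snapped to their mesh; rejected rows propagate as an error only if a
    set ends up incomplete.
    """
    frames = []
    sets: dict = {}
    manual_by_key: dict = {}
    for (subj, t), sub in dataset.manual.groupby(["subject", "timepoint"]):
        manual_by_key[(subj, int(t))] = sub
    for subj in dataset.subjects:
        for t in dataset.timepoints:
            mesh = dataset.mesh(subj, t)
            lset = detect_all(mesh, subject=subj, timepoint=t)
            manual = manual_by_key.get((subj, t))
            if manual is not None:
                from .mesh import nearest_point_on_surface

                pts = manual[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
                snapped, dist = nearest_point_on_surface(mesh, pts)
                for (_, row), p, d in zip(manual.iterrows(), snapped, dist):
                    if d > 1.0:
                        log.warning(
                            "manual landmark %s/%s %.2f mm off surface; rejected",
                            row["code"], row["side"], d,
                        )
                        continue
                    lset.add(row["code"], row["side"], p, "manual")
            if not lset.is_complete:
                raise RuntimeError(
                    f"incomplete landmark set for {subj} T{t} "
                    f"({len(lset.entries)}/17 landmarks)"
                )
            sets[(subj, t)] = lset
            frames.append(lset.to_frame())
    return sets, pd.concat(frames, ignore_index=True)


def measure_study(dataset: StudyDataset, sets: dict) -> pd.DataFrame:
    catalog = default_catalog()
    frames = []
    for subj in dataset.subjects:
        for t in dataset.timepoints:
            mesh = dataset.mesh(subj, t)
            frames.append(measure_all(sets[(subj, t)], mesh, catalog))
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the versioned report bundle."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(
            f"output directory {out} exists and is not empty (set overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    timings: dict = {}
    report: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": [],
    }

    def stage(name):
        log.info("stage: %s", name)
        report["stages"].append(name)
        timings[name] = time.time()

    def done(name):
        timings[name] = round(time.time() - timings[name], 2)

    stage("simulate")
    model = default_growth_model(seed=config.seed, noise_sd=config.noise_sd)
    dataset = generate_study(
        config.n_subjects, config.n_timepoints, model,
        resolution=config.resolution,
    )
    dataset.truth.to_csv(out / "landmarks_truth.csv", index=False, float_format=_FLOAT_FMT)
    done("simulate")

    stage("landmarks")
    sets, detected = detect_study_landmarks(dataset)
    detected.to_csv(out / "landmarks_detected.csv", index=False, float_format=_FLOAT_FMT)
    done("landmarks")

    stage("measure")
    measurements = measure_study(dataset, sets)
    measurements.to_csv(out / "measurements.csv", index=False, float_format=_FLOAT_FMT)
    done("measure")

    stage("growth")
    summaries = summarize_study(measurements, side=config.report.side)
    summaries.to_csv(out / "growth_summaries.csv", index=False, float_format=_FLOAT_FMT)
    done("growth")

    stage("stats")
    catalog = default_catalog()
    param_level = summaries.groupby("parameter")["normalized_total_change"].mean()
    grouping = dict(catalog.groups)
    grouping.pop("angle", None)
    groups_tbl = group_summary(param_level, grouping)
    sub_tbl = group_summary(param_level, catalog.subgroups)
    wide = subject_group_means(summaries)
    anova = rm_anova_orientation(wide, alpha=config.stats.alpha)
    stats_payload = {
        "group_means": groups_tbl.to_dict(orient="records"),
        "ap_subgroup_means": sub_tbl.to_dict(orient="records"),
        "group_order": list(
            groups_tbl.sort_values("mean", ascending=False)["group"]
        ),
        "anova": {
            "effect": anova.effect,
            "F": anova.f_statistic,
            "df": [anova.df_num, anova.df_den],
            "p": anova.p_value,
            "gg_epsilon": anova.gg_epsilon,
            "p_gg": anova.p_value_gg,
            "alpha": anova.alpha,
            "bonferroni_threshold": anova.bonferroni_threshold,
            "significant": anova.effect_significant,
            "pairwise": anova.pairwise.to_dict(orient="records"),
        },
    }
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_payload, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    done("stats")

    stage("report")
    from . import plots

    plots.plot_distances(measurements, out / "figures" / "distances.png", config.report.side)
    plots.plot_monthly_changes(measurements, out / "figures" / "monthly_changes.png", config.report.side)
    plots.plot_percent_changes(measurements, out / "figures" / "percent_changes.png", config.report.side)
    plots.plot_angles(measurements, out / "figures" / "angles.png")
    plots.plot_volume(measurements, out / "figures" / "volume.png")
    done("report")

    report["timings_s"] = timings
    report["stats"] = stats_payload
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    return report
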