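"""End-to-end orchestration: phantom -> thresholds -> segmentation ->
centerline -> cross-section measurement -> summaries, plus the cohort-level
statistical tables.  Every stage writes its artifact to the run directory
and the run manifest records config, versions and seed, so a run is exactly
reproducible from the manifest alone."""

from __future__ import annotations

import dataclasses
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centerline import define_segments, extract_centerline
from .cohort import Cohort, CohortSpec, generate_cohort
from .fuzzyconn import SeedSet, fuzzy_connectedness_segment
from .measure import profile_segment, summarize_segment
from .phantom import default_seed_points, generate_phantom, renal_phantom
from .stats import agreement, roc_auc
from .summarize import (
    APPROACHES,
    filter_cohort,
    measurability_stats,
    records_from_cohort,
    summarize_kidney,
)
from .thresholds import RoiSet, ThresholdSet, default_phantom_rois, estimate_thresholds
from .volume import ImageVolume

MEASURE_DIRECTIONS = {
    "min_d_mm": "lower",
    "min_a_mm2": "lower",
    "dred_pct": "higher",
    "ared_pct": "higher",
}


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    The fixed study constants keep their established values by default:
    curvature scale 10 for the cross-section contour smoothing, and the
    reference-position rules of 10 mm from the aorta and 5 mm around
    bifurcations.
    """

    modality: str = "CTA"
    dred_pct: float = 50.0
    noise_sd: float = 0.0
    step_mm: float = 0.5
    inplane_step_mm: float = 0.2
    curvature_scale: float = 10.0
    min_aorta_distance_mm: float = 10.0
    bifurcation_margin_mm: float = 5.0
    approaches: tuple[str, ...] = APPROACHES
    merge_mode: str = "recompute"
    auc_ci_method: str = "delong"
    seed: int = 0
    out_dir: str = "stenoquant_run"
    volume_path: str | None = None  # analyse an existing volume instead of a phantom
    ut_override: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("CTA", "MRA"):
            raise ValueError("modality must be CTA or MRA")
        for name in ("step_mm", "inplane_step_mm", "min_aorta_distance_mm", "bifurcation_margin_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        payload.pop("approaches", None) or payload.update(
            {}
        )  # tuples from YAML arrive as lists
        cfg = cls(**{k: v for k, v in payload.items() if k in {f.name for f in dataclasses.fields(cls)}})
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def validate_inputs(
    volume: ImageVolume,
    rois: RoiSet | None = None,
    seeds: SeedSet | None = None,
) -> list[str]:
    """Consistency checks before any computation; returns failure messages."""
    failures: list[str] = []
    extent = volume.extent_mm
    if rois is not None:
        for i, roi in enumerate(rois.rois):
            if not 0 <= roi.slice_index < volume.shape[0]:
                failures.append(f"ROI {i}: slice {roi.slice_index} outside the volume")
            cy, cx = roi.center_yx_mm
            if not (0 <= cy <= extent[1] and 0 <= cx <= extent[2]):
                failures.append(f"ROI {i}: centre ({cy}, {cx}) mm outside the volume extent")
    if seeds is not None:
        for label, pos in seeds.seeds:
            rel = np.asarray(pos) - np.asarray(volume.origin)
            if np.any(rel < 0) or np.any(rel > extent):
                failures.append(
                    f"seed label {label} at {tuple(pos)} mm exceeds the physical extent "
                    f"{tuple(np.round(extent, 1))} mm (mm/voxel mix-up?)"
                )
    return failures


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns artifact paths and in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: dict = {"out_dir": str(out)}

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise StageError(f"[{name}] {exc}") from exc

        return wrap

    # ---------------------------------------------------------------- phantom / input
    def _phantom():
        if config.volume_path:
            return ImageVolume.load(config.volume_path), None, None
        spec = renal_phantom(
            modality=config.modality,
            dred_pct=config.dred_pct,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        volume, truth = generate_phantom(spec)
        volume.save(str(out / "volume.nii.gz"))
        truth.to_json(str(out / "truth.json"))
        return volume, truth, spec

    volume, truth, spec = stage("phantom")(_phantom)
    result["truth"] = truth

    # ---------------------------------------------------------------- thresholds
    def _thresholds():
        if spec is None:
            raise ValueError("threshold ROIs for external volumes must be supplied via the CLI")
        aorta_rois, bg_rois = default_phantom_rois(spec, volume)
        failures = validate_inputs(volume, rois=aorta_rois)
        if failures:
            raise ValueError("; ".join(failures))
        ts = estimate_thresholds(volume, aorta_rois, bg_rois, modality=config.modality)
        if config.modality == "MRA" and config.ut_override is not None:
            warnings.warn("an upper threshold is undefined for MRA; ignoring the override")
        elif config.ut_override is not None:
            ts = ThresholdSet(ts.aorta_value, ts.background_value, ts.lt, config.ut_override, ts.provenance)
        ts.to_json(str(out / "thresholds.json"))
        return ts

    thresholds = stage("thresholds")(_thresholds)
    result["thresholds"] = thresholds

    # ---------------------------------------------------------------- segmentation
    def _segment():
        seeds = SeedSet(default_seed_points(spec))
        failures = validate_inputs(volume, seeds=seeds)
        if failures:
            raise ValueError("; ".join(failures))
        labels = fuzzy_connectedness_segment(volume, seeds, thresholds)
        labels.save(str(out / "labels.nii.gz"))
        return labels, seeds

    labels, seeds = stage("segment")(_segment)
    result["labels"] = labels

    # ---------------------------------------------------------------- centerline + segments
    def _centerline():
        root_hint = tuple(spec.arteries[0].path_mm[0])
        tree = extract_centerline(labels, root_hint_mm=root_hint, label=2)
        tree.to_json(str(out / "centerline.json"))
        return define_segments(tree, artery_id=1)

    segments = stage("centerline")(_centerline)
    result["segments"] = segments

    # ---------------------------------------------------------------- measurement
    def _measure():
        profiles, summaries, prof_rows, sum_rows = [], [], [], []
        for seg in segments:
            profile = profile_segment(
                volume,
                seg,
                thresholds,
                step_mm=config.step_mm,
                inplane_step_mm=config.inplane_step_mm,
                curvature_scale=config.curvature_scale,
                min_aorta_distance_mm=config.min_aorta_distance_mm,
                bifurcation_margin_mm=config.bifurcation_margin_mm,
            )
            summary = summarize_segment(profile)
            profiles.append(profile)
            summaries.append(summary)
            for c in profile.cross_sections:
                prof_rows.append(
                    {
                        "artery": seg.artery_id,
                        "segment": seg.index,
                        "arc_mm": c.arc_length,
                        "area_mm2": c.area_mm2,
                        "shortest_diameter_mm": c.shortest_diameter_mm,
                        "eligible_for_max": c.eligible_for_max,
                        "valid": c.valid,
                    }
                )
            sum_rows.append(
                {
                    "artery": seg.artery_id,
                    "segment": seg.index,
                    "min_d_mm": summary.min_d_mm,
                    "min_a_mm2": summary.min_a_mm2,
                    "max_d_mm": summary.max_d_mm,
                    "max_a_mm2": summary.max_a_mm2,
                    "dred_pct": summary.dred_pct,
                    "ared_pct": summary.ared_pct,
                    "fallback_used": summary.fallback_used,
                    "measurable": summary.measurable,
                }
            )
        pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False, float_format="%.6g")
        pd.DataFrame(sum_rows).to_csv(out / "summaries.csv", index=False, float_format="%.6g")
        return profiles, summaries

    profiles, summaries = stage("measure")(_measure)
    result["profiles"] = profiles
    result["summaries"] = summaries

    # ---------------------------------------------------------------- manifest
    manifest = {
        "config": config.to_dict(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result["manifest"] = manifest
    return result


# --------------------------------------------------------------------------- cohort statistics
def cohort_statistics(
    cohort: Cohort, merge_mode: str = "recompute", auc_ci_method: str = "delong"
) -> dict[str, pd.DataFrame]:
    """Tidy statistical tables for a cohort: measurability accounting,
    inter-observer and inter-method agreement, and AUROC of every measure
    against the binary functional reference."""
    records = records_from_cohort(cohort)
    analysis, accounting = filter_cohort(records)
    tables: dict[str, pd.DataFrame] = {
        "accounting": accounting,
        "measurability": measurability_stats(cohort.measurements),
    }

    # inter-observer agreement at vessel level (both readers measured)
    rows = []
    meas = cohort.measurements
    for (modality, segment), grp in meas.groupby(["modality", "segment"]):
        wide = grp.pivot_table(
            index=["kidney", "artery"],
            columns="reader",
            values=["min_d_mm", "min_a_mm2", "dred_pct", "ared_pct"],
        ).dropna()
        if len(wide) < 3:
            continue
        for measure in ("min_d_mm", "min_a_mm2", "dred_pct", "ared_pct"):
            res = agreement(wide[(measure, 1)], wide[(measure, 2)])
            rows.append(
                {
                    "modality": modality,
                    "segment": segment,
                    "measure": measure,
                    "mean_difference": res.mean_difference,
                    "loa_low": res.loa_low,
                    "loa_high": res.loa_high,
                    "icc": res.icc,
                    "icc_ci_low": res.icc_ci_low,
                    "icc_ci_high": res.icc_ci_high,
                    "n": res.n,
                }
            )
    tables["interobserver"] = pd.DataFrame(rows)

    # per-kidney approach results for both modalities on the analysis set
    kid_rows = []
    for rec in analysis:
        label = rec.resolved_label()
        for modality in ("CTA", "MRA"):
            for approach in APPROACHES:
                res = summarize_kidney(rec, approach, modality, merge_mode=merge_mode)
                if res is None:
                    continue
                kid_rows.append(
                    {
                        "kidney": rec.kidney_id,
                        "modality": modality,
                        "approach": approach,
                        "label": label,
                        "visual_grade": rec.visual_grades.get(modality),
                        "min_d_mm": res.min_d_mm,
                        "min_a_mm2": res.min_a_mm2,
                        "dred_pct": res.dred_pct,
                        "ared_pct": res.ared_pct,
                    }
                )
    kidney_table = pd.DataFrame(kid_rows)
    tables["kidney_results"] = kidney_table

    # inter-method (CTA vs MRA) agreement per approach and measure
    rows = []
    if not kidney_table.empty:
        for approach, grp in kidney_table.groupby("approach"):
            wide = grp.pivot_table(
                index="kidney",
                columns="modality",
                values=list(MEASURE_DIRECTIONS),
            ).dropna()
            if len(wide) < 3:
                continue
            for measure in MEASURE_DIRECTIONS:
                res = agreement(wide[(measure, "CTA")], wide[(measure, "MRA")])
                rows.append(
                    {
                        "approach": approach,
                        "measure": measure,
                        "mean_difference": res.mean_difference,
                        "loa_low": res.loa_low,
                        "loa_high": res.loa_high,
                        "icc": res.icc,
                        "icc_ci_low": res.icc_ci_low,
                        "icc_ci_high": res.icc_ci_high,
                        "n": res.n,
                    }
                )
    tables["intermethod"] = pd.DataFrame(rows)

    # AUROC of every measure against the resolved reference
    rows = []
    if not kidney_table.empty:
        labels01 = {"positive": 1, "negative": 0}
        for (modality, approach), grp in kidney_table.groupby(["modality", "approach"]):
            y = grp["label"].map(labels01).to_numpy()
            if y.sum() == 0 or y.sum() == len(y):
                continue
            for measure, direction in MEASURE_DIRECTIONS.items():
                res = roc_auc(
                    grp[measure].to_numpy(), y, positive_direction=direction,
                    ci_method=auc_ci_method,
                )
                rows.append(
                    {
                        "modality": modality,
                        "approach": approach,
                        "measure": measure,
                        "auc": res.auc,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "n_pos": res.n_pos,
                        "n_neg": res.n_neg,
                    }
                )
    tables["auroc"] = pd.DataFrame(rows)
    return tables


def run_cohort(spec: CohortSpec, out_dir: str) -> dict[str, pd.DataFrame]:
    """Generate a cohort, compute all statistics and write the CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec)
    cohort.measurements.to_csv(out / "measurements.csv", index=False, float_format="%.6g")
    cohort.kidneys.to_csv(out / "kidneys.csv", index=False, float_format="%.6g")
    tables = cohort_statistics(cohort)
    for name, table in tables.items():
        table.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
    return tables
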