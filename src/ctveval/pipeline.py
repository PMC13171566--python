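"""End-to-end cohort analysis: per-patient metrics, model comparison,
ensemble probability maps and residuals.

The post-processing chain applied to every prediction before comparison is
fixed in order: largest connected component, then (if enabled)
cranio-caudal harmonization to the reference extent, then metric or
ensemble computation.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .craniocaudal import cc_differences, harmonize_cc
from .ensemble import (
    build_probability_map,
    default_levels,
    iso_volume_difference,
    isoprobability_mask,
)
from .mask import SegmentationMask, read_mask, write_float_volume, write_mask
from .metrics import evaluate_pair
from .ops import largest_component
from .residuals import compute_residuals, crossing_at, cumulative_curve
from .stats import ComparisonReport, MetricTable, compare

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PatientCase",
    "load_manifest",
    "evaluate_cohort",
    "summarize_metrics",
    "compare_models",
    "run_probability_analysis",
]

METRIC_COLUMNS = ["dice", "iou", "asd_mm", "hd_mm", "hd95_mm", "vd_cm3"]


@dataclass
class PipelineConfig:
    """Analysis options shared by the evaluation and ensemble stages."""

    keep_largest_component: bool = True
    harmonize_cc: bool = True
    connectivity: int = 26
    alpha: float = 0.05
    p_adjust: str = "none"  # or "holm"
    crossing_freq: float = 0.9
    iso_low_pct: float | None = None  # default: lowest attainable level (union)
    iso_high_pct: float = 100.0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PatientCase:
    """One patient's clinical mask and model predictions."""

    patient_id: str
    clinical: SegmentationMask
    predictions: dict[str, SegmentationMask]
    clinician_group: str = ""
    laterality: str = ""


def load_manifest(manifest_path: str | os.PathLike) -> list[PatientCase]:
    """Read a cohort manifest CSV and load its masks.

    The manifest has one row per mask with columns patient_id, label
    ("clinical" or a model name), path (relative to the manifest), and
    optional clinician_group / laterality. Patients with an unreadable
    mask are skipped with a logged warning; an empty result is an error.
    """
    manifest_path = str(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    df = pd.read_csv(manifest_path)
    cases: list[PatientCase] = []
    for pid, group in df.groupby("patient_id", sort=True):
        try:
            masks = {}
            for _, row in group.iterrows():
                path = row["path"]
                if not os.path.isabs(path):
                    path = os.path.join(base, path)
                masks[row["label"]] = read_mask(path, patient_id=str(pid), label=row["label"])
            if "clinical" not in masks:
                raise ValueError("no clinical mask listed")
            predictions = {k: v for k, v in masks.items() if k != "clinical"}
            cases.append(
                PatientCase(
                    patient_id=str(pid),
                    clinical=masks["clinical"],
                    predictions=predictions,
                    clinician_group=str(group["clinician_group"].iloc[0])
                    if "clinician_group" in group
                    else "",
                    laterality=str(group["laterality"].iloc[0])
                    if "laterality" in group
                    else "",
                )
            )
        except (OSError, ValueError) as exc:
            logger.warning("skipping patient %s: %s", pid, exc)
    if not cases:
        raise ValueError(f"no usable patients in manifest {manifest_path}")
    return cases


def cases_from_records(records: list[dict]) -> list[PatientCase]:
    """Adapt in-memory generator records into pipeline cases."""
    return [
        PatientCase(
            patient_id=r["patient_id"],
            clinical=r["clinical"],
            predictions=r["predictions"],
            clinician_group=r.get("clinician_group", ""),
            laterality=r.get("laterality", ""),
        )
        for r in records
    ]


def _postprocess(
    prediction: SegmentationMask,
    reference: SegmentationMask,
    config: PipelineConfig,
) -> SegmentationMask:
    out = prediction
    if config.keep_largest_component:
        out = largest_component(out, connectivity=config.connectivity)
    if config.harmonize_cc and not out.is_empty():
        out = harmonize_cc(out, reference)
    return out


def evaluate_cohort(
    cases: list[PatientCase], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-patient, per-model metric rows for a cohort.

    Each prediction is post-processed (largest component, optional
    cranio-caudal harmonization) and compared with the clinical mask.
    Cranial/caudal differences are recorded before harmonization (they
    are zero after, by construction) together with the harmonization flag.
    """
    config = config or PipelineConfig()
    rows = []
    for case in cases:
        for model, raw_pred in case.predictions.items():
            pred = raw_pred
            if config.keep_largest_component:
                pred = largest_component(pred, connectivity=config.connectivity)
            try:
                cranial_cm, caudal_cm = cc_differences(case.clinical, pred)
            except ValueError:
                cranial_cm = caudal_cm = np.nan
            if config.harmonize_cc and not pred.is_empty():
                pred = harmonize_cc(pred, case.clinical)
            ms = evaluate_pair(case.clinical, pred)
            rows.append(
                {
                    "patient_id": case.patient_id,
                    "model": model,
                    "clinician_group": case.clinician_group,
                    **ms.as_dict(),
                    "cranial_cm": cranial_cm,
                    "caudal_cm": caudal_cm,
                    "harmonized": config.harmonize_cc,
                }
            )
    if not rows:
        raise ValueError("cohort produced no metric rows")
    return pd.DataFrame(rows)


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD per model per metric (cohort-summary table layout)."""
    agg = metrics.groupby("model")[METRIC_COLUMNS].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def metric_tables(metrics: pd.DataFrame) -> dict[str, MetricTable]:
    """One patients x models table per metric, ready for rank tests."""
    return {
        m: MetricTable.from_long(metrics, m)
        for m in METRIC_COLUMNS
        if metrics[m].notna().any()
    }


def compare_models(
    tables: dict[str, MetricTable], alpha: float = 0.05, adjust: str = "none"
) -> dict[str, ComparisonReport]:
    """Friedman omnibus + Conover pairwise comparison per metric."""
    return {name: compare(tbl, alpha=alpha, adjust=adjust) for name, tbl in tables.items()}


def run_probability_analysis(
    cases: list[PatientCase],
    model_subset: list[str] | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> dict:
    """Ensemble probability maps, isoprobability volumes, and residuals.

    For each patient the subset's predictions are post-processed, averaged
    into an agreement map, and thresholded at every attainable level
    (100/K, ..., 100 percent). Residuals compare the clinical contour with
    the 100% (intersection) and lowest (union) isoprobability volumes; the
    iso-volume difference measures the ensemble disagreement region.

    Returns a dict with the per-patient ``residuals`` DataFrame, the
    cumulative ``curves`` per residual kind, their ``crossings`` at the
    configured cumulative frequency, and the level list used. If
    ``out_dir`` is given, agreement maps and isoprobability masks are
    written there as NIfTI.
    """
    config = config or PipelineConfig()
    rows = []
    levels_used: list[float] | None = None
    for case in cases:
        names = model_subset or sorted(case.predictions)
        missing = [m for m in names if m not in case.predictions]
        if missing:
            raise ValueError(f"patient {case.patient_id} lacks predictions: {missing}")
        if len(names) < 2:
            raise ValueError("probability analysis needs at least 2 models")
        preds = [
            _postprocess(case.predictions[m], case.clinical, config) for m in names
        ]
        pmap = build_probability_map(preds)
        levels = default_levels(pmap.n_models)
        levels_used = levels
        low_pct = config.iso_low_pct if config.iso_low_pct is not None else levels[0]
        v_high = isoprobability_mask(pmap, config.iso_high_pct)
        v_low = isoprobability_mask(pmap, low_pct)
        res = compute_residuals(case.clinical, v_high, v_low, patient_id=case.patient_id)
        ivd = iso_volume_difference(pmap, low_pct=low_pct, high_pct=config.iso_high_pct)
        rows.append(
            {
                "patient_id": case.patient_id,
                "clinician_group": case.clinician_group,
                "under_pct": res.under_pct,
                "over_pct": res.over_pct,
                "sum_pct": res.sum_pct,
                "iso_volume_difference_cm3": ivd,
            }
        )
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            write_float_volume(
                pmap.agreement,
                pmap.spacing_mm,
                os.path.join(out_dir, f"{case.patient_id}_probmap.nii.gz"),
                origin_mm=pmap.origin_mm,
            )
            for lv in levels:
                write_mask(
                    isoprobability_mask(pmap, lv),
                    os.path.join(out_dir, f"{case.patient_id}_iso{lv:g}.nii.gz"),
                )
    residuals_df = pd.DataFrame(rows)
    curves = {}
    crossings = {}
    for kind in ("under_pct", "over_pct", "sum_pct"):
        values = residuals_df[kind].to_numpy()
        curves[kind] = cumulative_curve(values)
        crossings[kind] = (
            crossing_at(values, config.crossing_freq) if values.size >= 2 else np.nan
        )
    return {
        "residuals": residuals_df,
        "curves": curves,
        "crossings": crossings,
        "levels": levels_used,
    }
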