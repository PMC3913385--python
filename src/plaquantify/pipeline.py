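"""End-to-end orchestration: images -> measurements -> subject summaries
-> statistics -> report.

The pipeline sequences the per-tooth image measurements (coverage and
dR%), joins them with the subject CSV, applies the exclusion filters,
aggregates per subject, and writes the descriptive case/control table,
the logistic-regression table, the coverage/dR% correlation and the
exclusion log. Every stage logs records in/out; re-running on identical
inputs yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import stats as stats_mod
from .cohort import (
    SMOKING_CODE,
    SubjectSummary,
    apply_exclusions,
    read_cohort_csv,
    summarize_subject,
)
from .errors import DataError, PlaquantifyError, SeparationError
from .image_model import PolygonROI, load_rois, read_image
from .plaque_segmentation import coverage
from .red_fluorescence import delta_r

__all__ = [
    "RunConfig",
    "run_pipeline",
    "measure_images",
    "analyze_summaries",
    "summaries_from_frame",
]

log = logging.getLogger("plaquantify")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (all defaults documented).

    ``threshold`` is the ratio-image plaque cut-off (>= 1); ``rounding``
    the integer-division mode (``floor`` or ``round``); deinterlacing is
    on by default with ``odd_rows`` parity; ``det_threshold_pct`` is the
    dR% detection threshold; ``smoking_encoding`` is ``ordinal`` (0/1/2)
    or ``binary`` (any smoking during pregnancy).
    """

    images_dir: Path
    roi_file: Path
    cohort_csv: Path
    out_dir: Path
    threshold: int = 1
    rounding: str = "floor"
    deinterlace: bool = True
    field: str = "odd_rows"
    det_threshold_pct: float = 20.0
    mm_per_pixel: float | None = None
    smoking_encoding: str = "ordinal"
    seed: int = 0

    def __post_init__(self) -> None:
        self.images_dir = Path(self.images_dir)
        self.roi_file = Path(self.roi_file)
        self.cohort_csv = Path(self.cohort_csv)
        self.out_dir = Path(self.out_dir)


def measure_images(
    images_dir: Path,
    roi_file: Path,
    threshold: int = 1,
    deinterlace_first: bool = True,
    field: str = "odd_rows",
    rounding: str = "floor",
    det_threshold_pct: float = 20.0,
    mm_per_pixel: float | None = None,
) -> pd.DataFrame:
    """Measure every polygon ROI in the ROI file against its image.

    ROI ``image_id`` values resolve to ``<images_dir>/<image_id>.png``
    (or ``.tif``/``.tiff``). Ellipse records with the same ``image_id``
    and ``tooth_id`` serve as the plaque-free reference for dR%; teeth
    without a reference get coverage only.
    """
    images_dir = Path(images_dir)
    records = load_rois(roi_file)
    polys = [r for r in records if r["type"] == "polygon"]
    ellipses = {
        (r["image_id"], r["tooth_id"]): r["roi"] for r in records if r["type"] == "ellipse"
    }
    rows = []
    cache: dict[str, object] = {}
    for rec in polys:
        image_id = rec["image_id"]
        if image_id not in cache:
            for suffix in (".png", ".tif", ".tiff", ".bmp"):
                candidate = images_dir / f"{image_id}{suffix}"
                if candidate.exists():
                    cache[image_id] = read_image(candidate, mm_per_pixel)
                    break
            else:
                raise FileNotFoundError(f"no image found for image_id {image_id!r}")
        img = cache[image_id]
        roi: PolygonROI = rec["roi"]
        cov = coverage(
            img, roi, threshold=threshold, deinterlace_first=deinterlace_first,
            field=field, rounding=rounding,  # type: ignore[arg-type]
        )
        row = {
            "image_id": image_id,
            "subject_id": image_id.split("_")[0],
            "tooth_id": roi.tooth_id,
            "roi_pixels": cov.roi_pixels,
            "plaque_pixels": cov.plaque_pixels,
            "coverage_pct": cov.coverage_pct,
            "plaque_area_mm2": cov.plaque_area_mm2,
            "reference_ratio": None,
            "delta_r_pct": None,
            "detected_pixels": None,
            "red_area_mm2": None,
        }
        ref = ellipses.get((image_id, roi.tooth_id))
        if ref is not None:
            dr = delta_r(img, roi, ref, detection_threshold_pct=det_threshold_pct)
            row.update(
                reference_ratio=dr.reference_ratio,
                delta_r_pct=dr.delta_r_pct,
                detected_pixels=dr.detected_pixels,
                red_area_mm2=dr.red_area_mm2,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_from_frame(df: pd.DataFrame) -> list[SubjectSummary]:
    """Subject summaries straight from a subject-level frame that already
    carries mean_coverage_pct / mean_delta_r_pct columns (as produced by
    the cohort simulator)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SubjectSummary(
                subject_id=str(row.subject_id),
                group=str(row.group),
                mean_coverage_pct=float(row.mean_coverage_pct),
                mean_delta_r_pct=float(row.mean_delta_r_pct),
                n_teeth_measured=int(getattr(row, "n_teeth", 0)) or 10,
                maternal_age=float(row.maternal_age),
                bmi=float(row.bmi),
                smoking=str(row.smoking),
                delivery_weeks=None
                if pd.isna(row.delivery_weeks)
                else float(row.delivery_weeks),
            )
        )
    return out


def _smoking_code(summary: SubjectSummary, encoding: str) -> int:
    code = SMOKING_CODE[summary.smoking]
    if encoding == "binary":
        return 1 if code == 2 else 0
    return code


def analyze_summaries(
    summaries: Sequence[SubjectSummary], smoking_encoding: str = "ordinal"
) -> dict:
    """Run the full statistical battery on subject summaries.

    Returns a dict with ``table1`` (list of GroupSummary), ``table2``
    (RegressionResult for case/control on coverage, dR%, smoking, BMI,
    age), and ``correlation`` (coverage vs dR%).
    """
    table1 = stats_mod.build_table1(summaries)
    y = [1 if s.group == "case" else 0 for s in summaries]
    predictors = pd.DataFrame(
        {
            "coverage_pct": [s.mean_coverage_pct for s in summaries],
            "delta_r_pct": [s.mean_delta_r_pct for s in summaries],
            "smoking_code": [_smoking_code(s, smoking_encoding) for s in summaries],
            "bmi": [s.bmi for s in summaries],
            "maternal_age": [s.maternal_age for s in summaries],
        }
    )
    table2 = None
    table2_note = None
    try:
        table2 = stats_mod.logistic_fit(y, predictors, outcome_name="case")
    except (DataError, SeparationError) as exc:
        # too few subjects or separation: the descriptive report still stands
        table2_note = str(exc)
        log.warning("logistic regression skipped: %s", exc)
    corr = stats_mod.pearson_r(
        [s.mean_coverage_pct for s in summaries],
        [s.mean_delta_r_pct for s in summaries],
    )
    return {
        "table1": table1,
        "table2": table2,
        "table2_note": table2_note,
        "correlation": corr,
    }


def _write_report(
    out_dir: Path,
    summaries: Sequence[SubjectSummary],
    results: dict,
    exclusion_log: Sequence[tuple[str, str]],
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stats_mod.table1_to_frame(results["table1"]).to_csv(
        out_dir / "table1.csv", index=False
    )
    if results["table2"] is not None:
        results["table2"].to_frame().round(6).to_csv(out_dir / "table2.csv", index=False)
    else:
        pd.DataFrame(
            columns=["predictor", "beta", "std_error", "wald_p",
                     "odds_ratio", "ci_lower", "ci_upper"]
        ).to_csv(out_dir / "table2.csv", index=False)
        (out_dir / "run_notes.txt").write_text(
            f"logistic regression skipped: {results.get('table2_note')}\n"
        )
    corr = results["correlation"]
    with open(out_dir / "correlation.json", "w") as fh:
        json.dump(
            {"pearson_r": round(corr.r, 4), "n": corr.n, "p_value": round(corr.p_value, 6)},
            fh,
            indent=1,
        )
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in summaries],
            "group": [s.group for s in summaries],
            "mean_coverage_pct": [s.mean_coverage_pct for s in summaries],
            "mean_delta_r_pct": [s.mean_delta_r_pct for s in summaries],
            "n_teeth_measured": [s.n_teeth_measured for s in summaries],
        }
    ).to_csv(out_dir / "subject_summaries.csv", index=False)
    pd.DataFrame(exclusion_log, columns=["subject_id", "reason"]).to_csv(
        out_dir / "exclusions.csv", index=False
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis and write the report directory.

    Stage order: read images -> (deinterlace ->) per-tooth coverage and
    dR% -> join with the cohort CSV -> exclusions -> subject summaries ->
    descriptive table / regression / correlation -> exclusion log. Any
    stage failure removes partial outputs and re-raises with the stage
    name attached.
    """
    t0 = time.time()
    out_dir = cfg.out_dir
    stage = "setup"
    try:
        for p in (cfg.images_dir, cfg.roi_file, cfg.cohort_csv):
            if not Path(p).exists():
                raise FileNotFoundError(p)

        stage = "measure"
        measurements = measure_images(
            cfg.images_dir,
            cfg.roi_file,
            threshold=cfg.threshold,
            deinterlace_first=cfg.deinterlace,
            field=cfg.field,
            rounding=cfg.rounding,
            det_threshold_pct=cfg.det_threshold_pct,
            mm_per_pixel=cfg.mm_per_pixel,
        )
        log.info("measure: %d teeth across %d images",
                 len(measurements), measurements["image_id"].nunique())

        stage = "join"
        records = read_cohort_csv(cfg.cohort_csv)
        by_subject = measurements.groupby("subject_id")
        from .plaque_segmentation import CoverageResult
        from .red_fluorescence import DeltaRResult

        for rec in records:
            if rec.subject_id in by_subject.groups:
                sub = by_subject.get_group(rec.subject_id)
                rec.tooth_measurements = [
                    (
                        CoverageResult(
                            tooth_id=str(r.tooth_id),
                            roi_pixels=int(r.roi_pixels),
                            plaque_pixels=int(r.plaque_pixels),
                            coverage_pct=float(r.coverage_pct),
                        ),
                        DeltaRResult(
                            tooth_id=str(r.tooth_id),
                            reference_ratio=float(r.reference_ratio or 0.0),
                            delta_r_pct=float(r.delta_r_pct or 0.0),
                            detected_pixels=int(r.detected_pixels or 0),
                        ),
                    )
                    for r in sub.itertuples(index=False)
                ]
        log.info("join: %d subject rows", len(records))

        stage = "exclusions"
        retained, excl_log = apply_exclusions(records)
        log.info("exclusions: %d in, %d retained, %d excluded",
                 len(records), len(retained), len(excl_log))

        stage = "summarize"
        summaries = [summarize_subject(r) for r in retained]

        stage = "analyze"
        results = analyze_summaries(summaries, smoking_encoding=cfg.smoking_encoding)

        stage = "report"
        _write_report(out_dir, summaries, results, excl_log)
        measurements.to_csv(out_dir / "measurements.csv", index=False)
        log.info("pipeline finished in %.2f s -> %s", time.time() - t0, out_dir)
        return out_dir
    except Exception as exc:
        if out_dir.exists() and stage != "setup":
            shutil.rmtree(out_dir, ignore_errors=True)
        raise PlaquantifyError(f"pipeline failed at stage {stage!r}: {exc}") from exc
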