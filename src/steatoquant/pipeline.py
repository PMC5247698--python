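"""End-to-end pipeline: simulate -> segment -> morphometry -> cohort report.

Each patient gets a simulated cohort row (true fat fraction, morphometry,
biochemistry) and a set of simulated microscope fields at that fat
fraction.  The fields are segmented, pooled into a measured mFPA, the
hexagonal-lobule hepatocyte count is recomputed under the configured
convention, and the full statistical report is run on the *measured* table
— the same path a real slide archive would take.

Everything is deterministic under the config seed; every output file
carries the config hash and seed, so re-running an identical config
reproduces byte-identical tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash, save_config
from .io import write_cohort_csv, write_report_json
from .morphometry import hepatocytes_per_lobule
from .segmentation import aggregate_mfpa, segment_fat
from .stats import cohort_report, roc
from .synthetic import CohortSpec, FieldSpec, generate_cohort, generate_field

__all__ = ["PipelineError", "run_end_to_end"]

logger = logging.getLogger("steatoquant.pipeline")

# simulated targets are capped below the packing bound so no patient's
# fields can fail placement
_MAX_SIMULATED_FRACTION = 0.35


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _field_seed(base_seed: int, patient_idx: int, field_idx: int) -> int:
    # distinct, reproducible per-field seeds within int32 range
    return int((base_seed * 1_000_003 + patient_idx * 1009 + field_idx) % (2**31 - 1))


def _measure_patient(
    config: PipelineConfig, patient_idx: int, true_mfpa_pct: float
) -> tuple[float, list[dict]]:
    target = min(true_mfpa_pct / 100.0, _MAX_SIMULATED_FRACTION)
    results = []
    field_rows = []
    for j in range(config.n_fields):
        spec = FieldSpec(
            width_px=config.field_px,
            height_px=config.field_px,
            um_per_px=config.um_per_px,
            target_fat_fraction=target,
            artifact_density=config.artifact_density,
            seed=_field_seed(config.seed, patient_idx, j),
        )
        rgb, _truth = generate_field(spec)
        seg = segment_fat(rgb, config.segmentation)
        results.append(seg)
        logger.info(
            "segmented field patient=%d field=%d fat_um2=%.1f parenchyma_um2=%.1f",
            patient_idx, j, seg.fat_area_um2, seg.parenchyma_area_um2,
        )
        field_rows.append(
            {
                "patient_idx": patient_idx,
                "field_idx": j,
                "field_id": seg.field_id,
                "fat_area_um2": seg.fat_area_um2,
                "parenchyma_area_um2": seg.parenchyma_area_um2,
                "fraction": seg.fat_fraction,
            }
        )
    biopsy = aggregate_mfpa(results, biopsy_id=f"patient-{patient_idx}")
    return biopsy.mfpa_pct, field_rows


def run_end_to_end(config: PipelineConfig, workdir: str | Path) -> dict:
    """Run the whole pipeline into ``workdir``; returns the report bundle.

    Outputs: ``config.json``, ``cohort_true.csv`` (simulated truth),
    ``fields.csv`` (per-field segmentation areas), ``cohort_measured.csv``
    (measured mFPA merged with morphometry), ``report.json`` and the
    ``summary/correlations/brackets/roc_points`` CSV tables.  On failure the
    outputs written so far are retained for debugging.
    """
    config.validate()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    provenance = {"config_sha256": chash, "seed": config.seed, "version": __version__}
    save_config(config, workdir / "config.json")

    try:
        cohort = generate_cohort(
            CohortSpec(n_patients=config.n_patients, seed=config.seed)
        )
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        raise PipelineError("simulate-cohort", exc) from exc
    write_cohort_csv(cohort, workdir / "cohort_true.csv", provenance)

    try:
        measured_mfpa = []
        all_field_rows = []
        for i, true_mfpa in enumerate(cohort["mfpa_pct"].to_numpy()):
            mfpa, field_rows = _measure_patient(config, i, float(true_mfpa))
            measured_mfpa.append(mfpa)
            all_field_rows.extend(field_rows)
    except Exception as exc:
        raise PipelineError("segment-fields", exc) from exc
    write_cohort_csv(pd.DataFrame(all_field_rows), workdir / "fields.csv", provenance)

    try:
        measured = cohort.copy()
        measured["mfpa_pct"] = measured_mfpa
        measured["hpl"] = hepatocytes_per_lobule(
            measured["lr_um"].to_numpy(),
            measured["ha_um2"].to_numpy(),
            config.hexagon_convention,
        )
    except Exception as exc:
        raise PipelineError("morphometry", exc) from exc
    write_cohort_csv(measured, workdir / "cohort_measured.csv", provenance)

    try:
        report = cohort_report(measured, cutoffs_u_l=config.cutoffs_u_l)
    except Exception as exc:
        raise PipelineError("cohort-report", exc) from exc
    report["meta"] = dict(provenance)
    write_report_json(report, workdir / "report.json")
    _write_tables(report, measured, workdir, provenance)
    return report


def _write_tables(
    report: dict, measured: pd.DataFrame, workdir: Path, provenance: dict
) -> None:
    rows = []
    for group, stats_by_var in report["summary"].items():
        for var, entry in stats_by_var.items():
            if var == "n" or "median" not in entry:
                continue
            rows.append({"group": group, "variable": var, **entry})
    write_cohort_csv(pd.DataFrame(rows), workdir / "summary.csv", provenance)

    rows = []
    for stratum, by_var in report["correlations"].items():
        for var, entry in by_var.items():
            if "rs" in entry:
                rows.append({"stratum": stratum, "variable": var, **entry})
    write_cohort_csv(pd.DataFrame(rows), workdir / "correlations.csv", provenance)

    rows = []
    for var, by_bracket in report["brackets"]["medians"].items():
        for bracket, entry in by_bracket.items():
            if "median" in entry:
                rows.append({"variable": var, "bracket": bracket, **entry})
    write_cohort_csv(pd.DataFrame(rows), workdir / "brackets.csv", provenance)

    rows = []
    for threshold in (5.0, 20.0):
        labels = (measured["mfpa_pct"] >= threshold).to_numpy()
        if labels.all() or not labels.any():
            continue
        for col, enzyme in (("alt_u_l", "alt"), ("ast_u_l", "ast")):
            curve = roc(measured[col].to_numpy(dtype=float), labels)
            for t, sens, spec in zip(
                curve.thresholds, curve.sensitivity, curve.specificity
            ):
                rows.append(
                    {
                        "score": enzyme,
                        "mfpa_threshold": threshold,
                        "cutoff_u_l": "inf" if np.isinf(t) else float(t),
                        "sensitivity": float(sens),
                        "specificity": float(spec),
                        "auroc": curve.auroc,
                    }
                )
    write_cohort_csv(pd.DataFrame(rows), workdir / "roc_points.csv", provenance)
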