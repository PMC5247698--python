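"""Readers and writers for fields, masks, cohort tables and reports.

Fields travel as 8-bit RGB PNG or TIFF with the micron-per-pixel
calibration in a JSON sidecar (``<image>.json``); calibration is never
guessed.  Cohort tables are plain CSV with a fixed column schema; files
written by the pipeline carry a provenance comment line (config hash and
seed) so identical runs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .synthetic import COHORT_COLUMNS, FieldSpec, GroundTruth, RGBField

__all__ = [
    "read_field",
    "write_field",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_report_json",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


def read_field(path: str | Path, um_per_px: float | None = None) -> RGBField:
    """Load a calibrated RGB field from PNG or TIFF.

    Calibration comes from ``um_per_px`` if given, otherwise from the
    ``<image>.json`` sidecar; with neither, loading refuses rather than
    guessing a scale.
    """
    path = Path(path)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise ValueError(f"unsupported image format {path.suffix!r}; use PNG or TIFF")
    if path.suffix.lower() == ".png":
        pixels = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
    else:
        pixels = np.asarray(tifffile.imread(path))
        if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.dtype != np.uint8:
            raise ValueError(f"{path} is not an 8-bit RGB TIFF")
    if um_per_px is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(
                f"no calibration for {path.name}: pass um_per_px or provide {sidecar.name}"
            )
        meta = json.loads(sidecar.read_text())
        um_per_px = meta.get("um_per_px")
        if um_per_px is None:
            raise ValueError(f"sidecar {sidecar.name} has no 'um_per_px' entry")
    field = RGBField(pixels=pixels, um_per_px=float(um_per_px), field_id=path.stem)
    field.validate()
    return field


def _mask_to_png(mask: np.ndarray, path: Path) -> None:
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)


def write_field(
    directory: str | Path,
    rgb: RGBField,
    truth: GroundTruth | None = None,
    spec: FieldSpec | None = None,
    fmt: str = "png",
) -> Path:
    """Write a field image plus a JSON sidecar (and truth masks, if given)."""
    if fmt not in ("png", "tiff"):
        raise ValueError("fmt must be 'png' or 'tiff'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".png" if fmt == "png" else ".tif"
    img_path = directory / f"{rgb.field_id}{suffix}"
    if fmt == "png":
        Image.fromarray(rgb.pixels, mode="RGB").save(img_path)
    else:
        tifffile.imwrite(img_path, rgb.pixels)

    meta: dict = {"um_per_px": rgb.um_per_px, "field_id": rgb.field_id}
    if spec is not None:
        meta["spec"] = {
            "width_px": spec.width_px,
            "height_px": spec.height_px,
            "um_per_px": spec.um_per_px,
            "target_fat_fraction": spec.target_fat_fraction,
            "vacuole_diameter_um": list(spec.vacuole_diameter_um),
            "artifact_density": spec.artifact_density,
            "seed": spec.seed,
        }
    if truth is not None:
        meta["true_fat_fraction"] = truth.true_fat_fraction
        meta["vacuole_centres_and_radii_px"] = [
            list(v) for v in truth.vacuole_centres_and_radii
        ]
        _mask_to_png(truth.fat_mask, directory / f"{rgb.field_id}.fat_mask.png")
        _mask_to_png(truth.artifact_mask, directory / f"{rgb.field_id}.artifact_mask.png")
    sidecar = img_path.with_suffix(img_path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return img_path


def write_cohort_csv(
    df: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a cohort table with an optional provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if provenance:
            items = " ".join(f"{k}={v}" for k, v in sorted(provenance.items()))
            fh.write(f"# steatoquant {items}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, checking the expected column schema."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} is missing columns: {missing}")
    return df


def write_report_json(report: dict, path: str | Path) -> None:
    """Serialise a report bundle deterministically (sorted keys)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
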