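"""Hepatocyte and lobule morphometry.

Hepatocyte cross-sections are modelled as ellipses measured along two
perpendicular diameters; the liver lobule is idealised as a regular hexagon
whose radius is the portal-tract-to-central-vein distance.  Dividing the
hexagon cross-section area by the hepatocyte cross-section area gives an
approximate (2-D, not stereological) hepatocyte count per lobule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HepatocyteMeasure",
    "BiopsyMorphometry",
    "ellipse_area",
    "biopsy_hepatocyte_area",
    "biopsy_lobule_radius",
    "hexagon_area",
    "hepatocytes_per_lobule",
    "morphometry_table",
    "HEXAGON_CONVENTIONS",
]

#: Supported interpretations of the lobule "radius" measurement.
#: ``circumradius`` — the distance runs from the lobule centre (central vein)
#: to a corner (portal tract): area = (3*sqrt(3)/2) * R**2.
#: ``apothem`` — the distance runs to an edge midpoint: area = 2*sqrt(3) * a**2.
HEXAGON_CONVENTIONS = ("circumradius", "apothem")

#: Number of hepatocytes conventionally sampled per biopsy.
RECOMMENDED_HEPATOCYTE_SAMPLE = 50


def ellipse_area(d1_um: float, d2_um: float) -> float:
    """Area of an ellipse from two perpendicular diameters, in square microns.

    ``pi * (d1/2) * (d2/2)``; symmetric in its arguments and exact for a
    circle when ``d1 == d2``.
    """
    if d1_um < 0 or d2_um < 0:
        raise ValueError(f"diameters must be non-negative, got ({d1_um}, {d2_um})")
    # grouping the diameters keeps the result exactly symmetric in floats
    return math.pi * (d1_um * d2_um) / 4.0


@dataclass(frozen=True)
class HepatocyteMeasure:
    """One hepatocyte measured along two perpendicular diameters (microns)."""

    d1_um: float
    d2_um: float

    def __post_init__(self) -> None:
        if self.d1_um < 0 or self.d2_um < 0:
            raise ValueError("hepatocyte diameters must be non-negative")

    @property
    def area_um2(self) -> float:
        return ellipse_area(self.d1_um, self.d2_um)


@dataclass(frozen=True)
class BiopsyMorphometry:
    """Per-biopsy morphometry summary.

    ``ha_um2`` and ``lr_um`` are medians of the per-biopsy measurements;
    ``hpl`` is the hexagonal-lobule hepatocyte count approximation derived
    from them.
    """

    biopsy_id: str
    ha_um2: float
    lr_um: float
    hpl: float
    n_hepatocytes: int
    n_lobule_measurements: int
    hexagon_convention: str = "circumradius"

    def __post_init__(self) -> None:
        if self.ha_um2 <= 0 or self.lr_um <= 0 or self.hpl <= 0:
            raise ValueError("populated morphometry values must be positive")


def _median(values: np.ndarray) -> float:
    # even count -> midpoint of the central pair (numpy's convention)
    return float(np.median(values))


def biopsy_hepatocyte_area(measures: Sequence[HepatocyteMeasure] | Iterable) -> float:
    """Median hepatocyte area (um^2) over a biopsy's sampled hepatocytes.

    Accepts ``HepatocyteMeasure`` objects or precomputed areas.  Warns when
    fewer than 50 hepatocytes are supplied, the conventional per-biopsy
    sample size.
    """
    measures = list(measures)
    if not measures:
        raise ValueError("at least one hepatocyte measure is required")
    if isinstance(measures[0], HepatocyteMeasure):
        areas = np.array([m.area_um2 for m in measures], dtype=float)
    else:
        areas = np.asarray(measures, dtype=float)
        if (areas < 0).any():
            raise ValueError("hepatocyte areas must be non-negative")
    if areas.size < RECOMMENDED_HEPATOCYTE_SAMPLE:
        warnings.warn(
            f"only {areas.size} hepatocytes supplied; "
            f"{RECOMMENDED_HEPATOCYTE_SAMPLE} is the recommended sample size",
            stacklevel=2,
        )
    return _median(areas)


def biopsy_lobule_radius(distances_um: Sequence[float]) -> float:
    """Median portal-tract-to-central-vein distance (um) for a biopsy."""
    distances = np.asarray(list(distances_um), dtype=float)
    if distances.size == 0:
        raise ValueError("at least one lobule distance is required")
    if (distances <= 0).any():
        raise ValueError("lobule distances must be positive")
    return _median(distances)


def hexagon_area(radius_um, convention: str = "circumradius"):
    """Area of a regular hexagon from its radius measurement.

    With the ``circumradius`` convention the area is ``(3*sqrt(3)/2) * R**2``;
    with ``apothem`` it is ``2*sqrt(3) * a**2`` (a factor 4/3 larger for the
    same numerical radius).  Accepts scalars or arrays.
    """
    if convention not in HEXAGON_CONVENTIONS:
        raise ValueError(
            f"unknown hexagon convention {convention!r}; choose from {HEXAGON_CONVENTIONS}"
        )
    r = np.asarray(radius_um, dtype=float)
    if (r <= 0).any():
        raise ValueError("hexagon radius must be positive")
    if convention == "circumradius":
        area = (3.0 * math.sqrt(3.0) / 2.0) * r**2
    else:
        area = 2.0 * math.sqrt(3.0) * r**2
    return float(area) if np.isscalar(radius_um) else area


def hepatocytes_per_lobule(lr_um, ha_um2, convention: str = "circumradius"):
    """Approximate hepatocytes per lobule: hexagon area over hepatocyte area.

    This is a 2-D areas ratio on the tissue section, not an actual cell
    count.  Accepts scalars or arrays (broadcast).
    """
    ha = np.asarray(ha_um2, dtype=float)
    if (ha <= 0).any():
        raise ValueError("hepatocyte area must be positive")
    hpl = hexagon_area(lr_um, convention) / ha
    return float(hpl) if np.isscalar(lr_um) and np.isscalar(ha_um2) else hpl


def summarize_biopsy(
    biopsy_id: str,
    hepatocytes: Sequence[HepatocyteMeasure],
    lobule_distances_um: Sequence[float],
    convention: str = "circumradius",
) -> BiopsyMorphometry:
    """Combine raw measurements into a ``BiopsyMorphometry`` record."""
    ha = biopsy_hepatocyte_area(hepatocytes)
    lr = biopsy_lobule_radius(lobule_distances_um)
    hpl = hepatocytes_per_lobule(lr, ha, convention)
    return BiopsyMorphometry(
        biopsy_id=str(biopsy_id),
        ha_um2=ha,
        lr_um=lr,
        hpl=hpl,
        n_hepatocytes=len(list(hepatocytes)),
        n_lobule_measurements=len(list(lobule_distances_um)),
        hexagon_convention=convention,
    )


def morphometry_table(
    hepatocytes: pd.DataFrame,
    lobules: pd.DataFrame,
    convention: str = "circumradius",
) -> pd.DataFrame:
    """Per-biopsy morphometry from tables of raw measurements.

    ``hepatocytes`` needs columns (biopsy_id, d1_um, d2_um); ``lobules``
    needs (biopsy_id, distance_um).  Biopsies present in both tables are
    summarised; the result has one row per biopsy.
    """
    for df, cols, name in (
        (hepatocytes, {"biopsy_id", "d1_um", "d2_um"}, "hepatocytes"),
        (lobules, {"biopsy_id", "distance_um"}, "lobules"),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} table is missing columns: {sorted(missing)}")

    rows = []
    shared = sorted(set(hepatocytes["biopsy_id"]) & set(lobules["biopsy_id"]), key=str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-sample warning handled per-row below
        for biopsy_id in shared:
            h = hepatocytes[hepatocytes["biopsy_id"] == biopsy_id]
            l = lobules[lobules["biopsy_id"] == biopsy_id]
            measures = [
                HepatocyteMeasure(d1, d2)
                for d1, d2 in zip(h["d1_um"].to_numpy(), h["d2_um"].to_numpy())
            ]
            summary = summarize_biopsy(
                biopsy_id, measures, l["distance_um"].to_list(), convention
            )
            rows.append(
                {
                    "biopsy_id": summary.biopsy_id,
                    "ha_um2": summary.ha_um2,
                    "lr_um": summary.lr_um,
                    "hpl": summary.hpl,
                    "n_hepatocytes": summary.n_hepatocytes,
                    "n_lobule_measurements": summary.n_lobule_measurements,
                }
            )
    return pd.DataFrame(rows)
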