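"""Fat proportionate area from calibrated RGB fields.

Fat vacuoles in an H&E section are unstained, so they read as near-white in
all three colour channels.  Segmentation thresholds the channels jointly,
then filters the resulting connected components by area and circularity so
that elongated sinusoids and oversized vessel lumens — which are just as
white — are moved to an exclusion mask instead of being counted as fat.
Excluded pixels leave both the fat numerator and the parenchyma denominator,
mirroring how a pathologist edits artifacts out of the measured area.

The per-biopsy measured fat proportionate area (mFPA) pools fat and
parenchyma areas over the sampled fields:

    mFPA = 100 * sum(fat area) / sum(parenchyma area)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .synthetic import RGBField

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "BiopsyMfpa",
    "segment_fat",
    "aggregate_mfpa",
    "sample_fields",
    "adequacy_check",
]

#: Conventional number of randomly sampled fields per biopsy.
DEFAULT_N_FIELDS = 21


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters.

    ``channel_thresholds`` define the whiteness rule: a pixel is a fat
    candidate when every channel is at or above its bound.  The area window
    and circularity cut implement automated artifact editing: components
    smaller than a microvesicle, larger than any vacuole, or too elongated
    are excluded rather than counted.
    """

    channel_thresholds: tuple[int, int, int] = (200, 200, 200)
    min_object_area_um2: float = 20.0
    max_object_area_um2: float = 8000.0
    min_circularity: float = 0.5
    fill_holes: bool = True
    # whiteness components touching the border and covering more than this
    # fraction of the field are off-section background, not fat
    background_min_fraction: float = 0.10

    def validate(self) -> None:
        if not all(0 <= t <= 255 for t in self.channel_thresholds):
            raise ValueError("channel thresholds must lie in [0, 255]")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")
        if not 0 <= self.min_object_area_um2 < self.max_object_area_um2:
            raise ValueError("need 0 <= min_object_area_um2 < max_object_area_um2")


@dataclass(frozen=True)
class SegmentationResult:
    """Masks and calibrated areas for one segmented field.

    Invariants: ``fat_mask`` is a subset of ``parenchyma_mask``;
    ``exclusion_mask`` is disjoint from both (excluded pixels count in
    neither numerator nor denominator).
    """

    field_id: str
    um_per_px: float
    fat_mask: np.ndarray         # bool
    parenchyma_mask: np.ndarray  # bool, includes fat
    exclusion_mask: np.ndarray   # bool
    fat_area_um2: float
    parenchyma_area_um2: float

    @property
    def fat_fraction(self) -> float:
        return self.fat_area_um2 / self.parenchyma_area_um2


@dataclass(frozen=True)
class BiopsyMfpa:
    """Pooled per-biopsy fat proportionate area over sampled fields."""

    biopsy_id: str
    field_results: tuple[SegmentationResult, ...]
    mfpa_pct: float
    n_fields: int
    adequacy_converged: bool


def _circularity(area_px: float, perimeter_px: float) -> float:
    if perimeter_px <= 0:
        return 1.0  # single-pixel/degenerate component; the area window decides
    return min(1.0, 4.0 * math.pi * area_px / perimeter_px**2)


def segment_fat(
    rgb: RGBField,
    params: SegmentationParams | None = None,
    manual_exclusion: np.ndarray | None = None,
) -> SegmentationResult:
    """Segment fat vacuoles in one calibrated field.

    Candidate fat pixels satisfy the whiteness rule in all three channels.
    8-connected components are then triaged: border-touching components
    covering over ``background_min_fraction`` of the field are off-section
    background (excluded from tissue entirely); components outside the area
    window or under the circularity cut go to the exclusion mask; the rest
    are fat.  A user-supplied ``manual_exclusion`` mask is always excluded,
    overriding any automatic call.
    """
    params = params or SegmentationParams()
    params.validate()
    rgb.validate()
    pixels = rgb.pixels
    h, w = pixels.shape[:2]
    if manual_exclusion is not None:
        manual_exclusion = np.asarray(manual_exclusion, dtype=bool)
        if manual_exclusion.shape != (h, w):
            raise ValueError(
                f"manual exclusion mask shape {manual_exclusion.shape} does not "
                f"match field shape {(h, w)}"
            )

    t = params.channel_thresholds
    candidate = (
        (pixels[:, :, 0] >= t[0]) & (pixels[:, :, 1] >= t[1]) & (pixels[:, :, 2] >= t[2])
    )
    if candidate.all():
        raise ValueError(f"no tissue detected in field {rgb.field_id!r}: all pixels white")
    if params.fill_holes:
        candidate = ndimage.binary_fill_holes(candidate)

    px_area_um2 = rgb.um_per_px**2
    labels = measure.label(candidate, connectivity=2)
    fat_mask = np.zeros((h, w), dtype=bool)
    exclusion_mask = np.zeros((h, w), dtype=bool)
    background_mask = np.zeros((h, w), dtype=bool)
    min_background_px = params.background_min_fraction * h * w

    for region in measure.regionprops(labels):
        y0, x0, y1, x1 = region.bbox
        touches_border = y0 == 0 or x0 == 0 or y1 == h or x1 == w
        region_mask = labels[y0:y1, x0:x1] == region.label
        if touches_border and region.area > min_background_px:
            background_mask[y0:y1, x0:x1] |= region_mask
            continue
        area_um2 = region.area * px_area_um2
        keep = (
            params.min_object_area_um2 <= area_um2 <= params.max_object_area_um2
            and _circularity(region.area, region.perimeter) >= params.min_circularity
        )
        target = fat_mask if keep else exclusion_mask
        target[y0:y1, x0:x1] |= region_mask

    if manual_exclusion is not None:
        exclusion_mask |= manual_exclusion & ~background_mask
        fat_mask &= ~manual_exclusion

    parenchyma_mask = ~background_mask & ~exclusion_mask
    if not parenchyma_mask.any():
        raise ValueError(f"no tissue detected in field {rgb.field_id!r}")

    return SegmentationResult(
        field_id=rgb.field_id,
        um_per_px=rgb.um_per_px,
        fat_mask=fat_mask,
        parenchyma_mask=parenchyma_mask,
        exclusion_mask=exclusion_mask,
        fat_area_um2=float(fat_mask.sum()) * px_area_um2,
        parenchyma_area_um2=float(parenchyma_mask.sum()) * px_area_um2,
    )


def aggregate_mfpa(
    results: Sequence[SegmentationResult],
    biopsy_id: str,
    adequacy_tolerance_pp: float = 0.5,
    adequacy_window: int = 5,
) -> BiopsyMfpa:
    """Pool field results into a per-biopsy mFPA percentage.

    The estimate is the pooled-area ratio (total fat over total parenchyma),
    not the mean of per-field ratios, so larger usable tissue areas weigh
    more.  The adequacy flag records whether the running estimate had
    stabilised over the last fields (False when there are too few fields to
    judge).
    """
    results = list(results)
    if not results:
        raise ValueError("aggregate_mfpa requires at least one field result")
    for r in results:
        if r.parenchyma_area_um2 <= 0:
            raise ValueError(f"field {r.field_id!r} has zero parenchyma area")
    fat = sum(r.fat_area_um2 for r in results)
    parenchyma = sum(r.parenchyma_area_um2 for r in results)
    fractions = [r.fat_fraction for r in results]
    converged = (
        len(fractions) >= adequacy_window
        and adequacy_check(fractions, adequacy_tolerance_pp, adequacy_window)
    )
    return BiopsyMfpa(
        biopsy_id=str(biopsy_id),
        field_results=tuple(results),
        mfpa_pct=100.0 * fat / parenchyma,
        n_fields=len(results),
        adequacy_converged=converged,
    )


def sample_fields(candidate_fields: Sequence, n: int = DEFAULT_N_FIELDS, seed: int = 0) -> list:
    """Uniform random sample of ``n`` fields without replacement."""
    candidates = list(candidate_fields)
    if len(candidates) < n:
        raise ValueError(f"need at least {n} candidate fields, got {len(candidates)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in idx]


def adequacy_check(
    per_field_fractions: Sequence[float],
    tolerance_pp: float = 0.5,
    window: int = 5,
) -> bool:
    """Has the running mFPA estimate stabilised?

    The running estimate after k fields is the mean of the first k per-field
    fat fractions, in percent.  The check passes when the estimate moved by
    no more than ``tolerance_pp`` percentage points over the last ``window``
    added fields.  This is a convergence heuristic for choosing how many
    fields to image, not a statistical test.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    fractions = np.asarray(list(per_field_fractions), dtype=float)
    n = fractions.size
    if n < window:
        raise ValueError(f"need at least window={window} per-field fractions, got {n}")
    running = 100.0 * np.cumsum(fractions) / np.arange(1, n + 1)
    tail = running[max(0, n - window - 1):]
    return bool(tail.max() - tail.min() <= tolerance_pp)
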