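"""Per-quadrant feeding-activity statistics and the lagged variance.

For quadrant *i* of a frame, with A_total the quadrant pixel area, A_fish the
fish pixel count and A_max the area of the largest connected fish region:

    FishAreaRatio_i = 100 * A_fish / A_total          (percent)
    AreaMaxRatio_i  = 100 * A_max  / A_total          (percent)
    FAI_i           = FishAreaRatio_i + AreaMaxRatio_i

FAI (Feeding Activity Index) is high when fish crowd one quadrant: the fish
area ratio reflects how many fish are present, the max-region ratio how
tightly they cluster.  The temporal statistic compares the current frame with
the frame L frames earlier (default L = 20):

    FAIdiff_i = FAI_{t-L,i} - FAI_{t,i}
    AvgFAIdiff = (1/4) * sum_i FAIdiff_i
    FAIvar     = (1/4) * sum_i (FAIdiff_i - AvgFAIdiff)^2

i.e. the population variance (divisor 4) of the four lagged differences.
FAIvar spikes when fish rapidly redistribute across quadrants — at feeding
onset (aggregation toward bait) and at dispersal — and is near zero both for
calm wandering and for quiet clustered feeding.  All ratios are kept on the
percent scale so deployment thresholds such as 100 or 50 apply directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .mask_model import SegmentationMask, connected_regions, split_quadrants

__all__ = ["QuadrantStats", "FrameFAI", "VarianceResult", "quadrant_stats", "frame_fai", "faivar"]


@dataclass(frozen=True)
class QuadrantStats:
    """Aggregation statistics for one quadrant of one frame."""

    quadrant_index: int
    area_fish: int
    area_max: int
    area_total: int
    fish_area_ratio: float  # percent in [0, 100]
    area_max_ratio: float  # percent in [0, 100]
    fai: float  # percent-sum in [0, 200]


@dataclass(frozen=True)
class FrameFAI:
    """The four per-quadrant FAI values of one frame, in quadrant order 1..4."""

    frame_index: int
    fai_by_quadrant: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.fai_by_quadrant)
        if len(vals) != 4:
            raise InvalidInputError(f"expected 4 FAI values, got {len(vals)}")
        object.__setattr__(self, "fai_by_quadrant", vals)


@dataclass(frozen=True)
class VarianceResult:
    """Lagged FAI differences and their population variance for one frame."""

    frame_index: int
    lag: int
    fai_diff: tuple[float, float, float, float]
    avg_diff: float
    variance: float


def quadrant_stats(sub_mask: np.ndarray, quadrant_index: int) -> QuadrantStats:
    """Compute the area ratios and FAI for one quadrant's sub-mask.

    An empty (all-background) sub-mask yields zero ratios; a zero-area
    sub-mask is invalid.
    """
    pixels = np.asarray(sub_mask).astype(bool, copy=False)
    area_total = pixels.size
    if area_total == 0:
        raise InvalidInputError(
            f"quadrant {quadrant_index}: sub-mask has zero pixel area"
        )
    area_fish = int(pixels.sum())
    regions = connected_regions(pixels, quadrant_index)
    area_max = max((r.area for r in regions), default=0)
    fish_area_ratio = 100.0 * area_fish / area_total
    area_max_ratio = 100.0 * area_max / area_total
    return QuadrantStats(
        quadrant_index=quadrant_index,
        area_fish=area_fish,
        area_max=area_max,
        area_total=area_total,
        fish_area_ratio=fish_area_ratio,
        area_max_ratio=area_max_ratio,
        fai=fish_area_ratio + area_max_ratio,
    )


def frame_fai(mask: SegmentationMask) -> FrameFAI:
    """Compute the four quadrant FAI values of one frame."""
    if not isinstance(mask, SegmentationMask):
        mask = SegmentationMask(mask)
    fais = tuple(
        quadrant_stats(sub, quad.index).fai for quad, sub in split_quadrants(mask)
    )
    return FrameFAI(frame_index=mask.frame_index, fai_by_quadrant=fais)


def faivar(current: FrameFAI, lagged: FrameFAI, lag: int) -> VarianceResult:
    """Population variance of the four lag-L FAI differences.

    The differences are taken lagged-minus-current; only their variance is
    consumed downstream, which is invariant to the global sign.
    """
    if lag < 1:
        raise InvalidInputError(f"lag must be >= 1 frame, got {lag}")
    spacing = current.frame_index - lagged.frame_index
    if spacing != lag:
        raise InvalidInputError(
            f"frame spacing {spacing} (frames {lagged.frame_index} -> "
            f"{current.frame_index}) does not match lag {lag}"
        )
    diff = np.asarray(lagged.fai_by_quadrant) - np.asarray(current.fai_by_quadrant)
    avg = float(diff.mean())
    variance = float(np.mean((diff - avg) ** 2))  # divisor 4: population variance
    return VarianceResult(
        frame_index=current.frame_index,
        lag=lag,
        fai_diff=tuple(float(d) for d in diff),
        avg_diff=avg,
        variance=variance,
    )
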