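"""Segmentation masks, quadrant partitioning and connected fish regions.

A video frame arrives as a binary fish/background mask.  The analysis splits
each frame into four equal quadrants (1 = upper-left, 2 = upper-right,
3 = lower-left, 4 = lower-right) and, inside each quadrant, finds the
8-connected components of fish pixels.  Everything downstream (area ratios,
the feeding activity index) is built on these primitives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError

__all__ = [
    "SegmentationMask",
    "Quadrant",
    "ConnectedRegion",
    "split_quadrants",
    "connected_regions",
]

#: 3x3 structuring element giving 8-connectivity (diagonal pixels touch).
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationMask:
    """One frame's binary fish mask.

    Parameters
    ----------
    pixels
        2-D boolean grid, True = fish, row 0 at the image top.  Any array
        castable to bool is accepted; nonzero values count as fish.
    frame_index
        0-based position of the frame in its video sequence.
    """

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise InvalidInputError(
                f"mask pixels must be 2-D, got {arr.ndim} dimension(s)"
            )
        if arr.shape[0] < 2:
            raise InvalidInputError(
                f"mask height must be >= 2 so every quadrant is non-empty, "
                f"got height {arr.shape[0]}"
            )
        if arr.shape[1] < 2:
            raise InvalidInputError(
                f"mask width must be >= 2 so every quadrant is non-empty, "
                f"got width {arr.shape[1]}"
            )
        if self.frame_index < 0:
            raise InvalidInputError(f"frame_index must be >= 0, got {self.frame_index}")
        object.__setattr__(self, "pixels", arr.astype(bool, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def fish_pixel_count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class Quadrant:
    """One of the four sub-images, as half-open pixel spans into the parent.

    Index convention: 1 upper-left, 2 upper-right, 3 lower-left, 4 lower-right.
    """

    index: int
    row_span: tuple[int, int]
    col_span: tuple[int, int]

    @property
    def shape(self) -> tuple[int, int]:
        return (
            self.row_span[1] - self.row_span[0],
            self.col_span[1] - self.col_span[0],
        )


@dataclass(frozen=True)
class ConnectedRegion:
    """A maximal 8-connected component of fish pixels within one quadrant."""

    quadrant_index: int
    area: int
    label: int  # label id in the quadrant's label image


def _as_pixels(mask: "SegmentationMask | np.ndarray") -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.pixels
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2-D grid, got {arr.ndim} dimension(s)")
    return arr.astype(bool, copy=False)


def split_quadrants(
    mask: "SegmentationMask | np.ndarray",
) -> list[tuple[Quadrant, np.ndarray]]:
    """Split a frame into its four quadrants.

    The frame is halved horizontally and vertically.  For odd dimensions the
    top/left halves receive the extra row/column (ceil division), so the four
    spans always tile the frame exactly once.

    Returns a list of ``(Quadrant, sub_mask)`` pairs in index order 1..4;
    each ``sub_mask`` is a view into the parent pixel grid.
    """
    pixels = _as_pixels(mask)
    h, w = pixels.shape
    if h < 2:
        raise InvalidInputError(f"cannot split along the row axis: height {h} < 2")
    if w < 2:
        raise InvalidInputError(f"cannot split along the column axis: width {w} < 2")
    rm = (h + 1) // 2  # top half takes the extra row
    cm = (w + 1) // 2  # left half takes the extra column
    spans = [
        (1, (0, rm), (0, cm)),
        (2, (0, rm), (cm, w)),
        (3, (rm, h), (0, cm)),
        (4, (rm, h), (cm, w)),
    ]
    return [
        (Quadrant(i, rs, cs), pixels[rs[0] : rs[1], cs[0] : cs[1]])
        for i, rs, cs in spans
    ]


def connected_regions(
    sub_mask: np.ndarray, quadrant_index: int
) -> list[ConnectedRegion]:
    """Find the 8-connected fish components inside one quadrant's sub-mask.

    Components are computed after cropping, so a fish straddling a quadrant
    border contributes one component to each side.  Returns an empty list for
    an all-background sub-mask; the areas always sum to the sub-mask's fish
    pixel count.
    """
    pixels = _as_pixels(sub_mask)
    labels, n_labels = ndimage.label(pixels, structure=EIGHT_CONNECTED)
    if n_labels == 0:
        return []
    areas = np.bincount(labels.ravel(), minlength=n_labels + 1)[1:]
    return [
        ConnectedRegion(quadrant_index=quadrant_index, area=int(a), label=lab)
        for lab, a in enumerate(areas, start=1)
    ]
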