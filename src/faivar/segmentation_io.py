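"""Mask file I/O, the pluggable segmenter contract and the ECA block.

Masks travel as 8-bit PNGs: either grayscale (0 = background, any nonzero
value = fish) or indexed/palette label images in the PASCAL-VOC style, where
one palette index (default 1) is the fish class.  The upstream segmentation
model is deliberately pluggable — anything satisfying
:class:`SegmenterContract` (a callable mapping one image frame to a same-size
binary :class:`~faivar.mask_model.SegmentationMask`) can feed the pipeline.
A simple intensity-threshold segmenter is provided as the reference
implementation for synthetic data.

The module also ships ECA (Efficient Channel Attention) as a standalone,
fixed-weight numeric block: per-channel global average pooling, a 1-D
convolution across each channel's k neighboring channel descriptors (zero
padding at the channel ends), a sigmoid gate, and channel-wise rescaling.
It is provided as a verified building block and interface example; training
it inside a segmentation network is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import metadata as importlib_metadata
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from PIL import Image

from .errors import InvalidConfigError, InvalidInputError, MaskFormatError
from .mask_model import SegmentationMask

__all__ = [
    "SegmenterContract",
    "ECAParams",
    "read_mask",
    "write_mask",
    "load_mask_dir",
    "threshold_segmenter",
    "make_threshold_segmenter",
    "eca_attention",
    "adaptive_kernel_size",
    "load_segmenter",
]

#: entry-point group external packages register segmenters under.
SEGMENTER_ENTRY_POINT_GROUP = "faivar.segmenters"

DEFAULT_FISH_CLASS = 1


@runtime_checkable
class SegmenterContract(Protocol):
    """A segmenter maps one image frame to a binary mask of equal size."""

    def __call__(self, frame: np.ndarray) -> SegmentationMask: ...


def read_mask(
    path: "Path | str",
    fish_class: int = DEFAULT_FISH_CLASS,
    frame_index: int = 0,
) -> SegmentationMask:
    """Read one mask PNG.

    Grayscale images: nonzero pixels are fish.  Palette images: pixels equal
    to ``fish_class`` are fish.  RGB images are rejected with a hint to
    convert them to a label format first.
    """
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except (OSError, ValueError) as exc:
        raise MaskFormatError(f"cannot read mask file {path}: {exc}") from exc
    if img.mode == "P":
        arr = np.asarray(img)
        pixels = arr == fish_class
    elif img.mode in ("L", "1", "I", "I;16"):
        arr = np.asarray(img)
        pixels = arr != 0
    else:
        raise MaskFormatError(
            f"{path}: unsupported image mode {img.mode!r}; convert RGB frames "
            "to a grayscale or palette label image first"
        )
    return SegmentationMask(pixels, frame_index=frame_index)


def write_mask(
    mask: SegmentationMask,
    path: "Path | str",
    palette: bool = False,
    fish_class: int = DEFAULT_FISH_CLASS,
) -> None:
    """Write a mask as PNG: grayscale 0/255 by default, or a palette label
    image with fish pixels set to ``fish_class``."""
    path = Path(path)
    if palette:
        arr = np.where(mask.pixels, np.uint8(fish_class), np.uint8(0))
        img = Image.fromarray(arr, mode="P")
        # minimal VOC-style palette: background black, fish class a color
        pal = [0] * 768
        pal[3 * fish_class : 3 * fish_class + 3] = [128, 0, 0]
        img.putpalette(pal)
    else:
        img = Image.fromarray(np.where(mask.pixels, np.uint8(255), np.uint8(0)), "L")
    img.save(path, format="PNG")


def load_mask_dir(
    directory: "Path | str", fish_class: int = DEFAULT_FISH_CLASS
) -> list[SegmentationMask]:
    """Load every ``*.png`` in a directory in lexicographic filename order,
    assigning 0-based frame indices in that order."""
    directory = Path(directory)
    if not directory.is_dir():
        raise MaskFormatError(f"not a directory: {directory}")
    paths = sorted(directory.glob("*.png"), key=lambda p: p.name)
    return [
        read_mask(p, fish_class=fish_class, frame_index=i)
        for i, p in enumerate(paths)
    ]


def threshold_segmenter(
    frame: np.ndarray,
    threshold: float,
    invert: bool = False,
    frame_index: int = 0,
) -> SegmentationMask:
    """Baseline segmenter: pixels brighter than ``threshold`` are fish
    (``invert=True`` for dark fish on a bright background)."""
    arr = np.asarray(frame)
    if arr.ndim != 2:
        raise MaskFormatError(
            f"threshold segmenter needs a single-channel image, got shape {arr.shape}"
        )
    pixels = arr < threshold if invert else arr > threshold
    return SegmentationMask(pixels, frame_index=frame_index)


def make_threshold_segmenter(
    threshold: float, invert: bool = False
) -> Callable[[np.ndarray], SegmentationMask]:
    """Bind a threshold into a callable satisfying :class:`SegmenterContract`."""

    def segmenter(frame: np.ndarray) -> SegmentationMask:
        return threshold_segmenter(frame, threshold, invert=invert)

    return segmenter


def load_segmenter(name: str) -> SegmenterContract:
    """Look up an externally registered segmenter by entry-point name."""
    eps = importlib_metadata.entry_points(group=SEGMENTER_ENTRY_POINT_GROUP)
    for ep in eps:
        if ep.name == name:
            return ep.load()
    raise InvalidConfigError(
        f"no segmenter named {name!r} registered under entry-point group "
        f"{SEGMENTER_ENTRY_POINT_GROUP!r}"
    )


# --------------------------------------------------------------------------
# ECA: Efficient Channel Attention
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ECAParams:
    """Fixed weights for the ECA block: an odd-length 1-D cross-channel
    kernel."""

    kernel: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.kernel)
        if k == 0 or k % 2 == 0:
            raise InvalidConfigError(f"ECA kernel size must be odd, got {k}")
        object.__setattr__(self, "kernel", tuple(float(w) for w in self.kernel))

    @property
    def kernel_size(self) -> int:
        return len(self.kernel)


def adaptive_kernel_size(n_channels: int, gamma: int = 2, b: int = 1) -> int:
    """Channel-adaptive kernel size: nearest odd integer to
    ``log2(C)/gamma + b/gamma``."""
    if n_channels < 1:
        raise InvalidConfigError(f"n_channels must be >= 1, got {n_channels}")
    k = int(abs((np.log2(n_channels) + b) / gamma))
    return max(k if k % 2 == 1 else k + 1, 1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def eca_attention(
    channel_maps: np.ndarray, params: "ECAParams | np.ndarray | tuple"
) -> np.ndarray:
    """Apply ECA channel attention to a (C, H, W) stack of channel maps.

    Per channel c: ``g_c`` = spatial mean of channel c; the gate is
    ``a_c = sigmoid(sum_j w_j * g_{c+j-(k-1)//2})`` with zero padding at the
    channel ends; the output channel is ``a_c * input_c``.  Gates lie
    strictly in (0, 1); shape and channel count are preserved.
    """
    if not isinstance(params, ECAParams):
        params = ECAParams(tuple(np.atleast_1d(np.asarray(params, dtype=float))))
    maps = np.asarray(channel_maps, dtype=float)
    if maps.ndim != 3:
        raise InvalidInputError(
            f"channel maps must have shape (C, H, W), got {maps.shape}"
        )
    means = maps.mean(axis=(1, 2))
    kernel = np.asarray(params.kernel)
    # ECA's indexing g_{c+j-(k-1)/2} is a correlation with zero padding at
    # the channel ends; pad explicitly (robust for k > C) and pre-flip the
    # kernel since np.convolve flips its second argument.
    half = (params.kernel_size - 1) // 2
    padded = np.pad(means, half)
    pre_activation = np.convolve(padded, kernel[::-1], mode="valid")
    gates = _sigmoid(pre_activation)
    return gates[:, None, None] * maps
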