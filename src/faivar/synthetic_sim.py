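"""Agent-based fish-school simulator producing mask sequences with ground truth.

The simulator emulates the overhead/side view of a feeding trial in a
rectangular tank: N fish of elliptical footprint move through four behavioral
phases —

* WANDER    independent uniform random steps (calm pre-feeding swimming),
* GATHER    rapid directed motion toward a bait point (bait has been cast),
* FEED      low-amplitude jitter inside a cluster radius around the bait,
* DISPERSE  radial motion away from the bait back to wandering.

Ground-truth labels mark GATHER and FEED frames as FEEDING (bait is already
in the water during the approach) and WANDER/DISPERSE as NON_FEEDING.  Fish
are independent ellipses; overlap is allowed and frequent during feeding —
that occlusion is exactly the regime a mask-level method must tolerate.
Boundaries reflect, so the fish count is constant and total fish area varies
only through overlap and edge clipping.

One global random stream, seeded from the config, is consumed in a fixed
per-frame order (motion first, then a speckle field that is drawn even when
the speckle rate is zero), so enabling speckle noise does not perturb
trajectories.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from skimage.draw import ellipse as draw_ellipse

from .errors import InvalidConfigError
from .mask_model import SegmentationMask
from .temporal_classifier import FeedingState

__all__ = [
    "SimulationConfig",
    "SimulatedSequence",
    "PHASES",
    "simulate",
    "render_grayscale",
    "write_sequence",
]

PHASES = ("WANDER", "GATHER", "FEED", "DISPERSE")

#: truth label per phase: bait is present from the start of GATHER.
PHASE_LABEL = {
    "WANDER": FeedingState.NON_FEEDING,
    "GATHER": FeedingState.FEEDING,
    "FEED": FeedingState.FEEDING,
    "DISPERSE": FeedingState.NON_FEEDING,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a simulated feeding trial.

    Defaults describe a 256x256 view of a school of 30 fish (each an ellipse
    of 12-18 px semi-major, 5-8 px semi-minor axis) over a 400-frame episode:
    120 wander, 60 gather, 140 feed, 80 disperse, with the bait point in the
    lower-right quadrant.  Speeds are pixels per frame.
    """

    height: int = 256
    width: int = 256
    n_fish: int = 30
    semi_major: tuple[float, float] = (12.0, 18.0)
    semi_minor: tuple[float, float] = (5.0, 8.0)
    wander_frames: int = 120
    gather_frames: int = 60
    feed_frames: int = 140
    disperse_frames: int = 80
    bait_point: tuple[float, float] = (192.0, 192.0)  # (row, col)
    wander_step: float = 3.0
    gather_speed: float = 6.0
    feed_jitter: float = 1.5
    disperse_speed: float = 4.0
    feed_radius: float = 40.0
    speckle_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise InvalidConfigError(
                f"frame must be at least 2x2, got {self.height}x{self.width}"
            )
        if self.n_fish < 0:
            raise InvalidConfigError(f"n_fish must be >= 0, got {self.n_fish}")
        for name in ("semi_major", "semi_minor"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise InvalidConfigError(f"{name} range must satisfy 0 < lo <= hi")
        if 2 * self.semi_major[1] >= min(self.height, self.width):
            raise InvalidConfigError(
                f"fish of semi-major axis {self.semi_major[1]} px do not fit in a "
                f"{self.height}x{self.width} frame"
            )
        if self.n_frames < 1:
            raise InvalidConfigError("phase frame counts must sum to >= 1")
        for name in (
            "wander_frames",
            "gather_frames",
            "feed_frames",
            "disperse_frames",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        r, c = self.bait_point
        if not (0 <= r < self.height and 0 <= c < self.width):
            raise InvalidConfigError(
                f"bait point {self.bait_point} lies outside the "
                f"{self.height}x{self.width} frame"
            )
        if not (0 <= self.speckle_rate < 1):
            raise InvalidConfigError(
                f"speckle_rate must lie in [0, 1), got {self.speckle_rate}"
            )
        for name in ("wander_step", "gather_speed", "feed_jitter", "disperse_speed"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.feed_radius <= 0:
            raise InvalidConfigError("feed_radius must be > 0")

    @property
    def n_frames(self) -> int:
        return (
            self.wander_frames
            + self.gather_frames
            + self.feed_frames
            + self.disperse_frames
        )

    @property
    def phase_sequence(self) -> list[str]:
        """Phase name of every frame, in order."""
        return (
            ["WANDER"] * self.wander_frames
            + ["GATHER"] * self.gather_frames
            + ["FEED"] * self.feed_frames
            + ["DISPERSE"] * self.disperse_frames
        )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        """Build a config from a plain dict (e.g. parsed YAML), rejecting
        unknown keys by name."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {', '.join(unknown)}")
        coerced = dict(mapping)
        for key in ("semi_major", "semi_minor", "bait_point"):
            if key in coerced and isinstance(coerced[key], list):
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("semi_major", "semi_minor", "bait_point"):
            d[key] = list(d[key])
        return d


@dataclass(frozen=True)
class SimulatedSequence:
    """Output of one simulation run: masks, truth labels, phases, config."""

    masks: list[SegmentationMask]
    truth_labels: list[FeedingState]
    phases: list[str] = field(default_factory=list)
    config: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not (len(self.masks) == len(self.truth_labels) == len(self.phases)):
            raise InvalidConfigError(
                "masks, truth_labels and phases must have equal lengths"
            )


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions back into [lo, hi] by mirror reflection."""
    span = hi - lo
    v = np.mod(values - lo, 2.0 * span)
    return lo + np.where(v > span, 2.0 * span - v, v)


def _render_mask(
    pos: np.ndarray,
    semi_major: np.ndarray,
    semi_minor: np.ndarray,
    angles: np.ndarray,
    shape: tuple[int, int],
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for (r, c), a, b, th in zip(pos, semi_major, semi_minor, angles):
        rr, cc = draw_ellipse(r, c, a, b, shape=shape, rotation=th)
        mask[rr, cc] = True
    return mask


def simulate(config: SimulationConfig | None = None) -> SimulatedSequence:
    """Run the phase-structured school simulation.

    Deterministic for a fixed config (including its seed): the same config
    yields bit-identical mask sequences.
    """
    cfg = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fish
    shape = (cfg.height, cfg.width)
    bait = np.asarray(cfg.bait_point, dtype=float)

    pos = rng.uniform((0.0, 0.0), (cfg.height - 1.0, cfg.width - 1.0), size=(n, 2))
    angles = rng.uniform(0.0, np.pi, size=n)
    a = rng.uniform(*cfg.semi_major, size=n)
    b = rng.uniform(*cfg.semi_minor, size=n)
    # Per-fish feeding station inside the cluster.  Radii are sampled
    # linearly (not area-uniformly), packing the school densest at the bait
    # point the way fish crowd the food itself; a centrally dense pack also
    # stays one connected blob instead of fragmenting into marginal lobes.
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    radius = cfg.feed_radius * rng.uniform(0.0, 1.0, size=n)
    home = bait + radius[:, None] * np.column_stack([np.sin(theta), np.cos(theta)])

    masks: list[SegmentationMask] = []
    phases = cfg.phase_sequence
    for t, phase in enumerate(phases):
        if n > 0:
            if phase == "WANDER":
                pos = pos + rng.uniform(-cfg.wander_step, cfg.wander_step, (n, 2))
            elif phase == "GATHER":
                delta = home - pos
                dist = np.maximum(np.linalg.norm(delta, axis=1), 1e-9)
                step = np.minimum(cfg.gather_speed, dist)
                pos = pos + delta / dist[:, None] * step[:, None]
                pos = pos + rng.normal(0.0, 0.5, (n, 2))
            elif phase == "FEED":
                # mean-reverting jitter around each fish's feeding station:
                # the school holds its shape instead of diffusing into lobes
                pos = pos + rng.uniform(-cfg.feed_jitter, cfg.feed_jitter, (n, 2))
                pos = pos + 0.15 * (home - pos)
                delta = pos - bait
                dist = np.maximum(np.linalg.norm(delta, axis=1), 1e-9)
                over = dist > cfg.feed_radius
                scale = np.where(over, cfg.feed_radius / dist, 1.0)
                pos = bait + delta * scale[:, None]
            else:  # DISPERSE
                delta = pos - bait
                dist = np.maximum(np.linalg.norm(delta, axis=1), 1e-9)
                pos = pos + delta / dist[:, None] * cfg.disperse_speed
                pos = pos + rng.uniform(-cfg.wander_step, cfg.wander_step, (n, 2))
            pos = np.column_stack(
                [
                    _reflect(pos[:, 0], 0.0, cfg.height - 1.0),
                    _reflect(pos[:, 1], 0.0, cfg.width - 1.0),
                ]
            )
            frame = _render_mask(pos, a, b, angles, shape)
        else:
            frame = np.zeros(shape, dtype=bool)
        # speckle field is drawn every frame regardless of rate, so toggling
        # noise never perturbs the motion draws that follow
        speckle = rng.random(shape)
        if cfg.speckle_rate > 0:
            frame = frame ^ (speckle < cfg.speckle_rate)
        masks.append(SegmentationMask(frame, frame_index=t))

    labels = [PHASE_LABEL[p] for p in phases]
    return SimulatedSequence(masks=masks, truth_labels=labels, phases=phases, config=cfg)


def render_grayscale(
    sequence: SimulatedSequence,
    fish_intensity: float = 200.0,
    background_intensity: float = 50.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Render masks as grayscale frames (float arrays, clipped to [0, 255]).

    With ``noise_sd == 0``, thresholding a frame at the midpoint between the
    two intensities recovers the mask exactly.
    """
    if fish_intensity == background_intensity:
        raise InvalidConfigError(
            "fish and background intensities must be distinct "
            f"(both {fish_intensity})"
        )
    rng = np.random.default_rng(seed)
    frames = []
    for mask in sequence.masks:
        img = np.where(mask.pixels, float(fish_intensity), float(background_intensity))
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames.append(np.clip(img, 0.0, 255.0))
    return frames


def write_sequence(sequence: SimulatedSequence, out_dir: "Path | str") -> None:
    """Write a run to disk: numbered mask PNGs, truth.csv and a config echo."""
    from .segmentation_io import write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mask in sequence.masks:
        write_mask(mask, out / f"{mask.frame_index:05d}.png")
    with open(out / "truth.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "label"])
        for mask, label in zip(sequence.masks, sequence.truth_labels):
            writer.writerow([mask.frame_index, label.value])
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(sequence.config.to_mapping(), fh, sort_keys=False)
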