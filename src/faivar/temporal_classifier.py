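"""Rolling FAI history, threshold rule and the feeding state machine.

The bare decision rule — "feeding iff FAIvar exceeds a threshold" — cannot by
itself reproduce a full feeding episode: FAIvar is near zero both during calm
wandering and during quiet clustered feeding, and it spikes both at feeding
onset (aggregation) and at the end (dispersal).  The classifier therefore
treats above-threshold spikes as *transitions*, disambiguated by the
concentration trend: the change in the school's peak quadrant FAI
(``max_i FAI_i`` now minus ``max_i FAI_i`` at lag L).  A rising peak means
fish are piling into one region; a falling peak means the crowded region is
emptying.  (When the same quadrant is dominant at both times this equals
that quadrant's own FAI change; taking the max at each time separately keeps
the sign right in the brief window where dominance hands over from the
emptying bait quadrant to a filling neighbour.)

* from NON_FEEDING, an above-threshold spike with a rising peak starts a
  feeding episode (aggregation);
* from FEEDING, an above-threshold spike with a falling peak ends it
  (dispersal);
* either transition additionally requires the peak change to carry the
  spike: |trend| >= sqrt(FAIvar), the RMS dispersion of the four lagged
  differences.  At a real onset or offset the crowded quadrant's change is
  the dominant difference, so this always holds; it fails precisely for
  borderline spikes whose variance comes from diffuse multi-quadrant
  drift with a near-flat peak, which are not aggregation events;
* below-threshold frames never change state, so quiet mid-feeding frames stay
  FEEDING and calm wandering stays NON_FEEDING;
* a contiguous above-threshold run triggers at most one transition: after a
  transition fires the machine is disarmed until FAIvar falls back below the
  threshold.  A variance spike is one event — without this, the tail of a
  dispersal spike (when another quadrant briefly becomes dominant and is
  still gaining FAI) would immediately re-trigger a phantom onset.

The first L frames of a sequence are labelled UNKNOWN (warm-up): the lag-L
difference is undefined there.  A ``raw-threshold`` mode implementing the
bare rule (feeding iff above threshold) is available for comparison.

Defaults are lag = 20 frames and threshold = 100; both are per-deployment
parameters — a calmer species warrants a longer lag, an intensely feeding
one a different threshold (50 is a typical value for small, fast feeders).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import InvalidConfigError, InvalidInputError, SequencingError
from .faivar_core import FrameFAI, faivar
from .mask_model import SegmentationMask

__all__ = [
    "FeedingState",
    "FeedingDecision",
    "FAISeriesBuffer",
    "FeedingAnalyzer",
    "push_frame",
    "decide",
    "label_sequence",
    "feeding_episodes",
]

DEFAULT_LAG = 20
DEFAULT_THRESHOLD = 100.0

MODES = ("state-machine", "raw-threshold")


class FeedingState(str, Enum):
    UNKNOWN = "UNKNOWN"
    NON_FEEDING = "NON_FEEDING"
    FEEDING = "FEEDING"


@dataclass(frozen=True)
class FeedingDecision:
    """The per-frame classification outcome.

    ``faivar_value`` and ``trend`` are ``None`` during warm-up.  ``trend`` is
    the signed change of the peak quadrant FAI over the lag window;
    ``dominant_quadrant`` is the quadrant with the highest FAI this frame
    (ties broken by lowest index).
    """

    frame_index: int
    faivar_value: float | None
    threshold: float
    above_threshold: bool
    state: FeedingState
    dominant_quadrant: int
    trend: float | None


class FAISeriesBuffer:
    """Bounded history of the most recent ``lag + 1`` FrameFAI records.

    Records must be strictly consecutive in frame index; the lagged variance
    is computable once the buffer is full.
    """

    def __init__(self, lag: int = DEFAULT_LAG):
        if lag < 1:
            raise InvalidConfigError(f"lag must be >= 1 frame, got {lag}")
        self.lag = int(lag)
        self._frames: deque[FrameFAI] = deque(maxlen=self.lag + 1)

    def __len__(self) -> int:
        return len(self._frames)

    @property
    def full(self) -> bool:
        return len(self._frames) == self.lag + 1

    @property
    def current(self) -> FrameFAI:
        if not self._frames:
            raise InvalidInputError("buffer is empty")
        return self._frames[-1]

    @property
    def lagged(self) -> FrameFAI:
        """The frame ``lag`` frames before the current one."""
        if not self.full:
            raise InvalidInputError(
                f"lagged frame undefined: buffer holds {len(self)} of "
                f"{self.lag + 1} records (warm-up)"
            )
        return self._frames[0]

    def push(self, frame: FrameFAI) -> "FAISeriesBuffer":
        if self._frames:
            expected = self._frames[-1].frame_index + 1
            if frame.frame_index != expected:
                raise SequencingError(
                    f"non-consecutive frame: expected index {expected}, "
                    f"got {frame.frame_index}"
                )
        self._frames.append(frame)
        return self


def push_frame(buffer: FAISeriesBuffer, frame: FrameFAI) -> FAISeriesBuffer:
    """Append ``frame`` to ``buffer``, evicting the oldest record when full."""
    return buffer.push(frame)


def _dominant_quadrant(frame: FrameFAI) -> int:
    fai = frame.fai_by_quadrant
    return 1 + max(range(4), key=lambda i: (fai[i], -i))


def decide(
    buffer: FAISeriesBuffer,
    threshold: float,
    previous_state: FeedingState = FeedingState.UNKNOWN,
    mode: str = "state-machine",
    armed: bool = True,
) -> FeedingDecision:
    """Classify the buffer's current frame.

    During warm-up the state is UNKNOWN.  Afterwards FAIvar is computed from
    the current and lag-L frames and the state machine described in the
    module docstring is applied; ``mode="raw-threshold"`` instead labels
    FEEDING iff FAIvar exceeds the threshold.  ``armed=False`` suppresses
    transitions (the spike already produced one); the streaming analyzer
    manages this flag, re-arming on below-threshold frames.
    """
    if threshold <= 0:
        raise InvalidInputError(f"threshold must be > 0, got {threshold}")
    if mode not in MODES:
        raise InvalidInputError(f"mode must be one of {MODES}, got {mode!r}")
    current = buffer.current
    dominant = _dominant_quadrant(current)
    if not buffer.full:
        return FeedingDecision(
            frame_index=current.frame_index,
            faivar_value=None,
            threshold=threshold,
            above_threshold=False,
            state=FeedingState.UNKNOWN,
            dominant_quadrant=dominant,
            trend=None,
        )
    result = faivar(current, buffer.lagged, buffer.lag)
    above = result.variance > threshold
    trend = max(current.fai_by_quadrant) - max(buffer.lagged.fai_by_quadrant)
    if mode == "raw-threshold":
        state = FeedingState.FEEDING if above else FeedingState.NON_FEEDING
    else:
        state = previous_state
        coherent = abs(trend) >= result.variance**0.5
        if above and armed and coherent:
            if previous_state is FeedingState.FEEDING:
                if trend < 0:
                    state = FeedingState.NON_FEEDING  # dispersal spike
            elif trend > 0:
                state = FeedingState.FEEDING  # onset spike
        # below-threshold frames retain the previous state
        if state is FeedingState.UNKNOWN:
            state = FeedingState.NON_FEEDING
    return FeedingDecision(
        frame_index=current.frame_index,
        faivar_value=result.variance,
        threshold=threshold,
        above_threshold=above,
        state=state,
        dominant_quadrant=dominant,
        trend=trend,
    )


class FeedingAnalyzer:
    """Streaming classifier: feed one frame at a time, get a decision back.

    Accepts either precomputed :class:`FrameFAI` records or raw
    :class:`SegmentationMask` frames (FAI is computed on the fly).
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        lag: int = DEFAULT_LAG,
        mode: str = "state-machine",
    ):
        if threshold <= 0:
            raise InvalidConfigError(f"threshold must be > 0, got {threshold}")
        if mode not in MODES:
            raise InvalidConfigError(f"mode must be one of {MODES}, got {mode!r}")
        self.threshold = float(threshold)
        self.mode = mode
        self.buffer = FAISeriesBuffer(lag)
        self.state = FeedingState.UNKNOWN
        self.armed = True  # False while the current spike has already fired

    @property
    def lag(self) -> int:
        return self.buffer.lag

    def update(self, frame: "FrameFAI | SegmentationMask") -> FeedingDecision:
        if isinstance(frame, SegmentationMask):
            from .faivar_core import frame_fai

            frame = frame_fai(frame)
        push_frame(self.buffer, frame)
        decision = decide(
            self.buffer, self.threshold, self.state, self.mode, armed=self.armed
        )
        fired = decision.above_threshold and (
            (decision.state is FeedingState.FEEDING and self.state is not FeedingState.FEEDING)
            or (self.state is FeedingState.FEEDING and decision.state is FeedingState.NON_FEEDING)
        )
        if fired:
            self.armed = False
        elif not decision.above_threshold:
            self.armed = True
        self.state = decision.state
        return decision


def label_sequence(
    frames: Iterable[FrameFAI],
    threshold: float = DEFAULT_THRESHOLD,
    lag: int = DEFAULT_LAG,
    mode: str = "state-machine",
) -> list[FeedingDecision]:
    """Batch driver: classify an ordered FrameFAI sequence frame by frame."""
    frames = list(frames)
    if not frames:
        raise InvalidInputError("cannot label an empty frame sequence")
    analyzer = FeedingAnalyzer(threshold=threshold, lag=lag, mode=mode)
    return [analyzer.update(f) for f in frames]


def feeding_episodes(
    states: Sequence[FeedingState],
) -> list[tuple[int, int]]:
    """Maximal runs of FEEDING as inclusive ``(start, end)`` index pairs."""
    episodes: list[tuple[int, int]] = []
    start: int | None = None
    for i, s in enumerate(states):
        if s is FeedingState.FEEDING or s == FeedingState.FEEDING:
            if start is None:
                start = i
        elif start is not None:
            episodes.append((start, i - 1))
            start = None
    if start is not None:
        episodes.append((start, len(states) - 1))
    return episodes
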