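"""Rolling buffer, threshold rule and the feeding state machine."""

import math

import numpy as np
import pytest

from conftest import population_mean_var
from faivar import (
    FAISeriesBuffer,
    FeedingAnalyzer,
    FeedingState,
    FrameFAI,
    InvalidInputError,
    SequencingError,
    decide,
    feeding_episodes,
    label_sequence,
    push_frame,
)


def _fai(idx, values):
    return FrameFAI(frame_index=idx, fai_by_quadrant=tuple(values))


def constant_frames(n, values=(10.0, 12.0, 8.0, 9.0)):
    return [_fai(i, values) for i in range(n)]


class TestBuffer:
    def test_push_grows_until_capacity(self):
        buf = FAISeriesBuffer(lag=3)
        for i in range(4):
            push_frame(buf, _fai(i, (0, 0, 0, 0)))
        assert len(buf) == 4 and buf.full
        push_frame(buf, _fai(4, (0, 0, 0, 0)))
        assert len(buf) == 4
        assert buf.lagged.frame_index == 1  # oldest evicted

    def test_non_consecutive_push_rejected(self):
        buf = FAISeriesBuffer(lag=3)
        push_frame(buf, _fai(5, (0, 0, 0, 0)))
        with pytest.raises(SequencingError):
            push_frame(buf, _fai(7, (0, 0, 0, 0)))

    def test_lagged_undefined_during_warmup(self):
        buf = FAISeriesBuffer(lag=3)
        push_frame(buf, _fai(0, (0, 0, 0, 0)))
        with pytest.raises(InvalidInputError):
            _ = buf.lagged


class TestDecide:
    def test_warmup_is_unknown_with_undefined_faivar(self):
        buf = FAISeriesBuffer(lag=20)
        push_frame(buf, _fai(0, (1, 2, 3, 4)))
        d = decide(buf, threshold=100.0)
        assert d.state is FeedingState.UNKNOWN
        assert d.faivar_value is None and d.trend is None
        assert not d.above_threshold

    @pytest.mark.parametrize("threshold", [100.0, 50.0])
    def test_constant_scene_resolves_to_non_feeding(self, threshold):
        """A static school has FAIvar 0, hence NON_FEEDING after warm-up,
        at both deployment thresholds (100 and 50)."""
        decisions = label_sequence(constant_frames(25), threshold=threshold, lag=20)
        assert [d.state for d in decisions[:20]] == [FeedingState.UNKNOWN] * 20
        assert all(d.state is FeedingState.NON_FEEDING for d in decisions[20:])
        assert decisions[20].faivar_value == 0.0

    def test_below_threshold_retains_previous_state(self):
        buf = FAISeriesBuffer(lag=1)
        push_frame(buf, _fai(0, (10, 0, 0, 0)))
        push_frame(buf, _fai(1, (16, 2, 0, 0)))
        _, var = population_mean_var((10 - 16, 0 - 2, 0, 0))
        assert var == pytest.approx(6.0)  # well below both 100 and 50
        for prev in (FeedingState.NON_FEEDING, FeedingState.FEEDING):
            d = decide(buf, threshold=100.0, previous_state=prev)
            assert d.state is prev

    def test_invalid_threshold_rejected(self):
        buf = FAISeriesBuffer(lag=1)
        push_frame(buf, _fai(0, (0, 0, 0, 0)))
        with pytest.raises(InvalidInputError):
            decide(buf, threshold=0.0)

    def test_dominant_quadrant_tie_breaks_to_lowest_index(self):
        buf = FAISeriesBuffer(lag=1)
        push_frame(buf, _fai(0, (5, 5, 5, 5)))
        d = decide(buf, threshold=100.0)
        assert d.dominant_quadrant == 1


def onset_then_quiet_sequence(lag=20, quiet=30):
    """Quadrant 2 ramps 20 -> 120 over the lag window while the others fall,
    then the scene freezes: an onset spike followed by quiet feeding."""
    frames = []
    idx = 0
    for i in range(lag + 1):
        f = 20.0 + 100.0 * i / lag
        others = 30.0 - 20.0 * i / lag
        frames.append(_fai(idx, (others, f, others, others)))
        idx += 1
    last = frames[-1].fai_by_quadrant
    for _ in range(quiet):
        frames.append(_fai(idx, last))
        idx += 1
    return frames


class TestStateMachine:
    def test_onset_spike_then_quiet_feeding_stays_feeding(self):
        frames = onset_then_quiet_sequence(lag=20, quiet=30)
        decisions = label_sequence(frames, threshold=100.0, lag=20)
        # onset frame: variance of the full ramp difference, dominant rising
        onset = decisions[20]
        diffs = np.subtract(frames[0].fai_by_quadrant, frames[20].fai_by_quadrant)
        _, var = population_mean_var(diffs)
        assert onset.faivar_value == pytest.approx(var)
        assert onset.above_threshold and onset.trend > 0
        assert onset.state is FeedingState.FEEDING
        # after the scene freezes for a full lag window, faivar returns to 0
        assert decisions[-1].faivar_value == pytest.approx(0.0)
        assert all(
            d.state is FeedingState.FEEDING for d in decisions[20:]
        ), "quiet mid-feeding frames must retain FEEDING"

    def test_dispersal_spike_ends_episode(self):
        frames = onset_then_quiet_sequence(lag=20, quiet=30)
        idx = len(frames)
        top = frames[-1].fai_by_quadrant
        for i in range(1, 22):
            f = max(top[1] - 6.0 * i, 10.0)
            others = min(top[0] + 2.0 * i, 40.0)
            frames.append(_fai(idx, (others, f, others, others)))
            idx += 1
        decisions = label_sequence(frames, threshold=100.0, lag=20)
        assert decisions[-1].state is FeedingState.NON_FEEDING
        episodes = feeding_episodes([d.state for d in decisions])
        assert len(episodes) == 1

    def test_infinite_threshold_never_feeds(self):
        frames = onset_then_quiet_sequence()
        decisions = label_sequence(frames, threshold=math.inf, lag=20)
        assert all(
            d.state is FeedingState.NON_FEEDING for d in decisions[20:]
        )

    def test_raw_threshold_mode_follows_variance_only(self):
        frames = onset_then_quiet_sequence(lag=20, quiet=30)
        decisions = label_sequence(frames, threshold=100.0, lag=20, mode="raw-threshold")
        for d in decisions[20:]:
            expected = FeedingState.FEEDING if d.above_threshold else FeedingState.NON_FEEDING
            assert d.state is expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            label_sequence([])

    def test_determinism(self):
        frames = onset_then_quiet_sequence()
        a = [d.state for d in label_sequence(frames, threshold=100.0, lag=20)]
        b = [d.state for d in label_sequence(frames, threshold=100.0, lag=20)]
        assert a == b

    def test_threshold_monotonicity(self):
        """Raising the threshold never increases above-threshold frames."""
        frames = onset_then_quiet_sequence()
        counts = []
        for thr in (10.0, 50.0, 100.0, 500.0):
            decisions = label_sequence(frames, threshold=thr, lag=20)
            counts.append(sum(d.above_threshold for d in decisions))
        assert counts == sorted(counts, reverse=True)

    def test_transitions_only_on_above_threshold_frames(self):
        frames = onset_then_quiet_sequence(lag=20, quiet=40)
        decisions = label_sequence(frames, threshold=100.0, lag=20)
        prev = None
        for d in decisions:
            if prev is not None and prev is not FeedingState.UNKNOWN:
                if d.state is not prev:
                    assert d.above_threshold
            prev = d.state

    def test_streaming_matches_batch(self):
        frames = onset_then_quiet_sequence()
        analyzer = FeedingAnalyzer(threshold=100.0, lag=20)
        streamed = [analyzer.update(f).state for f in frames]
        batch = [d.state for d in label_sequence(frames, threshold=100.0, lag=20)]
        assert streamed == batch
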