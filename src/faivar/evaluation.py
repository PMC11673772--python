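"""Frame-level evaluation of predicted feeding labels against ground truth."""

from __future__ import annotations

from typing import Mapping, Sequence

from .errors import InvalidInputError
from .temporal_classifier import FeedingState

__all__ = ["evaluate_labels"]

_FEED = FeedingState.FEEDING.value
_NON = FeedingState.NON_FEEDING.value
_UNK = FeedingState.UNKNOWN.value


def _as_value(label: "FeedingState | str") -> str:
    return label.value if isinstance(label, FeedingState) else str(label)


def evaluate_labels(
    predicted: Sequence["FeedingState | str"],
    truth: Sequence["FeedingState | str"],
    include_unknown: bool = False,
) -> Mapping[str, object]:
    """Compare per-frame predictions with ground truth.

    UNKNOWN (warm-up) predictions are excluded by default;
    ``include_unknown=True`` counts them as NON_FEEDING instead.  Returns
    accuracy, per-class precision/recall, the 2x2 confusion counts, and the
    episode-onset latency: predicted first FEEDING frame minus true first
    FEEDING frame (positive = late detection; None when either sequence has
    no FEEDING frame).
    """
    if len(predicted) != len(truth):
        raise InvalidInputError(
            f"prediction and truth lengths differ: {len(predicted)} vs {len(truth)}"
        )
    pred = [_as_value(p) for p in predicted]
    true = [_as_value(t) for t in truth]
    if include_unknown:
        pred = [_NON if p == _UNK else p for p in pred]
    pairs = [(p, t) for p, t in zip(pred, true) if p != _UNK]
    if not pairs:
        raise InvalidInputError("no labelled frames overlap after excluding warm-up")

    counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for p, t in pairs:
        if p == _FEED and t == _FEED:
            counts["tp"] += 1
        elif p == _FEED:
            counts["fp"] += 1
        elif t == _FEED:
            counts["fn"] += 1
        else:
            counts["tn"] += 1

    def _ratio(num: int, den: int) -> "float | None":
        return num / den if den else None

    tp, fp, fn, tn = counts["tp"], counts["fp"], counts["fn"], counts["tn"]
    first_true = next((i for i, t in enumerate(true) if t == _FEED), None)
    first_pred = next((i for i, p in enumerate(pred) if p == _FEED), None)
    latency = (
        first_pred - first_true
        if first_true is not None and first_pred is not None
        else None
    )
    return {
        "n_evaluated": len(pairs),
        "accuracy": (tp + tn) / len(pairs),
        "precision": {
            _FEED: _ratio(tp, tp + fp),
            _NON: _ratio(tn, tn + fn),
        },
        "recall": {
            _FEED: _ratio(tp, tp + fn),
            _NON: _ratio(tn, tn + fp),
        },
        "confusion": counts,
        "onset_latency_frames": latency,
    }
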