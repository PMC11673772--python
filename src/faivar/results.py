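"""Fixed CSV schema for per-frame analysis results.

One row per frame: ``frame_index, fai_1..fai_4, faivar, label``.  The
``faivar`` cell is empty during warm-up (lagged difference undefined).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import InvalidInputError
from .faivar_core import FrameFAI
from .temporal_classifier import FeedingDecision

__all__ = ["RESULT_COLUMNS", "results_frame", "write_results", "read_results"]

RESULT_COLUMNS = ["frame_index", "fai_1", "fai_2", "fai_3", "fai_4", "faivar", "label"]


def results_frame(
    fais: Sequence[FrameFAI], decisions: Sequence[FeedingDecision]
) -> pd.DataFrame:
    """Assemble per-frame FAI values and decisions into the result table."""
    if len(fais) != len(decisions):
        raise InvalidInputError(
            f"FAI and decision sequences differ in length: {len(fais)} vs {len(decisions)}"
        )
    rows = []
    for fai, dec in zip(fais, decisions):
        if fai.frame_index != dec.frame_index:
            raise InvalidInputError(
                f"frame index mismatch: FAI {fai.frame_index} vs decision {dec.frame_index}"
            )
        f1, f2, f3, f4 = fai.fai_by_quadrant
        rows.append(
            {
                "frame_index": fai.frame_index,
                "fai_1": f1,
                "fai_2": f2,
                "fai_3": f3,
                "fai_4": f4,
                "faivar": dec.faivar_value,
                "label": dec.state.value,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(df: pd.DataFrame, path: "Path | str") -> None:
    df.to_csv(path, index=False)


def read_results(path: "Path | str") -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("frame_index", "label") if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return df
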