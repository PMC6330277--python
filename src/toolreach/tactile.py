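"""Scoring of the tactile arm-length estimation task.

Participants report the perceived distance between two caliper pointers
pressed on the forearm; the physical gap is fixed at 7 cm.  The signed
error (estimate - 7) indexes the represented arm size: negative means
underestimation, positive overestimation.  Seven trials follow each of
the three experimental sessions (after pre-tool-use, after tool-use
training, after post-tool-use), and per-participant session means feed
the 2 x 3 mixed ANOVA downstream.  Estimates are never trimmed.
"""

from __future__ import annotations

import pandas as pd

TRUE_GAP_CM = 7.0

__all__ = ["TRUE_GAP_CM", "tactile_error", "aggregate_session", "score_table"]


def tactile_error(estimate_cm: float, true_gap_cm: float = TRUE_GAP_CM) -> float:
    """Signed estimation error in cm (negative = underestimation)."""
    if estimate_cm < 0:
        raise ValueError("estimate_cm must be >= 0")
    return estimate_cm - true_gap_cm


def aggregate_session(estimates_cm) -> float:
    """Mean signed error over one participant's trials in one session."""
    estimates = list(estimates_cm)
    if not estimates:
        raise ValueError("no tactile trials to aggregate")
    return sum(tactile_error(e) for e in estimates) / len(estimates)


def score_table(tactile: pd.DataFrame, per_hand: bool = False) -> pd.DataFrame:
    """Per-participant session-mean errors from a trial-level table.

    Expects columns ``participant_id, group, session_measurement, hand,
    estimate_cm``; hands are pooled unless ``per_hand``.
    """
    if (tactile["estimate_cm"] < 0).any():
        raise ValueError("negative tactile estimate")
    df = tactile.copy()
    df["error_cm"] = df["estimate_cm"] - TRUE_GAP_CM
    keys = ["participant_id", "group", "session_measurement"]
    if per_hand:
        keys.append("hand")
    return df.groupby(keys, as_index=False, sort=True)["error_cm"].mean()
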