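"""Test-retest overlap of categorized reading-aloud responses.

When the same reader pronounces the same pseudoword in two sessions, the
pair is coded 1 if both sessions gave the same vowel category, or both were
scored incorrect; it is coded 0 if the vowel differed or only one session was
incorrect.  All trials enter the coding, incorrect responses included.  A
participant's overlap is the mean of these codes over their items.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

INCORRECT = "incorrect"


def _outcome(df: pd.DataFrame) -> pd.Series:
    """Collapse each trial to its coded outcome: the response category, or
    ``"incorrect"`` for error trials (consonant errors / non-responses)."""
    return df["response_category"].where(~df["is_error"], INCORRECT)


def code_overlap(df: pd.DataFrame) -> pd.DataFrame:
    """Code session-1 vs session-2 agreement per participant x item.

    Expects a validated response table containing sessions 1 and 2; items
    present in only one session are excluded (count logged).  Returns one row
    per participant x item with columns ``session1_outcome``,
    ``session2_outcome`` and ``agree`` (0/1).
    """
    work = df.copy()
    work["outcome"] = _outcome(work)
    s1 = work[work["session"] == 1].set_index(["participant_id", "item_id"])["outcome"]
    s2 = work[work["session"] == 2].set_index(["participant_id", "item_id"])["outcome"]
    merged = pd.concat(
        {"session1_outcome": s1, "session2_outcome": s2}, axis=1, join="outer"
    )
    unmatched = int(merged.isna().any(axis=1).sum())
    if unmatched:
        log.info("code_overlap: excluded %d item(s) present in one session only",
                 unmatched)
    merged = merged.dropna()
    merged["agree"] = (
        merged["session1_outcome"] == merged["session2_outcome"]
    ).astype(int)
    return merged.reset_index()


def participant_overlap(
    overlaps: pd.DataFrame, grades: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-participant proportion of agreeing items, plus sample summaries.

    Returns ``(per_participant, summary)`` where ``summary`` carries the
    mean, sample SD, min and max of the per-participant proportions, and
    per-grade means/SDs when a participant -> grade mapping is given.
    """
    if overlaps.empty:
        raise ValueError("no overlap records")
    per = (
        overlaps.groupby("participant_id")["agree"]
        .agg(overlap="mean", n_items="size")
        .reset_index()
    )
    vals = per["overlap"].to_numpy()
    summary: dict = {
        "mean": float(vals.mean()),
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n_participants": int(len(vals)),
    }
    if grades:
        per["grade"] = per["participant_id"].map(grades)
        summary["by_grade"] = {
            g: {
                "mean": float(sub["overlap"].mean()),
                "sd": float(sub["overlap"].std(ddof=1)) if len(sub) > 1 else float("nan"),
                "n": int(len(sub)),
            }
            for g, sub in per.groupby("grade")
        }
    return per, summary
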