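"""Shannon entropy of categorical response distributions.

Entropy in bits quantifies response diversity: H = 0 when every included
trial carries the same response, log2(k) for a uniform spread over k
categories.  Item-level entropy measures how much readers disagree about one
pseudoword; participant-level entropy measures how variably one reader
pronounces the critical grapheme across items.

Inclusion rules differ by design: English-style entropies are computed over
all consonant-correct trials (every distinct transcribed vowel label is its
own category, including unmodeled vowels), German-style entropies over
correct trials only, so they are at most 1 bit (binary short/long outcome).
No small-sample bias correction is applied — the plug-in estimator is used.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .design import ENGLISH_STYLE, StudyDesign

log = logging.getLogger(__name__)


def shannon_entropy(distribution: Mapping[object, float]) -> float:
    """Shannon entropy, in bits, of a distribution given as counts or
    probabilities (normalised internally); 0*log2(0) is taken as 0."""
    vals = np.asarray(list(distribution.values()), dtype=float)
    if vals.size == 0 or (vals < 0).any() or vals.sum() <= 0:
        raise ValueError("distribution needs nonnegative values with positive sum")
    p = vals / vals.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 avoids returning -0.0


def _included(df: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    if design.language_mode == ENGLISH_STYLE:
        # only consonant errors / non-responses are excluded; every
        # transcribed vowel (modeled or not) counts as a category
        return df[df["consonant_correct"]]
    return df[~df["is_error"]]


def _entropy_rows(
    df: pd.DataFrame, design: StudyDesign, key_cols: list[str]
) -> pd.DataFrame:
    rows = []
    for key, sub in df.groupby(key_cols, sort=True):
        counts = sub["response_category"].value_counts()
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            {
                **dict(zip(key_cols, key)),
                "n_trials": int(counts.sum()),
                "n_categories": int((counts > 0).sum()),
                "entropy_bits": shannon_entropy(counts.to_dict()),
            }
        )
    return pd.DataFrame(rows)


def item_entropy(
    df: pd.DataFrame,
    design: StudyDesign,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Per-item response entropy over included trials, optionally split by a
    grouping column (e.g. grade); items with no includable trials in a group
    are omitted with a log message."""
    inc = _included(df, design)
    if inc.empty:
        log.warning("item_entropy: no includable trials")
        return pd.DataFrame(
            columns=["item_id", "condition", "n_trials", "n_categories", "entropy_bits"]
        )
    key_cols = ["item_id", "condition"]
    if group_by is not None:
        if group_by not in df.columns:
            raise ValueError(f"group_by column {group_by!r} not in table")
        key_cols = [group_by] + key_cols
    out = _entropy_rows(inc, design, key_cols)
    n_dropped = df["item_id"].nunique() - out["item_id"].nunique()
    if n_dropped:
        log.info("item_entropy: %d item(s) had no includable trials", n_dropped)
    return out


def condition_entropy_summary(item_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of item entropies per condition (and per group
    column if present) — the usual condition-level entropy table."""
    keys = [c for c in ("grade", "group") if c in item_table.columns] + ["condition"]
    agg = item_table.groupby(keys)["entropy_bits"].agg(
        mean="mean", sd=lambda s: s.std(ddof=1), n_items="size"
    )
    return agg.reset_index()


def participant_entropy(
    df: pd.DataFrame,
    design: StudyDesign,
    per_condition: bool = False,
) -> pd.DataFrame:
    """Per-participant response entropy over included trials.

    With ``per_condition=False`` one row per participant (their overall
    response diversity); with ``per_condition=True`` one row per participant
    x condition.
    """
    inc = _included(df, design)
    if inc.empty:
        log.warning("participant_entropy: no includable trials")
        return pd.DataFrame(
            columns=["participant_id", "n_trials", "n_categories", "entropy_bits"]
        )
    key_cols = ["participant_id"] + (["condition"] if per_condition else [])
    return _entropy_rows(inc, design, key_cols)
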