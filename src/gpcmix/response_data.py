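"""Trial-level response tables: I/O, validation, preprocessing filters and
condition summaries.

Responses live in a pandas DataFrame with one row per participant x item x
session, columns::

    participant_id, grade, item_id, condition, session,
    response_category, consonant_correct, is_error

``is_error`` marks trials excluded from entropy and model fitting — for
English-style designs these are consonant errors and non-responses (other
vowel responses are valid), for German-style designs consonant *and* vowel
errors and non-responses.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StudyDesign

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "participant_id",
    "grade",
    "item_id",
    "condition",
    "session",
    "response_category",
    "consonant_correct",
    "is_error",
)

_BOOL_MAP = {
    True: True, False: False, "True": True, "False": False,
    "true": True, "false": False, 1: True, 0: False, "1": True, "0": False,
}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def validate_responses(df: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Validate a response table against a design; returns a normalised copy.

    Raises ``ValueError`` on a missing required column, an unknown condition
    or category label (naming the offending row), or a duplicated
    (participant, item, session) triple.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        log.warning("ignoring unknown columns: %s", extra)
    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in ("consonant_correct", "is_error"):
        out[col] = out[col].map(_BOOL_MAP)
        if out[col].isna().any():
            row = int(out.index[out[col].isna()][0])
            raise ValueError(f"row {row}: non-boolean value in column {col!r}")
        out[col] = out[col].astype(bool)
    out["grade"] = out["grade"].astype(int)
    out["session"] = out["session"].astype(int)

    bad_cond = ~out["condition"].isin(design.conditions)
    if bad_cond.any():
        row = int(out.index[bad_cond][0])
        raise ValueError(
            f"row {row}: unknown condition {out.loc[row, 'condition']!r} "
            f"(expected one of {list(design.conditions)})"
        )
    bad_cat = ~out["response_category"].isin(design.valid_categories)
    if bad_cat.any():
        row = int(out.index[bad_cat][0])
        raise ValueError(
            f"row {row}: unknown response category "
            f"{out.loc[row, 'response_category']!r}"
        )
    dup = out.duplicated(subset=["participant_id", "item_id", "session"])
    if dup.any():
        row = int(out.index[dup][0])
        raise ValueError(
            f"row {row}: duplicate (participant, item, session) triple "
            f"({out.loc[row, 'participant_id']!r}, {out.loc[row, 'item_id']!r}, "
            f"{out.loc[row, 'session']})"
        )
    return out


def read_responses(path, design: StudyDesign) -> pd.DataFrame:
    """Read a delimited response table (CSV/TSV by extension) and validate it.

    Row order is preserved; unknown columns are dropped with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return validate_responses(df, design)


def write_responses(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


def _error_rates(df: pd.DataFrame, key: str) -> pd.Series:
    return df.groupby(key)["is_error"].mean()


def filter_participants(
    df: pd.DataFrame, max_error_rate: float = 0.5
) -> tuple[pd.DataFrame, list[str]]:
    """Remove participants whose error-trial proportion is *strictly* greater
    than ``max_error_rate`` (a participant at exactly the threshold is kept).

    Returns the kept rows and the sorted list of removed participant ids.
    """
    if not 0.0 <= max_error_rate <= 1.0:
        raise ValueError("max_error_rate must be in [0, 1]")
    if df.empty:
        return df, []
    rates = _error_rates(df, "participant_id")
    removed = sorted(rates.index[rates > max_error_rate])
    kept = df[~df["participant_id"].isin(removed)]
    if removed:
        log.info("removed %d participant(s) with error rate > %.0f%%: %s",
                 len(removed), 100 * max_error_rate, removed)
    return kept, removed


def filter_items(
    df: pd.DataFrame, max_error_rate: float = 0.6
) -> tuple[pd.DataFrame, list[str]]:
    """Remove items whose error rate is strictly greater than
    ``max_error_rate``; analogous to :func:`filter_participants`."""
    if not 0.0 <= max_error_rate <= 1.0:
        raise ValueError("max_error_rate must be in [0, 1]")
    if df.empty:
        return df, []
    rates = _error_rates(df, "item_id")
    removed = sorted(rates.index[rates > max_error_rate])
    kept = df[~df["item_id"].isin(removed)]
    if removed:
        log.info("removed %d item(s) with error rate > %.0f%%: %s",
                 len(removed), 100 * max_error_rate, removed)
    return kept, removed


def apply_filters(
    df: pd.DataFrame,
    participant_max_error: float = 0.5,
    item_max_error: float = 0.6,
) -> tuple[pd.DataFrame, dict]:
    """The preprocessing pipeline's filter step.

    Both error rates are computed on the unfiltered table (making the result
    independent of application order); removal is participants first, then
    items.
    """
    _, bad_participants = filter_participants(df, participant_max_error)
    _, bad_items = filter_items(df, item_max_error)
    kept = df[
        ~df["participant_id"].isin(bad_participants) & ~df["item_id"].isin(bad_items)
    ]
    report = {"removed_participants": bad_participants, "removed_items": bad_items}
    return kept, report


def condition_summary(
    df: pd.DataFrame,
    design: StudyDesign,
    group_by: str | None = "grade",
    percentages: bool | None = None,
) -> pd.DataFrame:
    """Mean (SD) response counts or percentages per condition x category.

    Per participant, trials in each condition are tallied by response
    category (all valid categories, errors included); the table reports the
    mean and sample SD of those tallies across participants, within each
    level of ``group_by`` (``None`` pools the whole sample).  German-style
    designs default to percentages because trial counts may differ across
    conditions; English-style defaults to raw counts.

    Returns a long-format frame with columns ``group, condition, category,
    mean, sd, n_participants``.
    """
    if percentages is None:
        percentages = design.language_mode == "german_style"
    if group_by is not None and group_by not in df.columns:
        raise ValueError(f"group_by column {group_by!r} not in table")

    work = df.copy()
    work["_group"] = work[group_by] if group_by is not None else "all"

    rows = []
    for group, gdf in work.groupby("_group", sort=True):
        if gdf.empty:
            continue
        # participant x condition x category counts on a complete grid
        counts = (
            gdf.groupby(["participant_id", "condition", "response_category"], sort=False)
            .size()
            .unstack("response_category", fill_value=0)
            .reindex(columns=list(design.valid_categories), fill_value=0)
        )
        full = counts.reindex(
            pd.MultiIndex.from_product(
                [gdf["participant_id"].unique(), design.conditions],
                names=["participant_id", "condition"],
            ),
            fill_value=0,
        )
        if percentages:
            totals = full.sum(axis=1)
            full = full.div(totals.replace(0, np.nan), axis=0) * 100.0
        for cond in design.conditions:
            sub = full.xs(cond, level="condition")
            for cat in design.valid_categories:
                vals = sub[cat].dropna()
                rows.append(
                    {
                        "group": group,
                        "condition": cond,
                        "category": cat,
                        "mean": float(vals.mean()) if len(vals) else np.nan,
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                        "n_participants": int(len(vals)),
                    }
                )
    if not rows:
        log.warning("condition_summary: no groups with records")
    return pd.DataFrame(rows)
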