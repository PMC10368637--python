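"""Long-format EMA dataset container and CSV round-trip.

One row per alcohol survey per participant.  The base schema (what a
raw export contains) is::

    participant_id, group_id, condition, signal_index, weekday,
    responded, drank, beer, wine, liquor

Derived columns (``day_index``, ``week_index``, ``week_type``,
``signal_count``, ``social_weekend``, ``total_drinks``) are appended on
write and recomputed on read.  ``drank`` and the serving counts are
missing whenever the survey was not answered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONTROL_WEEK, CONDITIONS, WEEKDAYS, SOCIAL_WEEKEND_DAYS

logger = logging.getLogger(__name__)

BASE_COLUMNS = [
    "participant_id",
    "group_id",
    "condition",
    "signal_index",
    "weekday",
    "responded",
    "drank",
    "beer",
    "wine",
    "liquor",
]
DERIVED_COLUMNS = [
    "day_index",
    "week_index",
    "week_type",
    "signal_count",
    "social_weekend",
    "total_drinks",
]
WEEK_TYPES = ("active", "inactive", CONTROL_WEEK)


class ValidationError(ValueError):
    """A record set violates the EMA schema invariants."""


class MissingnessError(ValueError):
    """A drinking occasion reports no serving information."""


@dataclass
class EMADataset:
    """EMA records plus the participant-level design table.

    ``records`` is the long table (one row per survey); ``participants``
    carries ``participant_id``, ``group_id``, ``condition``,
    ``schedule_order`` and, after :func:`~emahurdle.preprocess.derive_covariates`,
    per-person response counts.  ``provenance`` records where the data
    came from and what preparation has been applied.
    """

    records: pd.DataFrame
    participants: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_groups(self) -> int:
        return self.participants["group_id"].nunique()

    def copy(self) -> "EMADataset":
        return EMADataset(
            self.records.copy(), self.participants.copy(), dict(self.provenance)
        )

    def answered(self) -> pd.DataFrame:
        """Records for answered surveys with a non-missing drank flag."""
        rec = self.records
        return rec[rec["responded"] & rec["drank"].notna()]

    def write_csv(self, path) -> None:
        write_ema_csv(self, path)


def _infer_schedule_order(week_types: pd.Series) -> str | None:
    labels = set(week_types.dropna())
    if labels <= {CONTROL_WEEK}:
        return None
    first = week_types.iloc[0]
    return "ABAB" if first == "active" else "BABA"


def participants_from_records(records: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct the participant table from long-format records."""
    rows = []
    for pid, sub in records.groupby("participant_id", sort=True):
        sub = sub.sort_values("signal_index")
        order = (
            _infer_schedule_order(sub["week_type"])
            if "week_type" in sub.columns
            else None
        )
        rows.append(
            {
                "participant_id": pid,
                "group_id": sub["group_id"].iloc[0],
                "condition": sub["condition"].iloc[0],
                "schedule_order": order,
            }
        )
    return pd.DataFrame(rows)


def _coerce_types(rec: pd.DataFrame) -> pd.DataFrame:
    rec = rec.copy()
    rec["signal_index"] = rec["signal_index"].astype(int)

    def to_bool(col, nullable):
        s = rec[col]
        if s.dtype == object:
            s = s.map(
                {"True": True, "False": False, "true": True, "false": False}
            ).combine_first(rec[col])
        return s.astype("boolean") if nullable else s.astype(bool)

    rec["responded"] = to_bool("responded", nullable=False)
    rec["drank"] = to_bool("drank", nullable=True)
    for col in ("beer", "wine", "liquor"):
        rec[col] = pd.array(
            pd.to_numeric(rec[col], errors="coerce"), dtype="Int64"
        )
    return rec


def validate_records(
    rec: pd.DataFrame, n_signals: int = 56, week_length_signals: int = 14
) -> pd.Series:
    """Row-wise invariant check; returns a Series of reason strings.

    Empty string means the row is valid.  Checked invariants: signal
    index range, weekday/condition vocabulary, missingness pattern
    (unanswered surveys carry no outcome; answered drinking occasions
    carry at least one positive serving count), and day/week arithmetic
    when the derived columns are present.
    """
    reason = pd.Series("", index=rec.index, dtype=object)

    def flag(mask, msg):
        sel = mask & (reason == "")
        reason[sel] = msg

    flag(~rec["condition"].isin(CONDITIONS), "unknown condition")
    flag(~rec["weekday"].isin(WEEKDAYS), "unknown weekday")
    flag(
        (rec["signal_index"] < 1) | (rec["signal_index"] > n_signals),
        f"signal_index outside 1-{n_signals}",
    )
    unanswered = ~rec["responded"]
    flag(unanswered & rec["drank"].notna(), "unanswered survey with drank flag")
    servings_present = (
        rec[["beer", "wine", "liquor"]].notna().any(axis=1)
    )
    flag(unanswered & servings_present, "unanswered survey with servings")
    answered = rec["responded"]
    drank_true = answered & (rec["drank"] == True)  # noqa: E712 (nullable)
    flag(
        drank_true & ~servings_present,
        "drinking occasion with all servings missing",
    )
    totals = rec[["beer", "wine", "liquor"]].fillna(0).sum(axis=1)
    flag(drank_true & servings_present & (totals < 1), "drinking occasion with zero total drinks")
    drank_false = answered & (rec["drank"] == False)  # noqa: E712
    flag(drank_false & (totals > 0), "non-occasion with positive servings")
    neg = (rec[["beer", "wine", "liquor"]].fillna(0) < 0).any(axis=1)
    flag(neg, "negative serving count")

    if "week_type" in rec.columns:
        flag(~rec["week_type"].isin(WEEK_TYPES), "unknown week_type")
        is_control = rec["condition"] == "control"
        flag(
            is_control & (rec["week_type"] != CONTROL_WEEK),
            "control participant with active/inactive label",
        )
        flag(
            ~is_control & (rec["week_type"] == CONTROL_WEEK),
            "intervention participant with control_week label",
        )
    if "day_index" in rec.columns:
        expected_day = (rec["signal_index"] - 1) // 2 + 1
        flag(rec["day_index"] != expected_day, "day_index inconsistent with signal_index")
    if "week_index" in rec.columns and "day_index" in rec.columns:
        expected_week = (rec["day_index"] - 1) // 7 + 1
        flag(rec["week_index"] != expected_week, "week_index inconsistent with day_index")
    return reason


def read_ema_csv(path, strict: bool = True, n_signals: int = 56) -> EMADataset:
    """Read and validate a long-format EMA CSV.

    In strict mode any invariant violation raises
    :class:`ValidationError`; in lenient mode offending rows are dropped
    and counted (``provenance['n_dropped']``) with a logged warning.
    """
    rec = pd.read_csv(path, dtype={"participant_id": str, "group_id": str})
    missing = [c for c in BASE_COLUMNS if c not in rec.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    rec = _coerce_types(rec)
    reasons = validate_records(rec, n_signals=n_signals)
    bad = reasons != ""
    n_bad = int(bad.sum())
    if n_bad and strict:
        detail = reasons[bad].value_counts().to_dict()
        raise ValidationError(f"{n_bad} invalid rows: {detail}")
    if n_bad:
        logger.warning("dropped %d invalid rows: %s", n_bad,
                       reasons[bad].value_counts().to_dict())
        rec = rec[~bad].reset_index(drop=True)

    from .preprocess import attach_structure  # deferred: avoids cycle

    rec = attach_structure(rec)
    participants = participants_from_records(rec)
    return EMADataset(
        rec,
        participants,
        provenance={"source": str(path), "n_dropped": n_bad,
                    "winsorized": False},
    )


def write_ema_csv(dataset: EMADataset, path) -> None:
    """Write the long table with derived columns appended."""
    cols = BASE_COLUMNS + [c for c in DERIVED_COLUMNS if c in dataset.records.columns]
    dataset.records[cols].to_csv(path, index=False)
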