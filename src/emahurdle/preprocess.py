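"""Preparation of EMA drinking records.

Drink totaling across beverage categories, winsorization of improbable
per-occasion totals, covariate derivation (signal count, social
weekend, per-person response counts) and the descriptive/compliance
summary table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dataset import EMADataset, MissingnessError, participants_from_records
from .design import CONTROL_WEEK, SOCIAL_WEEKEND_DAYS, week_types_for_order

logger = logging.getLogger(__name__)

__all__ = [
    "total_drinks",
    "attach_structure",
    "winsorize_drinks",
    "derive_covariates",
    "descriptives",
]


def total_drinks(beer, wine, liquor) -> int:
    """Total drinks for one occasion: beer + wine + liquor servings.

    A missing category counts as zero provided at least one category
    was reported; if all three are missing the occasion carries no
    serving information and :class:`MissingnessError` is raised.
    """
    vals = [beer, wine, liquor]
    present = [v for v in vals if v is not None and not pd.isna(v)]
    if not present:
        raise MissingnessError("all serving categories missing for an occasion")
    if any(v < 0 or int(v) != v for v in present):
        raise ValueError("serving counts must be nonnegative integers")
    return int(sum(present))


def _total_drinks_vector(rec: pd.DataFrame) -> pd.array:
    """Vectorized totals: 0 for non-occasions, NA for unanswered."""
    servings = rec[["beer", "wine", "liquor"]]
    totals = servings.fillna(0).sum(axis=1).astype("Int64")
    drank = rec["drank"]
    out = totals.where(drank == True, other=0)  # noqa: E712
    out = out.mask(drank.isna(), other=pd.NA)
    missing_all = servings.isna().all(axis=1) & (drank == True)  # noqa: E712
    if missing_all.any():
        raise MissingnessError(
            f"{int(missing_all.sum())} drinking occasions report no servings"
        )
    return out.astype("Int64")


def attach_structure(rec: pd.DataFrame, assignments: pd.DataFrame | None = None,
                     surveys_per_day: int = 2, week_length_days: int = 7
                     ) -> pd.DataFrame:
    """Add calendar/design columns derived from the base schema.

    ``day_index``/``week_index`` follow the survey schedule;
    ``week_type`` is kept if present, otherwise reconstructed from a
    participant ``schedule_order`` table (required for intervention
    participants).  ``total_drinks`` is kept if present (it may have
    been winsorized) and recomputed from the serving columns otherwise.
    """
    rec = rec.copy()
    rec["day_index"] = (rec["signal_index"] - 1) // surveys_per_day + 1
    rec["week_index"] = (rec["day_index"] - 1) // week_length_days + 1
    rec["signal_count"] = rec["signal_index"]
    rec["social_weekend"] = rec["weekday"].isin(SOCIAL_WEEKEND_DAYS)

    if "week_type" not in rec.columns:
        is_control = rec["condition"] == "control"
        rec["week_type"] = CONTROL_WEEK
        if (~is_control).any():
            if assignments is None:
                raise ValueError(
                    "week_type column absent: a participant schedule_order "
                    "table is required to label intervention weeks"
                )
            order_of = assignments.set_index("participant_id")["schedule_order"]
            n_weeks = int(rec["week_index"].max())
            for pid, sub_idx in rec.index.groupby(rec["participant_id"]).items():
                order = order_of.get(pid)
                if order is None or pd.isna(order):
                    continue
                labels = week_types_for_order(order, n_weeks)
                rec.loc[sub_idx, "week_type"] = [
                    labels[w - 1] for w in rec.loc[sub_idx, "week_index"]
                ]
    if "total_drinks" not in rec.columns:
        rec["total_drinks"] = _total_drinks_vector(rec)
    else:
        rec["total_drinks"] = pd.array(
            pd.to_numeric(rec["total_drinks"], errors="coerce"), dtype="Int64"
        )
    return rec


def winsorize_drinks(
    dataset: EMADataset,
    cap: int | str = "next_largest",
    outliers=None,
):
    """Replace improbable per-occasion totals by the largest plausible one.

    Two explicit, reproducible modes (no silent auto-flagging):

    * ``cap="next_largest"`` with an ``outliers`` value set: every total
      in the set is replaced by the largest total *not* in the set;
    * ``cap=<integer threshold>``: totals strictly greater than the
      threshold are replaced by the largest total not exceeding it.

    Returns ``(dataset, n_changed, participants_affected)``; the drank
    flag and the number of drinking occasions are never altered.
    """
    if len(dataset) == 0:
        raise ValueError("cannot winsorize an empty dataset")
    ds = dataset.copy()
    rec = ds.records
    occasions = rec["responded"] & (rec["drank"] == True)  # noqa: E712
    totals = rec.loc[occasions, "total_drinks"].astype("Int64")

    if cap == "next_largest":
        if outliers is None:
            raise ValueError(
                "cap='next_largest' requires an explicit outlier value set"
            )
        outlier_vals = {int(v) for v in outliers}
        mask = totals.isin(outlier_vals)
    else:
        threshold = int(cap)
        mask = totals > threshold
    if mask.any():
        keep = totals[~mask]
        if keep.empty:
            raise ValueError("all occasion totals flagged as outliers")
        replacement = int(keep.max())
        idx = totals.index[mask]
        rec.loc[idx, "total_drinks"] = replacement
        affected = sorted(rec.loc[idx, "participant_id"].unique())
    else:
        affected = []
    n_changed = int(mask.sum())
    ds.provenance.update(
        {"winsorized": True, "winsorize_cap": cap, "n_winsorized": n_changed}
    )
    logger.info("winsorized %d occasion totals across %d participants",
                n_changed, len(affected))
    return ds, n_changed, affected


def derive_covariates(dataset: EMADataset) -> EMADataset:
    """Model covariates: a pure function of schedule and response fields.

    Adds/refreshes on the records: ``signal_count`` (the 1-based signal
    index, the linear time trend), ``social_weekend`` (Thursday through
    Saturday) and the participant's total ``n_responses``; on the
    participant table: ``n_responses`` plus answered-survey counts per
    week type.
    """
    ds = dataset.copy()
    rec = ds.records
    rec["signal_count"] = rec["signal_index"]
    rec["social_weekend"] = rec["weekday"].isin(SOCIAL_WEEKEND_DAYS)

    n_resp = rec.groupby("participant_id")["responded"].sum().astype(int)
    rec["n_responses"] = rec["participant_id"].map(n_resp)

    part = ds.participants.set_index("participant_id")
    part["n_responses"] = n_resp.reindex(part.index).fillna(0).astype(int)
    by_type = (
        rec[rec["responded"]]
        .groupby(["participant_id", "week_type"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    for wt in ("active", "inactive", CONTROL_WEEK):
        col = f"n_responses_{wt}"
        part[col] = by_type.get(wt, pd.Series(dtype=int)).reindex(part.index).fillna(0).astype(int)
    ds.participants = part.reset_index()
    ds.records = rec
    return ds


def descriptives(dataset: EMADataset) -> dict:
    """Compliance and consumption summary in the conventional layout.

    Per condition x week type (participant-level mean and SD):
    percentage of surveys answered, percentage of answered surveys with
    a drinking occasion, and drinks per occasion.  Plus overall
    response-percentage median/mean/SD and the count of participants
    reporting no alcohol at all.  Cells with no drinking occasions
    report missing drinks-per-occasion.
    """
    rec = dataset.records
    per_cell = []
    for (pid, cond, wt), sub in rec.groupby(
        ["participant_id", "condition", "week_type"], observed=True
    ):
        answered = sub["responded"].sum()
        occ = int((sub["drank"] == True).sum())  # noqa: E712
        drinks = sub.loc[sub["drank"] == True, "total_drinks"]  # noqa: E712
        per_cell.append(
            {
                "participant_id": pid,
                "condition": cond,
                "week_type": wt,
                "pct_responses": 100.0 * answered / len(sub),
                "pct_occasions": 100.0 * occ / answered if answered else np.nan,
                "drinks_per_occasion": float(drinks.mean()) if occ else np.nan,
                "n_occasions": occ,
            }
        )
    per_cell = pd.DataFrame(per_cell)
    by_cell = (
        per_cell.groupby(["condition", "week_type"], observed=True)
        .agg(
            pct_responses_mean=("pct_responses", "mean"),
            pct_responses_sd=("pct_responses", "std"),
            pct_occasions_mean=("pct_occasions", "mean"),
            pct_occasions_sd=("pct_occasions", "std"),
            drinks_per_occasion_mean=("drinks_per_occasion", "mean"),
            drinks_per_occasion_sd=("drinks_per_occasion", "std"),
            n_participants=("participant_id", "nunique"),
        )
        .reset_index()
    )

    per_person = rec.groupby("participant_id").agg(
        n_sent=("signal_index", "size"),
        n_answered=("responded", "sum"),
        n_occasions=("drank", lambda s: int((s == True).sum())),  # noqa: E712
    )
    resp_pct = 100.0 * per_person["n_answered"] / per_person["n_sent"]
    return {
        "by_cell": by_cell,
        "per_participant": per_cell,
        "response_pct_median": float(resp_pct.median()),
        "response_pct_mean": float(resp_pct.mean()),
        "response_pct_sd": float(resp_pct.std()),
        "n_zero_drinkers": int((per_person["n_occasions"] == 0).sum()),
        "n_participants": int(len(per_person)),
        "n_occasions_total": int(per_person["n_occasions"].sum()),
    }
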