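"""Behavior-change inference by pseudo-week randomization.

Each intervention participant gets a change score: the proportion of
answered surveys with a drinking occasion during active weeks minus
the same proportion during inactive weeks (negative = drinking less
often under active reminders).  Control participants, whose protocol
never changed, receive *pseudo* active/inactive labels: half are
randomly assigned ABAB and half BABA, the per-person score is computed
under those labels, and the assignment is repeated (default 100
iterations) with the scores averaged — a matched null for what change
scores look like absent any real crossover.  The two groups of scores
are then compared with a Mann–Whitney–Wilcoxon rank-sum test; a
Shapiro–Wilk normality check per group is reported as the gate that
motivates the nonparametric choice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ChangeScore",
    "PseudoWeekConfig",
    "RankSumResult",
    "UndefinedScoreError",
    "person_change_score",
    "pseudo_week_labels",
    "control_pseudo_change",
    "rank_sum_test",
    "compare_change_scores",
]


class UndefinedScoreError(ValueError):
    """No answered surveys in one of the labeled week types."""


@dataclass(frozen=True)
class ChangeScore:
    """Per-person active-vs-inactive difference in occasion proportion."""

    participant_id: str
    condition: str
    prop_active: float
    prop_inactive: float
    delta: float
    n_iterations_used: int = 1


@dataclass(frozen=True)
class PseudoWeekConfig:
    """Settings for the control-arm pseudo-week randomization."""

    n_iterations: int = 100
    seed: int = 0
    sign_convention: str = "fig3"  # "fig3": active - inactive; "methods": reverse
    numerator: str = "occasions"  # or "drinks"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.sign_convention not in ("fig3", "methods"):
            raise ValueError("sign_convention must be 'fig3' or 'methods'")
        if self.numerator not in ("occasions", "drinks"):
            raise ValueError("numerator must be 'occasions' or 'drinks'")


@dataclass(frozen=True)
class RankSumResult:
    """Rank-sum comparison of intervention vs. control change scores.

    ``W`` is the rank-sum of the first sample (the U statistic is also
    reported, plus both groups' conventions, since published W values
    may refer to either); ``Z`` uses the tie-corrected normal
    approximation without continuity correction; ``r = |Z|/sqrt(N)``.
    """

    W: float
    U: float
    W_second: float
    Z: float
    p: float
    r: float
    n1: int
    n2: int
    total_n_for_r: int
    method: str
    normality_gate: tuple


def _proportions(sub: pd.DataFrame, labels: dict, numerator: str):
    """(numerator sum, answered count) per label over one participant."""
    out = {}
    for label in ("active", "inactive"):
        weeks = [w for w, lab in labels.items() if lab == label]
        in_label = sub["week_index"].isin(weeks)
        answered = sub.loc[in_label, "responded"].sum()
        if numerator == "occasions":
            num = int((sub.loc[in_label, "drank"] == True).sum())  # noqa: E712
        else:
            num = int(
                sub.loc[in_label & (sub["drank"] == True), "total_drinks"].sum()  # noqa: E712
            )
        out[label] = (num, int(answered))
    return out


def person_change_score(
    records: pd.DataFrame,
    labels: dict,
    sign_convention: str = "fig3",
    numerator: str = "occasions",
) -> ChangeScore:
    """Change score for one participant under the given week labels.

    ``labels`` maps week index -> "active"/"inactive".  Proportions are
    drinking occasions over answered surveys per label; with
    ``numerator="drinks"`` the numerator is total drinks instead.
    Raises :class:`UndefinedScoreError` if either label has no answered
    survey.
    """
    props = _proportions(records, labels, numerator)
    (num_a, den_a), (num_i, den_i) = props["active"], props["inactive"]
    if den_a == 0 or den_i == 0:
        raise UndefinedScoreError(
            f"participant {records['participant_id'].iloc[0]!r} has no "
            "answered surveys in one labeled week type"
        )
    prop_a, prop_i = num_a / den_a, num_i / den_i
    delta = prop_a - prop_i
    if sign_convention == "methods":
        delta = -delta
    return ChangeScore(
        participant_id=str(records["participant_id"].iloc[0]),
        condition=str(records["condition"].iloc[0]),
        prop_active=prop_a,
        prop_inactive=prop_i,
        delta=delta,
    )


def _pseudo_orders(control_ids, iteration_index: int,
                   config: PseudoWeekConfig) -> np.ndarray:
    """ABAB/BABA order per control id for one iteration (even split)."""
    if len(control_ids) < 2:
        raise ValueError("pseudo-week labeling needs at least 2 control participants")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(iteration_index)])
    )
    perm = rng.permutation(len(control_ids))
    half = len(control_ids) // 2
    orders = np.empty(len(control_ids), dtype=object)
    orders[perm[:half]] = "ABAB"
    orders[perm[half: 2 * half]] = "BABA"
    if len(control_ids) % 2:
        orders[perm[-1]] = ("ABAB", "BABA")[rng.integers(2)]
    return orders


def pseudo_week_labels(
    control_ids, iteration_index: int, config: PseudoWeekConfig, n_weeks: int = 4
) -> pd.DataFrame:
    """Random ABAB/BABA pseudo-labels for one iteration.

    Half of the control participants (seeded random split; an odd
    leftover's order drawn from the same stream) get ABAB labels (odd
    weeks pseudo-active), the rest BABA.  A pure function of
    ``(config.seed, iteration_index)``.
    """
    control_ids = list(control_ids)
    orders = _pseudo_orders(control_ids, iteration_index, config)
    rows = []
    for pid, order in zip(control_ids, orders):
        for w in range(1, n_weeks + 1):
            odd = w % 2 == 1
            label = ("active" if odd else "inactive") if order == "ABAB" else (
                "inactive" if odd else "active")
            rows.append({"participant_id": pid, "week_index": w,
                         "pseudo_week_type": label, "order": order})
    return pd.DataFrame(rows)


def _week_tallies(records: pd.DataFrame, numerator: str):
    """Per participant x week: (numerator, answered) — basis for fast iteration."""
    rec = records
    drank = (rec["drank"] == True).fillna(False).astype(bool)  # noqa: E712
    if numerator == "occasions":
        num = drank.astype(int)
    else:
        num = rec["total_drinks"].where(drank, 0).fillna(0).astype(int)
    tmp = pd.DataFrame(
        {
            "participant_id": rec["participant_id"],
            "week_index": rec["week_index"],
            "num": num,
            "answered": rec["responded"].astype(int),
        }
    )
    return tmp.groupby(["participant_id", "week_index"], observed=True).sum()


def _tally_matrices(records: pd.DataFrame, ids, n_weeks: int, numerator: str):
    """(num, answered) as (len(ids) x n_weeks) arrays, week-major columns."""
    tallies = _week_tallies(records, numerator)
    weeks = range(1, n_weeks + 1)
    num = (
        tallies["num"].unstack(fill_value=0)
        .reindex(index=ids, columns=weeks, fill_value=0)
        .to_numpy(dtype=float)
    )
    ans = (
        tallies["answered"].unstack(fill_value=0)
        .reindex(index=ids, columns=weeks, fill_value=0)
        .to_numpy(dtype=float)
    )
    return num, ans


def control_pseudo_change(
    dataset, config: PseudoWeekConfig, n_weeks: int = 4
) -> list[ChangeScore]:
    """Averaged pseudo change scores for the control arm.

    Every iteration assigns ABAB/BABA pseudo-labels and scores each
    control participant; a participant's final delta is the mean over
    iterations in which the score is defined (undefined iterations are
    skipped and counted; a participant undefined in every iteration is
    excluded with a log entry).
    """
    rec = dataset.records
    controls = rec[rec["condition"] == "control"]
    ids = sorted(controls["participant_id"].unique())
    if not ids:
        return []
    num, ans = _tally_matrices(controls, ids, n_weeks, config.numerator)
    odd = np.arange(n_weeks) % 2 == 0  # weeks 1,3 (0-based 0,2)

    def delta_for(active_mask):
        num_a, ans_a = num[:, active_mask].sum(1), ans[:, active_mask].sum(1)
        num_i, ans_i = num[:, ~active_mask].sum(1), ans[:, ~active_mask].sum(1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = num_a / ans_a - num_i / ans_i
        d[(ans_a == 0) | (ans_i == 0)] = np.nan
        return d

    d_abab = delta_for(odd)       # odd weeks pseudo-active
    d_baba = delta_for(~odd)
    pa_abab = np.divide(num[:, odd].sum(1), ans[:, odd].sum(1),
                        out=np.full(len(ids), np.nan), where=ans[:, odd].sum(1) > 0)
    pa_baba = np.divide(num[:, ~odd].sum(1), ans[:, ~odd].sum(1),
                        out=np.full(len(ids), np.nan), where=ans[:, ~odd].sum(1) > 0)

    sums = np.zeros(len(ids))
    sums_pa = np.zeros(len(ids))
    counts = np.zeros(len(ids), dtype=int)
    for it in range(config.n_iterations):
        is_abab = _pseudo_orders(ids, it, config) == "ABAB"
        d_it = np.where(is_abab, d_abab, d_baba)
        pa_it = np.where(is_abab, pa_abab, pa_baba)
        ok = ~np.isnan(d_it)
        sums[ok] += d_it[ok]
        sums_pa[ok] += pa_it[ok]
        counts[ok] += 1

    scores = []
    for i, pid in enumerate(ids):
        if counts[i] == 0:
            logger.warning("control %s undefined in all iterations; excluded", pid)
            continue
        delta = sums[i] / counts[i]
        prop_a = sums_pa[i] / counts[i]
        if config.sign_convention == "methods":
            delta = -delta
        scores.append(
            ChangeScore(
                participant_id=str(pid),
                condition="control",
                prop_active=prop_a,
                prop_inactive=prop_a - (sums[i] / counts[i]),
                delta=delta,
                n_iterations_used=int(counts[i]),
            )
        )
    return scores


def rank_sum_test(x, y, total_n_for_r: int | None = None) -> RankSumResult:
    """Mann–Whitney–Wilcoxon comparison of two score samples.

    Mid-ranks for ties; ``Z`` from the tie-corrected normal
    approximation without continuity correction; the two-sided p-value
    is exact (full enumeration distribution) when both samples are
    small and tie-free, asymptotic otherwise.  ``r = |Z| / sqrt(N)``
    with ``N = total_n_for_r`` (defaults to n1 + n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    N = int(total_n_for_r) if total_n_for_r else n1 + n2

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = float(ranks[:n1].sum())
    W2 = float(ranks[n1:].sum())
    U = W - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        Z, p, method = 0.0, 1.0, "degenerate"
    else:
        Z = (U - n1 * n2 / 2.0) / np.sqrt(var_u)
        has_ties = bool((tie_counts > 1).any())
        if not has_ties and n <= 25:
            p = float(
                stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue
            )
            method = "exact"
        else:
            p = float(2.0 * stats.norm.sf(abs(Z)))
            method = "asymptotic"
    p = min(p, 1.0)
    r = abs(Z) / np.sqrt(N)

    def shapiro_p(v):
        if len(v) < 3 or np.ptp(v) == 0:
            return float("nan")
        return float(stats.shapiro(v).pvalue)

    return RankSumResult(
        W=W, U=float(U), W_second=W2, Z=float(Z), p=float(p), r=float(r),
        n1=n1, n2=n2, total_n_for_r=N, method=method,
        normality_gate=(shapiro_p(x), shapiro_p(y)),
    )


@dataclass
class ChangeScoreReport:
    """End-to-end comparison output."""

    intervention: list
    control: list
    test: RankSumResult
    mean_delta_intervention: float
    mean_delta_control: float
    median_delta_intervention: float
    median_delta_control: float
    direction: str
    n_excluded_intervention: int
    n_excluded_control: int

    def scores_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": s.participant_id,
                "condition": s.condition,
                "prop_active": s.prop_active,
                "prop_inactive": s.prop_inactive,
                "delta": s.delta,
                "n_iterations_used": s.n_iterations_used,
            }
            for s in self.intervention + self.control
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        t = self.test
        return {
            "W": t.W, "U": t.U, "W_second": t.W_second, "Z": t.Z, "p": t.p,
            "r": t.r, "n1": t.n1, "n2": t.n2, "total_n_for_r": t.total_n_for_r,
            "method": t.method, "normality_gate": list(t.normality_gate),
            "mean_delta_intervention": self.mean_delta_intervention,
            "mean_delta_control": self.mean_delta_control,
            "median_delta_intervention": self.median_delta_intervention,
            "median_delta_control": self.median_delta_control,
            "direction": self.direction,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compare_change_scores(dataset, config: PseudoWeekConfig | None = None,
                          n_weeks: int = 4) -> ChangeScoreReport:
    """Intervention change scores vs. the control pseudo-week null.

    Orchestrates :func:`person_change_score` on the intervention arms
    (true week labels), :func:`control_pseudo_change` on the control
    arm, and the rank-sum comparison; ``total_n_for_r`` is the full
    participant count of the dataset.
    """
    config = config or PseudoWeekConfig()
    rec = dataset.records
    intervention_scores = []
    n_excl_i = 0
    interv = rec[rec["condition"].isin(["mindfulness", "perspective_taking"])]
    ids_i = sorted(interv["participant_id"].unique())
    if ids_i:
        num, ans = _tally_matrices(interv, ids_i, n_weeks, config.numerator)
        first_week = (
            interv[interv["week_index"] == 1]
            .drop_duplicates("participant_id")
            .set_index("participant_id")["week_type"]
            .reindex(ids_i)
        )
        cond_of = (
            interv.drop_duplicates("participant_id")
            .set_index("participant_id")["condition"]
            .reindex(ids_i)
        )
        odd = np.arange(n_weeks) % 2 == 0
        active_mask = np.where(
            (first_week == "active").to_numpy()[:, None], odd[None, :], ~odd[None, :]
        )
        for i, pid in enumerate(ids_i):
            am = active_mask[i]
            num_a, ans_a = num[i, am].sum(), ans[i, am].sum()
            num_i_, ans_i_ = num[i, ~am].sum(), ans[i, ~am].sum()
            if ans_a == 0 or ans_i_ == 0:
                logger.warning(
                    "intervention %s has an empty week type; excluded", pid
                )
                n_excl_i += 1
                continue
            prop_a, prop_i = num_a / ans_a, num_i_ / ans_i_
            delta = prop_a - prop_i
            if config.sign_convention == "methods":
                delta = -delta
            intervention_scores.append(
                ChangeScore(
                    participant_id=str(pid),
                    condition=str(cond_of.loc[pid]),
                    prop_active=prop_a,
                    prop_inactive=prop_i,
                    delta=delta,
                )
            )

    control_scores = control_pseudo_change(dataset, config, n_weeks=n_weeks)
    n_controls = rec.loc[rec["condition"] == "control", "participant_id"].nunique()
    n_excl_c = n_controls - len(control_scores)

    if not intervention_scores or not control_scores:
        raise ValueError("need both intervention and control change scores")

    xi = np.array([s.delta for s in intervention_scores])
    yc = np.array([s.delta for s in control_scores])
    test = rank_sum_test(xi, yc, total_n_for_r=dataset.n_participants)
    diff = float(xi.mean() - yc.mean())
    direction = (
        "intervention-consistent (intervention scores more negative)"
        if diff < 0
        else "not intervention-consistent"
    )
    return ChangeScoreReport(
        intervention=intervention_scores,
        control=control_scores,
        test=test,
        mean_delta_intervention=float(xi.mean()),
        mean_delta_control=float(yc.mean()),
        median_delta_intervention=float(np.median(xi)),
        median_delta_control=float(np.median(yc)),
        direction=direction,
        n_excluded_intervention=n_excl_i,
        n_excluded_control=n_excl_c,
    )
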