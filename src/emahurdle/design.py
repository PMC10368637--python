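"""Trial-design and data-generating-process declarations.

The study design is a within-person crossover delivered by smartphone:
participants, recruited in small social groups, are randomized to one of
three conditions (two psychological-distancing interventions plus a
control) and then followed for four weeks with two alcohol surveys per
day.  Intervention participants alternate between *active* weeks (they
receive distancing reminders) and *inactive* weeks (neutral reminders),
in a counterbalanced ABAB or BABA order; control participants receive
neutral reminders throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import math

import numpy as np
import pandas as pd

CONDITIONS = ("mindfulness", "perspective_taking", "control")
INTERVENTION_CONDITIONS = ("mindfulness", "perspective_taking")
SCHEDULE_ORDERS = ("ABAB", "BABA")
WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
SOCIAL_WEEKEND_DAYS = frozenset({"Thu", "Fri", "Sat"})

#: week_type value carried by every control-arm record
CONTROL_WEEK = "control_week"


class InvalidDesignError(ValueError):
    """Raised when a study design fails its structural invariants."""


@dataclass(frozen=True)
class StudyDesign:
    """Structure of the crossover EMA trial.

    Parameters
    ----------
    n_groups:
        Number of social groups (the upper nesting level).
    participants_per_group:
        Either a single integer applied to every group or one integer
        per group.
    allocation:
        Proportion of participants assigned to each of
        ``(mindfulness, perspective_taking, control)``; must sum to 1.
    n_days, surveys_per_day, week_length_days:
        Follow-up length and survey density.  The default 28 days x 2
        surveys gives the canonical 56 signals over 4 weeks.
    start_weekday:
        Calendar weekday of day 1; anchors the social-weekend covariate.
    """

    n_groups: int = 10
    participants_per_group: int | Sequence[int] = 10
    allocation: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_days: int = 28
    surveys_per_day: int = 2
    week_length_days: int = 7
    start_weekday: str = "Mon"

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise InvalidDesignError("n_groups must be positive")
        for size in self.group_sizes():
            if size < 1:
                raise InvalidDesignError("group sizes must be positive")
        if self.n_days < self.week_length_days:
            raise InvalidDesignError("n_days shorter than one week")
        if abs(sum(self.allocation) - 1.0) > 1e-9:
            raise InvalidDesignError("allocation must sum to 1")
        if any(a < 0 for a in self.allocation):
            raise InvalidDesignError("allocation proportions must be >= 0")
        if self.start_weekday not in WEEKDAYS:
            raise InvalidDesignError(f"unknown weekday {self.start_weekday!r}")
        if self.surveys_per_day < 1:
            raise InvalidDesignError("surveys_per_day must be positive")

    def group_sizes(self) -> list[int]:
        if isinstance(self.participants_per_group, int):
            return [self.participants_per_group] * self.n_groups
        sizes = list(self.participants_per_group)
        if len(sizes) != self.n_groups:
            raise InvalidDesignError(
                "participants_per_group list length must equal n_groups"
            )
        return sizes

    @property
    def n_participants(self) -> int:
        return sum(self.group_sizes())

    @property
    def n_signals(self) -> int:
        return self.n_days * self.surveys_per_day

    @property
    def n_weeks(self) -> int:
        return math.ceil(self.n_days / self.week_length_days)

    def signal_calendar(self) -> pd.DataFrame:
        """Per-signal calendar shared by every participant.

        Returns a frame with ``signal_index`` (1-based), ``day_index``,
        ``week_index``, ``weekday`` and ``social_weekend``; the social
        weekend is Thursday through Saturday.
        """
        signal = np.arange(1, self.n_signals + 1)
        day = (signal - 1) // self.surveys_per_day + 1
        week = (day - 1) // self.week_length_days + 1
        start = WEEKDAYS.index(self.start_weekday)
        weekday = [WEEKDAYS[(start + d - 1) % 7] for d in day]
        return pd.DataFrame(
            {
                "signal_index": signal,
                "day_index": day,
                "week_index": week,
                "weekday": weekday,
                "social_weekend": [w in SOCIAL_WEEKEND_DAYS for w in weekday],
            }
        )


@dataclass(frozen=True)
class GenerativeParams:
    """Coefficients of the data-generating hurdle process.

    ``zi_*`` coefficients live on the log-odds-of-zero scale (a zero is
    an answered survey with no drinking), ``cond_*`` coefficients on the
    log-mean scale of the zero-truncated negative binomial for drinks on
    drinking occasions.  Defaults mirror the second (larger) study's
    fitted odds ratios and random-effect spreads; the weekly compliance
    rates reproduce its reported answered-survey means (22.41/28 active,
    23.54/28 inactive).
    """

    zi_intercept: float = math.log(10.4)
    zi_active_week: float = math.log(1.39)
    zi_condition: float = math.log(1.06)  # perspective-taking vs mindfulness
    zi_signal_count: float = 0.0
    zi_n_responses: float = math.log(1.02)
    zi_social_weekend: float = math.log(0.54)

    cond_intercept: float = math.log(1.79)
    cond_active_week: float = math.log(0.97)
    cond_condition: float = math.log(0.54)
    cond_signal_count: float = math.log(1.01)
    cond_n_responses: float = math.log(0.99)
    cond_social_weekend: float = math.log(1.27)

    nb_dispersion: float = 2.0

    re_sd_participant_zi: float = 0.447
    re_sd_group_zi: float = 0.282
    re_sd_participant_cond: float = 1.371
    re_sd_group_cond: float = 0.859

    compliance_active: float = 0.80
    compliance_inactive: float = 0.84

    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in (
            "re_sd_participant_zi",
            "re_sd_group_zi",
            "re_sd_participant_cond",
            "re_sd_group_cond",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("compliance_active", "compliance_inactive"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        return cls(**d)


def _allocation_counts(n: int, allocation: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n participants to conditions."""
    raw = [a * n for a in allocation]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def assign_design(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Randomize conditions and counterbalanced week orders.

    Returns the participant table: ``participant_id``, ``group_id``,
    ``condition`` and ``schedule_order`` (ABAB/BABA for intervention
    participants, missing for controls, whose weeks never differ).
    Conditions are allocated across the whole sample per
    ``design.allocation``; within each intervention condition the two
    week orders are split as evenly as possible, an odd leftover order
    drawn from the seeded stream.
    """
    rng = np.random.default_rng(seed)
    sizes = design.group_sizes()
    n = design.n_participants

    pid_width = max(3, len(str(n)))
    participant_id, group_id = [], []
    k = 0
    for g, size in enumerate(sizes, start=1):
        for _ in range(size):
            k += 1
            participant_id.append(f"P{k:0{pid_width}d}")
            group_id.append(f"G{g:02d}")

    counts = _allocation_counts(n, design.allocation)
    labels = np.repeat(CONDITIONS, counts)
    condition = labels[rng.permutation(n)]

    schedule = np.full(n, None, dtype=object)
    for cond in INTERVENTION_CONDITIONS:
        idx = np.flatnonzero(condition == cond)
        c = len(idx)
        orders = ["ABAB"] * (c // 2) + ["BABA"] * (c // 2)
        if c % 2:
            orders.append(SCHEDULE_ORDERS[rng.integers(2)])
        schedule[rng.permutation(idx)] = orders

    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "group_id": group_id,
            "condition": condition,
            "schedule_order": schedule,
        }
    )


def week_types_for_order(order: str | None, n_weeks: int) -> list[str]:
    """Active/inactive labels per week index for a schedule order.

    ABAB: odd weeks active; BABA: even weeks active; ``None`` (control)
    yields the constant ``control_week`` label.
    """
    if order is None:
        return [CONTROL_WEEK] * n_weeks
    if order == "ABAB":
        return ["active" if w % 2 == 1 else "inactive" for w in range(1, n_weeks + 1)]
    if order == "BABA":
        return ["inactive" if w % 2 == 1 else "active" for w in range(1, n_weeks + 1)]
    raise ValueError(f"unknown schedule order {order!r}")
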