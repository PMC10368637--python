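"""Forward simulation of the crossover EMA trial.

The generator is the analysis model run forwards: an answered survey
first draws "no alcohol" from a logistic model (zero sub-model), and a
drinking occasion then draws its drink count from a zero-truncated
negative binomial (conditional sub-model), both with participant- and
group-level random intercepts.  Survey compliance differs between
active and inactive weeks, emulating the lower response rates observed
under active reminders; compliance is independent of the drinking
outcome.  All randomness flows from ``params.seed`` through dedicated
child streams (responses, zero draws, counts, random effects,
assignment), so the zero-probability coefficients and the response
pattern share common random numbers across parameter changes and a
fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .dataset import EMADataset
from .design import (
    CONTROL_WEEK,
    GenerativeParams,
    StudyDesign,
    assign_design,
    week_types_for_order,
)
from .preprocess import derive_covariates

__all__ = ["generate_dataset", "sample_truncated_nb", "write_simulation"]


def sample_truncated_nb(rng, mu, k, max_tries: int = 1000) -> np.ndarray:
    """Draw from NB(mean mu, dispersion k) truncated to y >= 1.

    Rejection from the untruncated negative binomial (zeros are
    redrawn), which is exact; ``mu``/``k`` broadcast elementwise.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    k = np.broadcast_to(np.asarray(k, dtype=float), mu.shape).copy()
    n, p = k, k / (k + mu)
    y = rng.negative_binomial(n, p)
    for _ in range(max_tries):
        zero = y == 0
        if not zero.any():
            break
        y[zero] = rng.negative_binomial(n[zero], p[zero])
    else:
        y[y == 0] = 1  # pathological mu -> 0; occasion still has >= 1 drink
    return y


def _split_servings(rng, totals: np.ndarray) -> np.ndarray:
    """Distribute each total across (beer, wine, liquor)."""
    probs = np.array([0.5, 0.3, 0.2])
    return rng.multinomial(totals, probs)


def generate_dataset(design: StudyDesign, params: GenerativeParams) -> EMADataset:
    """Simulate one complete EMA dataset under the given design.

    Returns a fully structured :class:`EMADataset` with covariates
    derived; the participant table carries the realized condition and
    schedule-order assignment.
    """
    root = np.random.SeedSequence(params.seed)
    s_assign, s_effects, s_resp, s_zero, s_count, s_split = root.spawn(6)
    assignment = assign_design(
        design, seed=int(s_assign.generate_state(1)[0] % (2**31))
    )
    rng_eff = np.random.default_rng(s_effects)
    rng_resp = np.random.default_rng(s_resp)
    rng_zero = np.random.default_rng(s_zero)
    rng_count = np.random.default_rng(s_count)
    rng_split = np.random.default_rng(s_split)

    calendar = design.signal_calendar()
    n_signals = design.n_signals
    n_weeks = design.n_weeks
    n_part = len(assignment)
    group_ids = assignment["group_id"].to_numpy()
    groups = pd.Categorical(group_ids)
    group_code = groups.codes
    n_groups = len(groups.categories)

    # random intercepts, independent across sub-models
    u_zi = rng_eff.standard_normal(n_groups) * params.re_sd_group_zi
    v_zi = rng_eff.standard_normal(n_part) * params.re_sd_participant_zi
    u_cd = rng_eff.standard_normal(n_groups) * params.re_sd_group_cond
    v_cd = rng_eff.standard_normal(n_part) * params.re_sd_participant_cond

    # per participant x signal structure (participant-major ordering)
    week_of_signal = calendar["week_index"].to_numpy()
    is_perspective = (
        assignment["condition"].to_numpy() == "perspective_taking"
    ).astype(float)
    is_control = assignment["condition"].to_numpy() == "control"

    week_type = np.empty((n_part, n_signals), dtype=object)
    for i, order in enumerate(assignment["schedule_order"]):
        labels = week_types_for_order(None if pd.isna(order) else order, n_weeks)
        week_type[i] = [labels[w - 1] for w in week_of_signal]
    active = (week_type == "active").astype(float)

    # compliance pass (common random numbers with outcome draws)
    comp = np.where(active == 1.0, params.compliance_active,
                    params.compliance_inactive)
    responded = rng_resp.random((n_part, n_signals)) < comp
    n_responses = responded.sum(axis=1).astype(float)

    signal_count = np.broadcast_to(
        calendar["signal_count"].to_numpy(dtype=float)
        if "signal_count" in calendar
        else calendar["signal_index"].to_numpy(dtype=float),
        (n_part, n_signals),
    )
    weekend = np.broadcast_to(
        calendar["social_weekend"].to_numpy(dtype=float), (n_part, n_signals)
    )

    def linpred(prefix):
        p = params
        c = {f: getattr(p, f"{prefix}_{f}") for f in (
            "intercept", "active_week", "condition", "signal_count",
            "n_responses", "social_weekend")}
        return (
            c["intercept"]
            + c["active_week"] * active
            + c["condition"] * is_perspective[:, None]
            + c["signal_count"] * signal_count
            + c["n_responses"] * n_responses[:, None]
            + c["social_weekend"] * weekend
        )

    eta_zi = linpred("zi") + u_zi[group_code][:, None] + v_zi[:, None]
    eta_cd = linpred("cond") + u_cd[group_code][:, None] + v_cd[:, None]

    p_zero = 1.0 / (1.0 + np.exp(-np.clip(eta_zi, -35, 35)))
    zero_draw = rng_zero.random((n_part, n_signals)) < p_zero
    drank = responded & ~zero_draw

    mu = np.exp(np.clip(eta_cd, -35, 35))
    totals = np.zeros((n_part, n_signals), dtype=int)
    occ = drank.ravel()
    if occ.any():
        totals.ravel()[occ] = sample_truncated_nb(
            rng_count, mu.ravel()[occ], params.nb_dispersion
        )
    servings = np.zeros((n_part * n_signals, 3), dtype=int)
    if occ.any():
        servings[occ] = _split_servings(rng_split, totals.ravel()[occ])

    resp_flat = responded.ravel()
    drank_flat = pd.array(np.where(resp_flat, ~zero_draw.ravel(), False),
                          dtype="boolean")
    drank_flat[~resp_flat] = pd.NA
    serv_cols = {}
    for j, name in enumerate(("beer", "wine", "liquor")):
        col = pd.array(servings[:, j], dtype="Int64")
        col[~resp_flat] = pd.NA
        serv_cols[name] = col
    totals_flat = pd.array(totals.ravel(), dtype="Int64")
    totals_flat[~resp_flat] = pd.NA

    rec = pd.DataFrame(
        {
            "participant_id": np.repeat(
                assignment["participant_id"].to_numpy(), n_signals
            ),
            "group_id": np.repeat(group_ids, n_signals),
            "condition": np.repeat(assignment["condition"].to_numpy(), n_signals),
            "signal_index": np.tile(calendar["signal_index"].to_numpy(), n_part),
            "weekday": np.tile(calendar["weekday"].to_numpy(), n_part),
            "responded": resp_flat,
            "drank": drank_flat,
            "beer": serv_cols["beer"],
            "wine": serv_cols["wine"],
            "liquor": serv_cols["liquor"],
            "day_index": np.tile(calendar["day_index"].to_numpy(), n_part),
            "week_index": np.tile(week_of_signal, n_part),
            "week_type": week_type.ravel(),
            "signal_count": np.tile(calendar["signal_index"].to_numpy(), n_part),
            "social_weekend": np.tile(
                calendar["social_weekend"].to_numpy(), n_part
            ),
            "total_drinks": totals_flat,
        }
    )
    ds = EMADataset(
        rec,
        assignment.copy(),
        provenance={"source": "simulation", "seed": params.seed,
                    "winsorized": False},
    )
    return derive_covariates(ds)


def write_simulation(dataset: EMADataset, params: GenerativeParams,
                     csv_path, params_path) -> None:
    """Dataset CSV plus the true generating parameters for recovery tests."""
    dataset.write_csv(csv_path)
    with open(params_path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)
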