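"""Hurdle likelihood, quadrature, Wald/BH inference, and fitting."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats

import emahurdle as eh
from emahurdle.hurdle import (
    BernoulliLogit,
    DegenerateOutcomeError,
    ModelSpec,
    TruncatedNB,
    bh_adjust,
    fit_hurdle,
    hurdle_loglik,
    truncated_nb_logpmf,
    wald_summary,
)


class TestTruncatedNBLogpmf:
    def test_normalizes_to_one(self):
        y = np.arange(1, 10**6)
        total = np.exp(truncated_nb_logpmf(y, 2.0, 1.0)).sum()
        assert abs(total - 1.0) < 1e-8

    def test_zero_truncated_poisson_limit(self):
        # over the realistic drink-count support the NB at huge k is
        # indistinguishable from a zero-truncated Poisson
        y = np.arange(1, 11)
        ztp = stats.poisson.logpmf(y, 1.5) - np.log(-np.expm1(-1.5))
        assert np.abs(truncated_nb_logpmf(y, 1.5, 1e6) - ztp).max() < 1e-4

    def test_matches_pmf_ratio(self):
        # direct arithmetic on scipy's NB pmf terms
        nb = stats.nbinom(2, 2 / (2 + 3))  # mean 3, dispersion 2
        expected = math.log(nb.pmf(4) / (1 - nb.pmf(0)))
        assert abs(truncated_nb_logpmf(4, 3.0, 2.0) - expected) < 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            truncated_nb_logpmf(0, 2.0, 1.0)
        with pytest.raises(ValueError):
            truncated_nb_logpmf(1, -1.0, 1.0)

    def test_family_gradient_matches_numeric(self):
        y = np.array([1.0, 2.0, 5.0, 9.0])
        eta = np.array([-0.5, 0.2, 1.0, 2.0])
        extra = (0.4,)
        eps = 1e-6
        num = (
            TruncatedNB.loglik(y, eta + eps, extra)
            - TruncatedNB.loglik(y, eta - eps, extra)
        ) / (2 * eps)
        assert np.abs(num - TruncatedNB.dloglik(y, eta, extra)).max() < 1e-6


def _tiny_intervention_dataset(rng, n_part=3, n_obs=4):
    """Hand-built answered records for likelihood oracle checks."""
    rows = []
    for i in range(n_part):
        for j in range(n_obs):
            signal = j + 1
            drank = bool(rng.random() < 0.5)
            rows.append(
                {
                    "participant_id": f"P{i+1}",
                    "group_id": "G01",
                    "condition": "mindfulness",
                    "signal_index": signal,
                    "weekday": "Mon",
                    "responded": True,
                    "drank": drank,
                    "beer": int(1 + rng.integers(4)) if drank else 0,
                    "wine": 0,
                    "liquor": 0,
                    "week_type": "active" if signal <= 2 else "inactive",
                }
            )
    rec = pd.DataFrame(rows)
    rec["drank"] = rec["drank"].astype("boolean")
    for c in ("beer", "wine", "liquor"):
        rec[c] = rec[c].astype("Int64")
    from emahurdle.preprocess import attach_structure
    from emahurdle.dataset import EMADataset, participants_from_records

    rec = attach_structure(rec)
    ds = EMADataset(rec, participants_from_records(rec), {})
    from emahurdle.preprocess import derive_covariates

    return derive_covariates(ds)


class TestHurdleLoglik:
    SPEC = ModelSpec(
        zi_terms=("intercept", "active_week"),
        cond_terms=("intercept",),
        random_terms=("participant",),
        agq_points=15,
    )

    def test_matches_grid_integration(self, rng):
        # one random intercept at SD 0.5, tiny data: AGQ must agree
        # with dense numerical integration
        ds = _tiny_intervention_dataset(rng)
        theta = np.array([0.2, 0.5, 0.5, 0.3, 0.5, math.log(1.5)])
        #               [b0,  b_aw, sd | b0c, sdc, log k]
        got = hurdle_loglik(theta, ds, self.SPEC)

        rec = ds.answered()
        rec = rec[rec["week_type"].isin(["active", "inactive"])]
        v = np.linspace(-8, 8, 20001)
        phi = stats.norm.pdf(v)

        def marginal(loglik_fn, sd):
            total = 0.0
            for _, sub in rec.groupby("participant_id"):
                ll = loglik_fn(sub)  # (n_obs, nodes)
                A = np.trapezoid(np.exp(ll.sum(axis=0)) * phi, v)
                total += math.log(A)
            return total

        def zi_ll(sub):
            z = (~sub["drank"].astype(bool)).to_numpy(float)[:, None]
            active = (sub["week_type"] == "active").to_numpy(float)[:, None]
            eta = 0.2 + 0.5 * active + 0.5 * v[None, :]
            return z * eta - np.logaddexp(0, eta)

        def cond_ll(sub):
            drank = sub["drank"].astype(bool)
            y = sub.loc[drank, "total_drinks"].to_numpy(float)[:, None]
            if y.size == 0:
                return np.zeros((0, v.size))
            mu = np.exp(0.3 + 0.5 * v[None, :]) * np.ones_like(y)
            return truncated_nb_logpmf(y, mu, 1.5)

        expected = marginal(zi_ll, 0.5) + marginal(cond_ll, 0.5)
        assert abs(got - expected) < 1e-5

    def test_zero_sd_reduces_to_independent_loglik(self, rng):
        ds = _tiny_intervention_dataset(rng)
        theta = np.array([0.2, 0.5, 0.0, 0.3, 0.0, math.log(1.5)])
        got = hurdle_loglik(theta, ds, self.SPEC)
        rec = ds.answered()
        z = (~rec["drank"].astype(bool)).to_numpy(float)
        active = (rec["week_type"] == "active").to_numpy(float)
        eta = 0.2 + 0.5 * active
        logistic = (z * eta - np.logaddexp(0, eta)).sum()
        y = rec.loc[rec["drank"].astype(bool), "total_drinks"].to_numpy(float)
        cond = truncated_nb_logpmf(y, math.exp(0.3), 1.5).sum()
        assert abs(got - (logistic + cond)) < 1e-10

    def test_empty_dataset_gives_zero(self, small_dataset):
        empty = small_dataset.copy()
        empty.records = empty.records[empty.records["responded"]].iloc[0:0]
        assert hurdle_loglik(
            np.zeros(6), empty, self.SPEC
        ) == 0.0


class TestWaldSummary:
    def test_null_coefficient(self):
        or_, lo, hi, p = wald_summary(0.0, 0.5)
        assert or_ == 1.0
        assert abs(lo - 0.3753) < 1e-4
        assert abs(hi - 2.6645) < 1e-4
        assert abs(p - 1.0) < 1e-12

    def test_small_se_limit(self):
        or_, lo, hi, p = wald_summary(math.log(2), 1e-6)
        assert abs(or_ - 2.0) < 1e-9
        assert abs(lo - 2.0) < 1e-4 and abs(hi - 2.0) < 1e-4
        assert p < 1e-100

    def test_matches_normal_cdf_oracle(self):
        b, se = 0.3293, 0.1320
        or_, lo, hi, p = wald_summary(b, se)
        assert abs(or_ - 1.39) < 0.005
        assert abs(lo - 1.07) < 0.005 and abs(hi - 1.80) < 0.005
        # brute-force oracle via the error function
        z = b / se
        p_oracle = math.erfc(z / math.sqrt(2))
        assert abs(p - p_oracle) < 1e-12
        assert abs(p - 0.013) < 0.001

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_summary(1.0, 0.0)

    @given(st.floats(-3, 3), st.floats(0.01, 2))
    def test_ci_brackets_or(self, b, se):
        or_, lo, hi, p = wald_summary(b, se)
        assert lo <= or_ <= hi
        assert 0 < p <= 1


def _bh_oracle(p):
    """Step-up BH written out longhand, independent of statsmodels."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.011, 0.816], [0.022, 0.816]),
            ([0.041, 0.575], [0.082, 0.575]),
        ],
    )
    def test_two_test_family(self, raw, expected):
        assert np.allclose(bh_adjust(raw), expected, atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_matches_longhand_step_up(self, raw):
        got = bh_adjust(raw)
        assert np.allclose(got, _bh_oracle(raw), atol=1e-12)
        assert np.all(got >= np.asarray(raw) - 1e-15)
        assert np.all(got <= 1.0)


@pytest.fixture(scope="module")
def norand_dataset():
    """Simulated trial with no random effects (SDs all zero)."""
    params = eh.GenerativeParams(
        seed=21,
        re_sd_participant_zi=0.0, re_sd_group_zi=0.0,
        re_sd_participant_cond=0.0, re_sd_group_cond=0.0,
    )
    design = eh.StudyDesign(n_groups=6, participants_per_group=12)
    return eh.generate_dataset(design, params)


SMALL_SPEC = ModelSpec(
    zi_terms=("intercept", "active_week", "social_weekend"),
    cond_terms=("intercept", "active_week", "social_weekend"),
    agq_points=7,
)


class TestFitHurdle:
    def test_no_random_effects_matches_plain_glm_fits(self, norand_dataset):
        # with the SDs pinned at zero the mixed machinery must agree
        # with independent fixed-effects-only fits of each sub-model
        fit = fit_hurdle(
            norand_dataset, dataclasses.replace(SMALL_SPEC, random_terms=())
        )
        rec = norand_dataset.answered()
        rec = rec[rec["week_type"].isin(["active", "inactive"])]
        X = np.column_stack(
            [
                np.ones(len(rec)),
                (rec["week_type"] == "active").to_numpy(float),
                rec["social_weekend"].to_numpy(float),
            ]
        )
        z = (~rec["drank"].astype(bool)).to_numpy(float)

        import statsmodels.api as sm

        logit = sm.Logit(z, X).fit(disp=0)
        assert np.abs(fit.zero.coef - logit.params).max() < 1e-3

        drank = rec["drank"].astype(bool).to_numpy()
        y = rec.loc[drank, "total_drinks"].to_numpy(float)
        Xp = X[drank]

        def negll(theta):
            mu = np.exp(Xp @ theta[:-1])
            k = math.exp(theta[-1])
            n, pr = k, k / (k + mu)
            ll = stats.nbinom.logpmf(y, n, pr) - np.log1p(-stats.nbinom.pmf(0, n, pr))
            return -ll.sum()

        res = optimize.minimize(negll, np.zeros(4), method="BFGS")
        assert np.abs(fit.conditional.coef - res.x[:-1]).max() < 1e-3
        assert abs(math.log(fit.conditional.dispersion) - res.x[-1]) < 5e-3

    def test_free_sds_shrink_when_data_have_none(self, norand_dataset):
        # with random effects estimated freely on the same data the SD
        # estimates stay near the boundary and the slopes stay close to
        # the plain-GLM values (exact agreement is not expected: a
        # small positive SD can fit noise)
        free = fit_hurdle(norand_dataset, SMALL_SPEC, submodels=("zero",)).zero
        assert max(free.re_sd.values()) < 0.3
        pinned = fit_hurdle(
            norand_dataset, dataclasses.replace(SMALL_SPEC, random_terms=()),
            submodels=("zero",),
        ).zero
        assert np.abs(free.coef - pinned.coef).max() < 0.1

    def test_random_effects_nest_fixed_only_fit(self, medium_dataset):
        free = fit_hurdle(medium_dataset, SMALL_SPEC, submodels=("zero",))
        pinned = fit_hurdle(
            medium_dataset,
            dataclasses.replace(SMALL_SPEC, random_terms=()),
            submodels=("zero",),
        )
        assert free.zero.loglik >= pinned.zero.loglik - 1e-6

    def test_quadrature_point_convergence(self, medium_dataset):
        est = {}
        for q in (7, 15):
            spec = dataclasses.replace(SMALL_SPEC, agq_points=q)
            est[q] = fit_hurdle(medium_dataset, spec, submodels=("zero",)).zero.coef
        assert np.abs(est[7] - est[15]).max() < 1e-3

    def test_week_relabeling_inverts_odds_ratios(self, medium_dataset):
        fit_a = fit_hurdle(medium_dataset, SMALL_SPEC, submodels=("zero",)).zero
        swapped = dataclasses.replace(SMALL_SPEC, active_level="inactive")
        fit_b = fit_hurdle(medium_dataset, swapped, submodels=("zero",)).zero
        i = fit_a.terms.index("active_week")
        assert fit_a.odds_ratio[i] == pytest.approx(
            1.0 / fit_b.odds_ratio[i], rel=2e-3
        )

    def test_more_zeros_on_active_weeks_gives_or_above_one(self):
        # simulate a strong reminder effect; the zero sub-model OR for
        # active week must exceed 1 (more non-drinking occasions)
        params = eh.GenerativeParams(seed=3, zi_active_week=math.log(2.5))
        ds = eh.generate_dataset(
            eh.StudyDesign(n_groups=8, participants_per_group=12), params
        )
        fit = fit_hurdle(ds, dataclasses.replace(SMALL_SPEC, agq_points=1),
                         submodels=("zero",))
        assert fit.zero["active_week"]["OR"] > 1.0

    def test_degenerate_outcomes_raise(self, small_dataset):
        all_dry = small_dataset.copy()
        rec = all_dry.records
        drank_idx = (rec["drank"] == True).fillna(False)  # noqa: E712
        rec.loc[drank_idx, "drank"] = False
        rec.loc[drank_idx, ["beer", "wine", "liquor", "total_drinks"]] = 0
        with pytest.raises(DegenerateOutcomeError, match="zero"):
            fit_hurdle(all_dry, SMALL_SPEC)

    def test_coef_table_shape(self, medium_dataset):
        fit = fit_hurdle(medium_dataset, SMALL_SPEC, submodels=("zero",))
        tab = fit.zero.coef_table()
        assert list(tab["term"]) == list(SMALL_SPEC.zi_terms)
        assert (tab["ci_low"] <= tab["OR"]).all()
        assert (tab["OR"] <= tab["ci_high"]).all()
        assert tab["p"].between(0, 1, inclusive="right").all()
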