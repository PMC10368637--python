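"""Multilevel hurdle model for twice-daily drinking reports.

The outcome of an answered survey is the number of drinks since the
previous survey.  Two sub-models are estimated separately:

* a **zero sub-model** — logistic regression on the indicator of *no*
  alcohol use, so an odds ratio above 1 means more non-drinking
  occasions (the reporting orientation used throughout);
* a **conditional sub-model** — a zero-truncated negative binomial for
  the drink count on drinking occasions, mean ``mu = exp(x'b)`` and
  variance ``mu + mu^2/k``.

Each sub-model carries nested random intercepts (participant within
social group, and group), integrated out by adaptive Gauss–Hermite
quadrature (:mod:`emahurdle._agq`).  Fixed-effect covariates follow the
crossover design: active vs. inactive week, distancing strategy
contrast (perspective-taking vs. mindfulness), signal count (time
trend), each participant's total number of answered surveys (controls
for differential compliance between week types), and the social
weekend (Thursday–Saturday).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln
from statsmodels.stats.multitest import multipletests

from ._agq import NestedMarginalLogLik, SD_EPS, NumericalError
from .dataset import EMADataset

__all__ = [
    "ModelSpec",
    "HurdleFit",
    "SubmodelFit",
    "DegenerateOutcomeError",
    "truncated_nb_logpmf",
    "hurdle_loglik",
    "fit_hurdle",
    "wald_summary",
    "bh_adjust",
]

_ETA_CLIP = 30.0


class DegenerateOutcomeError(ValueError):
    """An outcome vector leaves one sub-model with nothing to fit."""


# ---------------------------------------------------------------------------
# observation families
# ---------------------------------------------------------------------------

def truncated_nb_logpmf(y, mu, k):
    """Log-pmf of the zero-truncated negative binomial.

    ``NB(y; mu, k)`` is parameterized by mean ``mu`` and dispersion
    ``k`` (variance ``mu + mu^2/k``); the zero class is removed and the
    remaining mass renormalized:
    ``log[ NB(y) / (1 - NB(0)) ]`` for integer ``y >= 1``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(y < 1):
        raise ValueError("truncated support starts at y = 1")
    if np.any(mu <= 0) or np.any(k <= 0):
        raise ValueError("mu and k must be positive")
    log_kmu = np.log(k + mu)
    log_nb = (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1.0)
        + k * (np.log(k) - log_kmu)
        + y * (np.log(mu) - log_kmu)
    )
    log_p0 = k * (np.log(k) - log_kmu)
    # log(1 - p0) via expm1 — p0 -> 1 as mu -> 0
    log_1mp0 = np.log(-np.expm1(log_p0))
    return log_nb - log_1mp0


class BernoulliLogit:
    """Bernoulli outcome, logit link; no auxiliary parameters."""

    n_extra = 0

    @staticmethod
    def loglik(y, eta, extra=()):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def dloglik(y, eta, extra=()):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return y - expit(eta)


class TruncatedNB:
    """Zero-truncated negative binomial, log link; extra = (log k,)."""

    n_extra = 1

    @staticmethod
    def loglik(y, eta, extra):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        k = np.exp(np.clip(extra[0], -20.0, 20.0))
        return truncated_nb_logpmf(y, mu, k)

    @staticmethod
    def dloglik(y, eta, extra):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        k = np.exp(np.clip(extra[0], -20.0, 20.0))
        log_kmu = np.log(k + mu)
        log_p0 = k * (np.log(k) - log_kmu)
        log_1mp0 = np.log(-np.expm1(log_p0))
        odds_p0 = np.exp(log_p0 - log_1mp0)  # p0 / (1 - p0)
        return y - (y + k) * mu / (k + mu) - mu * k * odds_p0 / (k + mu)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

DEFAULT_TERMS = (
    "intercept",
    "active_week",
    "condition",
    "signal_count",
    "n_responses",
    "social_weekend",
    "condition:active_week",
)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random-effect structure and estimation options.

    ``active_level`` names the week type coded 1 (default "active",
    reference = inactive); the condition contrast is perspective-taking
    vs. the mindfulness reference.  ``random_terms`` may drop either
    intercept.  ``agq_points = 1`` requests the Laplace approximation.
    """

    zi_terms: tuple = DEFAULT_TERMS
    cond_terms: tuple = DEFAULT_TERMS
    random_terms: tuple = ("group", "participant")
    active_level: str = "active"
    agq_points: int = 7
    optimizer_tol: float = 1e-8
    max_iter: int = 300
    n_restarts: int = 3

    def terms_for(self, submodel: str) -> tuple:
        return self.zi_terms if submodel == "zero" else self.cond_terms


def _design_matrix(rec: pd.DataFrame, terms, active_level: str) -> np.ndarray:
    active = (rec["week_type"] == active_level).to_numpy(dtype=float)
    perspective = (rec["condition"] == "perspective_taking").to_numpy(dtype=float)
    builders = {
        "intercept": lambda: np.ones(len(rec)),
        "active_week": lambda: active,
        "condition": lambda: perspective,
        "signal_count": lambda: rec["signal_count"].to_numpy(dtype=float),
        "n_responses": lambda: rec["n_responses"].to_numpy(dtype=float),
        "social_weekend": lambda: rec["social_weekend"].to_numpy(dtype=float),
        "condition:active_week": lambda: perspective * active,
    }
    cols = []
    for t in terms:
        if t not in builders:
            raise ValueError(f"unknown model term {t!r}")
        cols.append(builders[t]())
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class SubmodelFit:
    """One fitted sub-model: Wald table plus variance components."""

    name: str
    terms: tuple
    coef: np.ndarray
    se: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    re_sd: dict
    re_var: dict
    dispersion: float | None
    loglik: float
    converged: bool
    n_obs: int

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "submodel": self.name,
                "term": list(self.terms),
                "estimate": self.coef,
                "se": self.se,
                "OR": self.odds_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "estimate": self.coef[i],
            "se": self.se[i],
            "OR": self.odds_ratio[i],
            "ci_low": self.ci_low[i],
            "ci_high": self.ci_high[i],
            "p": self.p[i],
        }


@dataclass
class HurdleFit:
    """Joint result of the zero and conditional sub-models."""

    zero: SubmodelFit | None
    conditional: SubmodelFit | None
    n_observations: int
    n_participants: int
    n_groups: int
    spec: ModelSpec = None

    def coef_table(self) -> pd.DataFrame:
        parts = [s.coef_table() for s in (self.zero, self.conditional) if s]
        return pd.concat(parts, ignore_index=True)

    def to_dict(self) -> dict:
        out = {
            "n_observations": self.n_observations,
            "n_participants": self.n_participants,
            "n_groups": self.n_groups,
            "submodels": {},
        }
        for sub in (self.zero, self.conditional):
            if sub is None:
                continue
            out["submodels"][sub.name] = {
                "terms": list(sub.terms),
                "estimate": sub.coef.tolist(),
                "se": sub.se.tolist(),
                "OR": sub.odds_ratio.tolist(),
                "ci_low": sub.ci_low.tolist(),
                "ci_high": sub.ci_high.tolist(),
                "p": sub.p.tolist(),
                "re_sd": sub.re_sd,
                "re_var": sub.re_var,
                "dispersion": sub.dispersion,
                "loglik": sub.loglik,
                "converged": sub.converged,
                "n_obs": sub.n_obs,
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def wald_summary(b, se):
    """Odds ratio, 95% Wald interval and two-sided normal p-value."""
    b = np.asarray(b, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    or_ = np.exp(b)
    lo = np.exp(b - 1.96 * se)
    hi = np.exp(b + 1.96 * se)
    p = 2.0 * stats.norm.sf(np.abs(b / se))
    p = np.maximum(p, np.finfo(float).tiny)
    return or_, lo, hi, p


def bh_adjust(pvalues):
    """Benjamini–Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# likelihood assembly and fitting
# ---------------------------------------------------------------------------

def _prepare_submodel(dataset: EMADataset, spec: ModelSpec, submodel: str):
    """Outcome vector, design matrix and nesting indices for one sub-model."""
    from .preprocess import derive_covariates

    if "n_responses" not in dataset.records.columns:
        dataset = derive_covariates(dataset)
    rec = dataset.answered()
    terms = spec.terms_for(submodel)
    if "active_week" in terms or "condition:active_week" in terms:
        rec = rec[rec["week_type"].isin(["active", "inactive"])]
    if submodel == "zero":
        y = (~rec["drank"].astype(bool)).to_numpy(dtype=float)
    else:
        rec = rec[rec["drank"].astype(bool)]
        y = rec["total_drinks"].to_numpy(dtype=float)
    pid = pd.Categorical(rec["participant_id"])
    part_idx = pid.codes.astype(np.intp)
    gid_of_part = (
        rec.groupby(pd.Categorical(rec["participant_id"]), observed=True)["group_id"]
        .first()
        .reindex(pid.categories)
    )
    group_codes = pd.Categorical(gid_of_part).codes.astype(np.intp)
    X = _design_matrix(rec, terms, spec.active_level)
    return y, X, part_idx, group_codes, terms, rec


def _split_theta(theta, n_beta, random_terms, family):
    theta = np.asarray(theta, dtype=float)
    beta = theta[:n_beta]
    i = n_beta
    sd_part = sd_group = 0.0
    if "participant" in random_terms:
        sd_part = theta[i]
        i += 1
    if "group" in random_terms:
        sd_group = theta[i]
        i += 1
    extra = tuple(theta[i:i + family.n_extra])
    return beta, sd_part, sd_group, extra


def _submodel_negloglik_factory(dataset, spec, submodel, X_override=None):
    family = BernoulliLogit if submodel == "zero" else TruncatedNB
    y, X, part_idx, group_codes, terms, _ = _prepare_submodel(dataset, spec, submodel)
    if X_override is not None:
        X = X_override
    evaluator = NestedMarginalLogLik(
        y, X, part_idx, group_codes, family, n_points=spec.agq_points
    )
    n_beta = len(terms)

    def negloglik(theta):
        beta, sd_part, sd_group, extra = _split_theta(
            theta, n_beta, spec.random_terms, family
        )
        try:
            return -evaluator.value(beta, max(sd_part, 0.0),
                                    max(sd_group, 0.0), extra)
        except (NumericalError, FloatingPointError, OverflowError):
            return 1e12

    return negloglik, y, X, terms, family, evaluator


def _standardizer(X, terms):
    """Internal column standardization for optimizer conditioning.

    Returns the standardized matrix and the linear map A with
    ``beta_raw = A @ beta_std`` (identity when no column is rescaled).
    Columns are centered only when an intercept absorbs the shift.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    has_intercept = "intercept" in terms
    icol = terms.index("intercept") if has_intercept else -1
    A = np.eye(p)
    Xs = X.copy()
    for j in range(p):
        if j == icol:
            continue
        col = X[:, j]
        s = col.std()
        uniq = np.unique(col)
        if s == 0 or (uniq.size <= 2 and np.isin(uniq, [0.0, 1.0]).all()):
            continue
        m = col.mean() if has_intercept else 0.0
        Xs[:, j] = (col - m) / s
        A[j, j] = 1.0 / s
        if has_intercept:
            A[icol, j] = -m / s
    return Xs, A


def hurdle_loglik(theta, dataset: EMADataset, spec: ModelSpec | None = None) -> float:
    """Joint marginal log-likelihood of both sub-models.

    ``theta`` concatenates the zero sub-model parameters
    ``[beta..., sd_participant?, sd_group?]`` (random-effect SDs present
    per ``spec.random_terms``) followed by the conditional sub-model's
    ``[beta..., sd_participant?, sd_group?, log_k]``.  The sub-models
    share no parameters, so the joint value is the sum.
    """
    spec = spec or ModelSpec()
    n_sd = len(spec.random_terms)
    n_zero = len(spec.zi_terms) + n_sd
    theta = np.asarray(theta, dtype=float)
    nll_zero, *_ = _submodel_negloglik_factory(dataset, spec, "zero")
    nll_cond, *_ = _submodel_negloglik_factory(dataset, spec, "conditional")
    expected = n_zero + len(spec.cond_terms) + n_sd + 1
    if theta.size != expected:
        raise ValueError(f"theta must have length {expected}, got {theta.size}")
    return -(nll_zero(theta[:n_zero]) + nll_cond(theta[n_zero:]))


def _start_values(y, X, terms, family):
    """Plain-GLM warm start for the fixed effects."""
    import statsmodels.api as sm

    try:
        if family is BernoulliLogit:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
        else:
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=50)
        beta0 = np.asarray(fit.params, dtype=float)
        if not np.all(np.isfinite(beta0)):
            raise ValueError
        np.clip(beta0, -10.0, 10.0, out=beta0)
    except Exception:
        beta0 = np.zeros(X.shape[1])
    return beta0


def _clipped_inverse(H):
    """Inverse of the observed information, robust to indefiniteness.

    A finite-difference Hessian near a boundary (random-effect SD at 0)
    or on a flat small-sample likelihood can have non-positive
    eigenvalues; these are floored at a small positive multiple of the
    largest eigenvalue, which yields large (conservative) variances for
    the affected directions instead of spurious zeros.
    """
    H = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(H)
    floor = max(np.abs(vals).max(), 1.0) * 1e-10
    vals = np.maximum(vals, floor)
    return (vecs / vals) @ vecs.T


def _fd_hessian(fun, x, rel_step=1e-3):
    x = np.asarray(x, dtype=float)
    n = x.size
    h = np.maximum(np.abs(x) * rel_step, rel_step)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xi, xj = np.zeros(n), np.zeros(n)
            xi[i] = h[i]
            xj[j] = h[j]
            if i == j:
                fpp = fun(x + 2 * xi)
                fmm = fun(x - 2 * xi)
                H[i, i] = (fpp - 2 * f0 + fmm) / (4 * h[i] ** 2)
            else:
                fpp = fun(x + xi + xj)
                fpm = fun(x + xi - xj)
                fmp = fun(x - xi + xj)
                fmm = fun(x - xi - xj)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _fit_one_submodel(dataset, spec, submodel, rng=None) -> SubmodelFit:
    _, y, X_raw, terms, family, _ = _submodel_negloglik_factory(
        dataset, spec, submodel
    )
    if y.size == 0:
        raise DegenerateOutcomeError(f"{submodel} sub-model has no observations")
    if submodel == "zero" and (np.all(y == 0) or np.all(y == 1)):
        raise DegenerateOutcomeError(
            "zero sub-model cannot be fit: outcomes are all "
            + ("positive (no zero)" if np.all(y == 0) else "zero (no drinking)")
        )

    # optimize in a standardized-covariate parameterization
    Xs, A = _standardizer(X_raw, terms)
    negloglik, *_ = _submodel_negloglik_factory(dataset, spec, submodel,
                                                X_override=Xs)
    n_beta = len(terms)
    beta0 = _start_values(y, Xs, terms, family)
    sds0 = [0.3] * len(spec.random_terms)
    extra0 = [0.0] * family.n_extra
    x0 = np.concatenate([beta0, sds0, extra0])
    bounds = (
        [(None, None)] * n_beta
        + [(0.0, None)] * len(spec.random_terms)
        + [(None, None)] * family.n_extra
    )

    rng = rng or np.random.default_rng(0)
    best = None
    for attempt in range(spec.n_restarts + 1):
        res = optimize.minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": spec.max_iter,
                "ftol": spec.optimizer_tol,
                "gtol": 1e-6,
                "eps": 1e-5,
            },
        )
        if best is None or res.fun < best.fun - 1e-8:
            best = res
        if best.success:
            break
        x0 = np.concatenate(
            [beta0 + 0.2 * rng.standard_normal(n_beta), sds0, extra0]
        )
    res = best

    theta = res.x
    beta_std, sd_part, sd_group, extra = _split_theta(
        theta, n_beta, spec.random_terms, family
    )
    beta = A @ beta_std
    H = _fd_hessian(negloglik, theta)
    cov = _clipped_inverse(H)
    # map the covariance back to the raw-covariate scale
    A_full = np.eye(theta.size)
    A_full[:n_beta, :n_beta] = A
    cov = A_full @ cov @ A_full.T
    var = np.diag(cov)[:n_beta]
    se = np.sqrt(np.maximum(var, 1e-12))
    or_, lo, hi, p = wald_summary(beta, se)

    re_sd, re_var = {}, {}
    if "participant" in spec.random_terms:
        re_sd["participant"] = float(sd_part)
        re_var["participant"] = float(sd_part**2)
    if "group" in spec.random_terms:
        re_sd["group"] = float(sd_group)
        re_var["group"] = float(sd_group**2)

    return SubmodelFit(
        name=submodel,
        terms=terms,
        coef=beta.copy(),
        se=se,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p=p,
        re_sd=re_sd,
        re_var=re_var,
        dispersion=float(np.exp(extra[0])) if family.n_extra else None,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_obs=int(y.size),
    )


def fit_hurdle(
    dataset: EMADataset,
    spec: ModelSpec | None = None,
    submodels: tuple = ("zero", "conditional"),
) -> HurdleFit:
    """Maximum-likelihood fit of the multilevel hurdle model.

    Control-arm records are excluded whenever the active-week contrast
    is in the term list (controls have no active/inactive weeks).
    Standard errors come from the inverse finite-difference observed
    information; odds ratios, 95% CIs and p-values are Wald summaries.
    """
    spec = spec or ModelSpec()
    fits = {}
    for name in submodels:
        fits[name] = _fit_one_submodel(dataset, spec, name)
    _, _, part_idx, group_codes, _, rec = _prepare_submodel(dataset, spec, "zero")
    return HurdleFit(
        zero=fits.get("zero"),
        conditional=fits.get("conditional"),
        n_observations=int(len(rec)),
        n_participants=int(part_idx.max()) + 1 if len(rec) else 0,
        n_groups=int(group_codes.max()) + 1 if len(rec) else 0,
        spec=spec,
    )
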