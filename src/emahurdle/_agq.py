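"""Marginal log-likelihood for GLMs with nested random intercepts.

Integrates out a participant-within-group intercept and a group
intercept by nested one-dimensional adaptive Gauss–Hermite quadrature:
for each group-level node the participant integrals are recentred at
their conditional modes (found by Newton steps with finite-difference
curvature) and rescaled by the local curvature, which keeps a handful
of nodes accurate even with 50+ observations per participant.  One
quadrature point per dimension is the Laplace approximation.

The likelihood for group g is

    L_g = ∫ φ(u) Π_{i∈g} [ ∫ φ(v) Π_j f(y_ij | x_ij'β + σ_g u + σ_p v) dv ] du

with f supplied by a family object exposing ``loglik(y, eta, extra)``
and ``dloglik(y, eta, extra)`` (``extra`` holds auxiliary parameters
such as a log-dispersion).  A standard-deviation below ``SD_EPS`` is
treated as exactly zero (the integral collapses to a point mass), so
the no-random-effects model is nested without a boundary artefact.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

SD_EPS = 1e-8
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class NumericalError(RuntimeError):
    """Non-finite quantities encountered during likelihood evaluation."""


class NestedMarginalLogLik:
    """Reusable evaluator bound to one response vector and design.

    Parameters
    ----------
    y, X:
        Outcome vector and fixed-effect design matrix (n_obs x p).
    part_idx:
        Per-observation participant index in ``0..n_part-1``.
    group_of_part:
        Per-participant group index in ``0..n_groups-1``.
    family:
        Observation family (Bernoulli-logit or truncated NB).
    n_points:
        Quadrature points per dimension; 1 gives Laplace.
    """

    def __init__(self, y, X, part_idx, group_of_part, family, n_points: int = 7):
        self.y = np.asarray(y)
        self.X = np.asarray(X, dtype=float)
        self.part_idx = np.asarray(part_idx, dtype=np.intp)
        self.group_of_part = np.asarray(group_of_part, dtype=np.intp)
        self.family = family
        self.n_obs = self.y.shape[0]
        self.n_part = self.group_of_part.shape[0]
        self.n_groups = int(self.group_of_part.max()) + 1 if self.n_part else 0
        if n_points < 1:
            raise ValueError("n_points must be >= 1")
        self.z, self.w = np.polynomial.hermite.hermgauss(n_points)
        self._v_cache = np.zeros(self.n_part)
        self._u_cache = np.zeros(self.n_groups)

    # -- participant-level integral ------------------------------------

    def _part_loglik_sums(self, eta, extra):
        ll = self.family.loglik(self.y, eta, extra)
        return np.bincount(self.part_idx, weights=ll, minlength=self.n_part)

    def _inner(self, eta0, a_part, sd_part, extra):
        """log A_i for every participant given group offsets ``a_part``."""
        if sd_part < SD_EPS:
            eta = eta0 + a_part[self.part_idx]
            return self._part_loglik_sums(eta, extra)

        base = eta0 + a_part[self.part_idx]

        def grad(v):
            eta = base + sd_part * v[self.part_idx]
            d = self.family.dloglik(self.y, eta, extra)
            dsum = np.bincount(self.part_idx, weights=d, minlength=self.n_part)
            return sd_part * dsum - v

        v = self._v_cache.copy()
        h = np.full(self.n_part, -1.0)
        delta = 1e-4
        for _ in range(60):
            g = grad(v)
            h = (grad(v + delta) - grad(v - delta)) / (2.0 * delta)
            h = np.minimum(h, -1e-6)
            step = g / h
            # damp huge Newton proposals far from the mode
            np.clip(step, -5.0, 5.0, out=step)
            v = v - step
            if np.max(np.abs(step)) < 1e-9:
                break
        self._v_cache = v
        tau = 1.0 / np.sqrt(-h)

        contrib = np.empty((self.z.size, self.n_part))
        for r, (zr, wr) in enumerate(zip(self.z, self.w)):
            vr = v + np.sqrt(2.0) * tau * zr
            eta = base + sd_part * vr[self.part_idx]
            S = self._part_loglik_sums(eta, extra)
            contrib[r] = (
                np.log(np.sqrt(2.0) * tau * wr)
                + zr**2
                + S
                - 0.5 * vr**2
                - _LOG_SQRT_2PI
            )
        return logsumexp(contrib, axis=0)

    # -- group-level integral ------------------------------------------

    def value(self, beta, sd_part, sd_group, extra=()) -> float:
        """Marginal log-likelihood at the given parameters."""
        if self.n_obs == 0:
            return 0.0
        eta0 = self.X @ np.asarray(beta, dtype=float)
        if not np.all(np.isfinite(eta0)):
            raise NumericalError(
                f"non-finite linear predictor at beta={np.asarray(beta)!r}"
            )

        def T(u):
            a_part = sd_group * u[self.group_of_part]
            logA = self._inner(eta0, a_part, sd_part, extra)
            return np.bincount(self.group_of_part, weights=logA,
                               minlength=self.n_groups)

        if sd_group < SD_EPS:
            return float(np.sum(self._inner(eta0, np.zeros(self.n_part),
                                            sd_part, extra)))

        # moderately large FD step: the curvature enters the quadrature
        # scale directly, so a too-small step would inject FD noise into
        # the objective and wreck outer finite-difference gradients
        u = self._u_cache.copy()
        delta = 1e-2
        for _ in range(30):
            F0 = T(u) - 0.5 * u**2
            Fp = T(u + delta) - 0.5 * (u + delta) ** 2
            Fm = T(u - delta) - 0.5 * (u - delta) ** 2
            g = (Fp - Fm) / (2.0 * delta)
            h = np.minimum((Fp - 2.0 * F0 + Fm) / delta**2, -1e-6)
            step = g / h
            np.clip(step, -5.0, 5.0, out=step)
            u = u - step
            if np.max(np.abs(step)) < 1e-6:
                break
        self._u_cache = u
        F0 = T(u) - 0.5 * u**2
        Fp = T(u + delta) - 0.5 * (u + delta) ** 2
        Fm = T(u - delta) - 0.5 * (u - delta) ** 2
        h = np.minimum((Fp - 2.0 * F0 + Fm) / delta**2, -1e-6)
        tau = 1.0 / np.sqrt(-h)

        contrib = np.empty((self.z.size, self.n_groups))
        for r, (zr, wr) in enumerate(zip(self.z, self.w)):
            ur = u + np.sqrt(2.0) * tau * zr
            contrib[r] = (
                np.log(np.sqrt(2.0) * tau * wr)
                + zr**2
                + T(ur)
                - 0.5 * ur**2
                - _LOG_SQRT_2PI
            )
        total = float(np.sum(logsumexp(contrib, axis=0)))
        if not np.isfinite(total):
            raise NumericalError("non-finite marginal log-likelihood")
        return total
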