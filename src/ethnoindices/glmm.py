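"""Poisson mixed models with crossed random intercepts (Laplace fit).

Counts of use-types within a use-category are pseudo-replicated: each
informant contributes one cell per species and each species one cell per
informant.  The model therefore adds two crossed, non-nested random
intercepts — one per informant, one per species — to the fixed-effect
log-linear predictor:

    y_ij ~ Poisson(mu_ij),  log mu_ij = x_ij' beta + a_i + b_j,
    a_i ~ N(0, sigma_p^2),  b_j ~ N(0, sigma_s^2).

The marginal likelihood is approximated by a Laplace approximation (one
quadrature point).  For fixed variance parameters, the fixed effects and
random-effect modes are found jointly by penalized Newton iterations; the
two log standard deviations are then optimized by Nelder-Mead on the
Laplace log-likelihood.  The Newton system is solved by eliminating the
(large, diagonal) informant block, so each iteration costs O(n) plus a
small dense solve in the species-plus-fixed-effect block.

Numerical settings: inner Newton tolerance 1e-8 with step halving, at
most 500 iterations; a fitted log-sd below -6 (sd < 2.5e-3) is reported
as a variance at the boundary (zero), which is a diagnostic, not an
error.  Fits are maximum likelihood, so likelihood-ratio tests between
nested fixed-effect structures are valid for the stepwise simplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_data import ValidationError
from .count_models import (ModelResult, ModelSpec, build_design,
                           term_label)

__all__ = ["fit_poisson_glmm", "glmm_drop_term_test",
           "stepwise_backward_glmm"]

_BOUNDARY_LOG_SD = -6.0
_ETA_MAX = 30.0  # exp overflow guard; counts here are far below e^30


def _penalized_loglik(y, eta, u1, u2, s1, s2, logfact):
    mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    ll = float(np.sum(y * eta - mu) - logfact)
    pen = 0.5 * float(u1 @ u1) / s1 ** 2
    if u2 is not None:
        pen += 0.5 * float(u2 @ u2) / s2 ** 2
    return ll - pen, mu


class _LaplaceFitter:
    """Joint (beta, u) mode and Laplace log-likelihood for fixed sds."""

    def __init__(self, y, X, g1, q1, g2, q2):
        self.y, self.X = y, X
        self.g1, self.q1 = g1, q1
        self.g2, self.q2 = g2, q2          # g2/q2 may be None/0
        self.n, self.p = X.shape
        self.logfact = float(special.gammaln(y + 1).sum())
        self.beta = np.zeros(self.p)
        self.beta[0] = math.log(max(y.mean(), 1e-8))
        self.u1 = np.zeros(q1)
        self.u2 = np.zeros(q2) if q2 else None

    def _eta(self, beta, u1, u2):
        eta = self.X @ beta + u1[self.g1]
        if u2 is not None:
            eta = eta + u2[self.g2]
        return eta

    def _blocks(self, mu, s1, s2):
        """Hessian blocks of the penalized objective (negated)."""
        X, g1, g2 = self.X, self.g1, self.g2
        WX = mu[:, None] * X
        Hbb = X.T @ WX
        D1 = np.bincount(g1, weights=mu, minlength=self.q1) + 1.0 / s1 ** 2
        Hu1b = np.zeros((self.q1, self.p))
        np.add.at(Hu1b, g1, WX)
        if self.u2 is None:
            return Hbb, D1, Hu1b, None, None, None
        D2 = np.bincount(g2, weights=mu, minlength=self.q2) + 1.0 / s2 ** 2
        Hu2b = np.zeros((self.q2, self.p))
        np.add.at(Hu2b, g2, WX)
        S = np.zeros((self.q1, self.q2))
        np.add.at(S, (g1, g2), mu)
        return Hbb, D1, Hu1b, D2, Hu2b, S

    def mode(self, s1, s2, tol=1e-8, max_iter=500):
        """Newton iterations to the joint penalized mode."""
        beta, u1 = self.beta.copy(), self.u1.copy()
        u2 = None if self.u2 is None else self.u2.copy()
        eta = self._eta(beta, u1, u2)
        pll, mu = _penalized_loglik(self.y, eta, u1, u2, s1, s2, self.logfact)
        converged = False
        for _ in range(max_iter):
            resid = self.y - mu
            gb = self.X.T @ resid
            g1v = np.bincount(self.g1, weights=resid,
                              minlength=self.q1) - u1 / s1 ** 2
            Hbb, D1, Hu1b, D2, Hu2b, S = self._blocks(mu, s1, s2)
            if u2 is None:
                # eliminate the informant block from [[Hbb, Hu1b'],[Hu1b, D1]]
                Binv = Hu1b / D1[:, None]
                A = Hbb - Hu1b.T @ Binv
                rhs = gb - Binv.T @ g1v
                try:
                    dv = np.linalg.solve(A, rhs)
                except np.linalg.LinAlgError:
                    break
                db, du2 = dv, None
                du1 = (g1v - Hu1b @ dv) / D1
            else:
                g2v = np.bincount(self.g2, weights=resid,
                                  minlength=self.q2) - u2 / s2 ** 2
                # small block v = (beta, u2); eliminate u1
                B = np.hstack([Hu1b, S])                      # (q1, p+q2)
                A = np.zeros((self.p + self.q2, self.p + self.q2))
                A[:self.p, :self.p] = Hbb
                A[:self.p, self.p:] = Hu2b.T
                A[self.p:, :self.p] = Hu2b
                A[self.p:, self.p:] = np.diag(D2)
                Binv = B / D1[:, None]
                A = A - B.T @ Binv
                gv = np.concatenate([gb, g2v])
                rhs = gv - Binv.T @ g1v
                try:
                    dv = np.linalg.solve(A, rhs)
                except np.linalg.LinAlgError:
                    break
                db, du2 = dv[:self.p], dv[self.p:]
                du1 = (g1v - B @ dv) / D1
            # step-halving line search on the penalized log-likelihood
            step = 1.0
            for _ls in range(30):
                nb = beta + step * db
                nu1 = u1 + step * du1
                nu2 = None if u2 is None else u2 + step * du2
                neta = self._eta(nb, nu1, nu2)
                npll, nmu = _penalized_loglik(self.y, neta, nu1, nu2, s1, s2,
                                              self.logfact)
                if npll >= pll - 1e-12:
                    break
                step *= 0.5
            gain = npll - pll
            beta, u1, u2, eta, mu, pll = nb, nu1, nu2, neta, nmu, npll
            gnorm = max(np.max(np.abs(gb)), np.max(np.abs(g1v)))
            if gain < tol and gnorm < math.sqrt(tol) * (1 + abs(pll)):
                converged = True
                break
        self.beta, self.u1, self.u2 = beta, u1, u2  # warm start next call
        return beta, u1, u2, mu, pll, converged

    def _laplace_from_mode(self, mu, pll, s1, s2):
        _, D1, _, D2, _, S = self._blocks(mu, s1, s2)
        logdet = float(np.log(D1).sum())
        if self.u2 is not None:
            M = np.diag(D2) - (S / D1[:, None]).T @ S
            sign, ld2 = np.linalg.slogdet(M)
            if sign <= 0:
                return -math.inf
            logdet += ld2
        ll = pll - self.q1 * math.log(s1) - 0.5 * logdet
        if self.u2 is not None:
            ll -= self.q2 * math.log(s2)
        return ll

    def laplace_loglik(self, s1, s2):
        """Laplace log-likelihood with beta profiled at the joint mode."""
        beta, u1, u2, mu, pll, converged = self.mode(s1, s2)
        return self._laplace_from_mode(mu, pll, s1, s2), converged

    def mode_u(self, beta, s1, s2, tol=1e-10, max_iter=200):
        """Newton iterations over the random effects only (beta fixed)."""
        u1 = self.u1.copy()
        u2 = None if self.u2 is None else self.u2.copy()
        xb = self.X @ beta
        eta = xb + u1[self.g1] + (0 if u2 is None else u2[self.g2])
        pll, mu = _penalized_loglik(self.y, eta, u1, u2, s1, s2, self.logfact)
        for _ in range(max_iter):
            resid = self.y - mu
            g1v = np.bincount(self.g1, weights=resid,
                              minlength=self.q1) - u1 / s1 ** 2
            D1 = np.bincount(self.g1, weights=mu,
                             minlength=self.q1) + 1.0 / s1 ** 2
            if u2 is None:
                du1, du2 = g1v / D1, None
                gmax = np.max(np.abs(g1v))
            else:
                g2v = np.bincount(self.g2, weights=resid,
                                  minlength=self.q2) - u2 / s2 ** 2
                D2 = np.bincount(self.g2, weights=mu,
                                 minlength=self.q2) + 1.0 / s2 ** 2
                S = np.zeros((self.q1, self.q2))
                np.add.at(S, (self.g1, self.g2), mu)
                SD = S / D1[:, None]
                M = np.diag(D2) - SD.T @ S
                try:
                    du2 = np.linalg.solve(M, g2v - SD.T @ g1v)
                except np.linalg.LinAlgError:
                    break
                du1 = (g1v - S @ du2) / D1
                gmax = max(np.max(np.abs(g1v)), np.max(np.abs(g2v)))
            step = 1.0
            for _ls in range(30):
                nu1 = u1 + step * du1
                nu2 = None if u2 is None else u2 + step * du2
                neta = xb + nu1[self.g1] + (0 if nu2 is None else nu2[self.g2])
                npll, nmu = _penalized_loglik(self.y, neta, nu1, nu2, s1, s2,
                                              self.logfact)
                if npll >= pll - 1e-12:
                    break
                step *= 0.5
            gain = npll - pll
            u1, u2, mu, pll = nu1, nu2, nmu, npll
            if gain < tol and gmax < 1e-6 * (1 + abs(pll)):
                break
        self.u1 = u1
        if u2 is not None:
            self.u2 = u2
        return mu, pll

    def laplace_loglik_beta(self, beta, s1, s2):
        """True Laplace log-likelihood at given beta (u at its mode)."""
        mu, pll = self.mode_u(beta, s1, s2)
        return self._laplace_from_mode(mu, pll, s1, s2)

    def beta_cov(self, s1, s2):
        """Conditional covariance of beta at the current fit (given sds)."""
        mu, _ = self.mode_u(self.beta, s1, s2)
        Hbb, D1, Hu1b, D2, Hu2b, S = self._blocks(mu, s1, s2)
        if self.u2 is None:
            A = Hbb - Hu1b.T @ (Hu1b / D1[:, None])
            return np.linalg.inv(A)
        B = np.hstack([Hu1b, S])
        A = np.zeros((self.p + self.q2, self.p + self.q2))
        A[:self.p, :self.p] = Hbb
        A[:self.p, self.p:] = Hu2b.T
        A[self.p:, :self.p] = Hu2b
        A[self.p:, self.p:] = np.diag(D2)
        A = A - B.T @ (B / D1[:, None])
        return np.linalg.inv(A)[:self.p, :self.p]


def fit_poisson_glmm(counts, covariates: pd.DataFrame, participant_ids,
                     species_codes, spec: ModelSpec | None = None,
                     tol: float = 1e-8, max_iter: int = 500) -> ModelResult:
    """Fit the crossed random-intercept Poisson GLMM by Laplace ML.

    ``counts`` is one observation per (informant, species) cell;
    ``covariates`` must be aligned row-wise (columns ``age``, ``sex``,
    ``migrant``); ``participant_ids`` and ``species_codes`` label the two
    crossed grouping factors.  With a single species the model reduces to
    one random intercept and the species variance is reported as not
    estimable (None).  Returns a :class:`ModelResult` whose
    ``random_variances`` holds the two variance components and whose
    ``llf`` is the Laplace log-likelihood.
    """
    spec = spec or ModelSpec(random="crossed")
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValidationError("counts must be non-negative integers")
    g1_codes, g1 = np.unique(np.asarray(participant_ids), return_inverse=True)
    g2_codes, g2 = np.unique(np.asarray(species_codes), return_inverse=True)
    if len(g1_codes) < 2:
        raise ValidationError("need at least two informants")
    X, names = build_design(covariates, spec.terms)
    if not (len(y) == len(X) == len(g1) == len(g2)):
        raise ValidationError("counts, covariates and labels differ in length")
    if y.sum() == 0:
        coef = pd.DataFrame(np.nan, index=names,
                            columns=["estimate", "se", "statistic", "p"])
        return ModelResult(spec, spec.terms, coef, math.nan,
                           len(y) - X.shape[1], -math.inf, math.nan,
                           converged=False, degenerate=True, n_obs=len(y))

    two_factor = len(g2_codes) >= 2
    fitter = _LaplaceFitter(y, X, g1, len(g1_codes),
                            g2 if two_factor else None,
                            len(g2_codes) if two_factor else 0)

    def objective(theta):
        s1 = math.exp(min(theta[0], 5.0))
        s2 = math.exp(min(theta[1], 5.0)) if two_factor else 1.0
        ll, _ = fitter.laplace_loglik(s1, s2)
        return -ll

    x0 = np.full(2 if two_factor else 1, math.log(0.3))
    opt = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8,
                                     "maxiter": 400 * len(x0)})
    theta = np.clip(opt.x, _BOUNDARY_LOG_SD, 5.0)
    s1 = math.exp(theta[0])
    s2 = math.exp(theta[1]) if two_factor else 1.0
    _, inner_ok = fitter.laplace_loglik(s1, s2)

    # stage 2: the joint-mode beta profiles the penalized objective, not
    # the Laplace one; polish (theta, beta) against the true Laplace
    # log-likelihood with the random effects at their conditional mode
    nth = len(x0)

    def objective2(z):
        s1 = math.exp(min(max(z[0], _BOUNDARY_LOG_SD), 5.0))
        s2 = (math.exp(min(max(z[1], _BOUNDARY_LOG_SD), 5.0))
              if two_factor else 1.0)
        return -fitter.laplace_loglik_beta(z[nth:], s1, s2)

    z0 = np.concatenate([theta, fitter.beta])
    opt2 = optimize.minimize(objective2, z0, method="Nelder-Mead",
                             options={"xatol": 1e-6, "fatol": 1e-8,
                                      "maxiter": 500 * len(z0)})
    if np.isfinite(opt2.fun) and opt2.fun <= -fitter.laplace_loglik_beta(
            fitter.beta, s1, s2) + 1e-9:
        theta = np.clip(opt2.x[:nth], _BOUNDARY_LOG_SD, 5.0)
        s1 = math.exp(theta[0])
        s2 = math.exp(theta[1]) if two_factor else 1.0
        fitter.beta = opt2.x[nth:].copy()
        opt = opt2
    llf = fitter.laplace_loglik_beta(fitter.beta, s1, s2)
    fitter.mode_u(fitter.beta, s1, s2)
    beta = fitter.beta
    cov = fitter.beta_cov(s1, s2)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    stat = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(stat))
    coef = pd.DataFrame({"estimate": beta, "se": se, "statistic": stat,
                         "p": p}, index=names)
    boundary = bool(theta[0] <= _BOUNDARY_LOG_SD + 1e-6 or
                    (two_factor and theta[1] <= _BOUNDARY_LOG_SD + 1e-6))
    variances = {"participant": s1 ** 2,
                 "species": s2 ** 2 if two_factor else None}
    mu = np.exp(np.clip(fitter._eta(beta, fitter.u1, fitter.u2),
                        -_ETA_MAX, _ETA_MAX))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
    deviance = float(2 * dev_terms.sum())
    return ModelResult(spec, spec.terms, coef, deviance,
                       len(y) - X.shape[1], float(llf), math.nan,
                       converged=bool(opt.success and inner_ok),
                       random_variances=variances, boundary=boundary,
                       n_obs=len(y))


def glmm_drop_term_test(full: ModelResult,
                        reduced: ModelResult) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square between nested Laplace ML fits."""
    if not set(reduced.terms) <= set(full.terms):
        raise ValidationError("reduced model is not nested in the full model")
    if reduced.n_obs != full.n_obs:
        raise ValidationError("models were fitted on different data")
    df = len(full.terms) - len(reduced.terms)
    if df == 0:
        return 0.0, 0, 1.0
    lr = 2.0 * (full.llf - reduced.llf)
    return float(lr), df, float(stats.chi2.sf(max(lr, 0.0), df))


def stepwise_backward_glmm(counts, covariates, participant_ids, species_codes,
                           spec: ModelSpec | None = None) -> ModelResult:
    """Backward simplification of the GLMM fixed effects by LRT.

    Same droppable-term logic as the GLM stepwise (marginality respected,
    drop the least significant term while p > alpha); the random structure
    is kept throughout.
    """
    from .count_models import _droppable  # shared marginality rule

    spec = spec or ModelSpec(random="crossed")
    current = fit_poisson_glmm(counts, covariates, participant_ids,
                               species_codes, spec)
    if current.degenerate:
        return current
    log: list[dict] = []
    while current.terms:
        candidates = []
        for t in _droppable(current.terms):
            rest = tuple(u for u in current.terms if u != t)
            rspec = ModelSpec(rest, spec.family, spec.random, spec.alpha,
                              spec.dispersion_threshold)
            reduced = fit_poisson_glmm(counts, covariates, participant_ids,
                                       species_codes, rspec)
            stat, df, p = glmm_drop_term_test(current, reduced)
            candidates.append((p, t, reduced, stat, df))
        p, t, reduced, stat, df = max(candidates, key=lambda c: c[0])
        if p <= spec.alpha:
            break
        log.append({"term": term_label(t), "statistic": stat, "df": df,
                    "p": p, "test": "LRT"})
        current = reduced
    current.dropped = log
    return current
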