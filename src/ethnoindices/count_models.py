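"""Poisson / quasi-Poisson count models of use-type knowledge.

The response is a count of distinct use-types (per species, or per
use-category within a species-by-informant cell); covariates are the
informant's age in years (continuous), sex, and a pooled migrant indicator
(temporary + permanent migrants vs residents).  Maximal models contain the
three main effects and all two-way interactions; they are simplified by a
stepwise-backward procedure that drops the least significant droppable
term while its p-value exceeds alpha, respecting marginality (a main
effect is never dropped while an interaction containing it remains).

Poisson models are tested with likelihood-ratio chi-square tests.  When
the residual deviance per residual degree of freedom of the maximal model
exceeds a threshold (default 1.5), the model is treated as overdispersed
and re-fitted as a quasi-Poisson model: identical coefficients, standard
errors inflated by the square root of the dispersion, and F-tests on
scaled deviance for term deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_data import Dataset, ValidationError
from .group_comparison import significance_stars

__all__ = [
    "Term", "MAXIMAL_TERMS", "ModelSpec", "ModelResult",
    "build_design", "covariates_frame",
    "fit_poisson_glm", "dispersion_check", "drop_term_test",
    "stepwise_backward",
]

#: A model term: tuple of covariate names, canonically ordered.
Term = tuple[str, ...]

_VAR_ORDER = ("age", "sex", "migrant")
_COLUMN_LABEL = {"age": "age", "sex": "sex(men)", "migrant": "migration(yes)"}

#: Main effects plus all two-way interactions — the maximal model.
MAXIMAL_TERMS: tuple[Term, ...] = (
    ("age",), ("sex",), ("migrant",),
    ("age", "sex"), ("age", "migrant"), ("sex", "migrant"),
)


def canonical_term(term: Sequence[str]) -> Term:
    vs = sorted(set(term), key=_VAR_ORDER.index)
    if not vs:
        raise ValidationError("empty model term")
    return tuple(vs)


def term_label(term: Term) -> str:
    return ":".join(_COLUMN_LABEL[v] for v in term)


@dataclass
class ModelSpec:
    """Which fixed terms, error family and random structure to fit."""

    terms: tuple[Term, ...] = MAXIMAL_TERMS
    family: str = "poisson"           # poisson | quasipoisson
    random: str = "none"              # none | crossed
    alpha: float = 0.05
    dispersion_threshold: float = 1.5

    def __post_init__(self):
        # canonical term order: the fit is invariant to how the caller
        # listed the covariates
        self.terms = tuple(sorted(
            (canonical_term(t) for t in self.terms),
            key=lambda t: (len(t), tuple(_VAR_ORDER.index(v) for v in t))))
        for t in self.terms:
            for v in t:
                if v not in _VAR_ORDER:
                    raise ValidationError(f"unknown covariate {v!r}")
        # marginality: every interaction's parents must be present
        for t in self.terms:
            if len(t) > 1:
                for v in t:
                    if (v,) not in self.terms:
                        raise ValidationError(
                            f"interaction {term_label(t)} without "
                            f"main effect {v}")


def covariates_frame(dataset: Dataset) -> pd.DataFrame:
    """Per-informant covariates: age (years), sex (men=1), migrant (yes=1)."""
    rows = [{"participant_id": p.id, "age": p.age_years,
             "sex": 1.0 if p.sex == "male" else 0.0,
             "migrant": 1.0 if p.is_migrant else 0.0}
            for p in dataset.participants.values()]
    return pd.DataFrame(rows).set_index("participant_id")


def build_design(covariates: pd.DataFrame,
                 terms: Sequence[Term]) -> tuple[np.ndarray, list[str]]:
    """Design matrix (intercept first) for the given terms."""
    cols = [np.ones(len(covariates))]
    names = ["Intercept"]
    for t in terms:
        col = np.ones(len(covariates))
        for v in t:
            col = col * covariates[v].to_numpy(dtype=float)
        cols.append(col)
        names.append(term_label(t))
    return np.column_stack(cols), names


@dataclass
class ModelResult:
    """A fitted count model: coefficients, fit statistics, drop log."""

    spec: ModelSpec
    terms: tuple[Term, ...]
    coef: pd.DataFrame               # estimate, se, statistic, p per row
    deviance: float
    df_resid: int
    llf: float
    dispersion: float
    converged: bool = True
    degenerate: bool = False
    dropped: list[dict] = field(default_factory=list)
    random_variances: dict[str, float] | None = None
    boundary: bool = False
    n_obs: int = 0

    @property
    def family(self) -> str:
        return self.spec.family

    def term_table(self, all_terms: Sequence[Term] = MAXIMAL_TERMS,
                   alpha: float = 0.05) -> pd.DataFrame:
        """Report-shaped table: retained estimates, ``ns`` for dropped terms."""
        rows = [{"term": "Intercept",
                 "estimate": f"{self.coef.loc['Intercept', 'estimate']:.3f}"
                 if not self.degenerate else "ns"}]
        for t in all_terms:
            lab = term_label(t)
            if t in self.terms and not self.degenerate:
                est = self.coef.loc[lab, "estimate"]
                star = significance_stars(self.coef.loc[lab, "p"], alpha)
                rows.append({"term": lab,
                             "estimate": f"{est:.3f}"
                             + (star if star != "ns" else "")})
            else:
                rows.append({"term": lab, "estimate": "ns"})
        return pd.DataFrame(rows)


def _fit(y: np.ndarray, X: np.ndarray) -> sm.GLM:
    model = sm.GLM(y, X, family=sm.families.Poisson())
    return model.fit(maxiter=100, tol=1e-10)


def fit_poisson_glm(counts: Sequence[int], covariates: pd.DataFrame,
                    spec: ModelSpec | None = None) -> ModelResult:
    """Maximum-likelihood Poisson (or quasi-Poisson) GLM, log link.

    Coefficients are on the log scale.  ``quasipoisson`` uses the same
    point estimates with standard errors scaled by sqrt(dispersion) and
    t statistics on the residual degrees of freedom.  An all-zero response
    has no finite intercept and is returned flagged ``degenerate``.
    """
    spec = spec or ModelSpec()
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValidationError("counts must be non-negative integers")
    X, names = build_design(covariates, spec.terms)
    if len(y) != len(X):
        raise ValidationError("counts and covariates differ in length")
    if y.sum() == 0:
        coef = pd.DataFrame(np.nan, index=names,
                            columns=["estimate", "se", "statistic", "p"])
        return ModelResult(spec, spec.terms, coef, 0.0,
                           len(y) - X.shape[1], -math.inf, math.nan,
                           converged=False, degenerate=True, n_obs=len(y))
    res = _fit(y, X)
    df_resid = int(res.df_resid)
    if df_resid <= 0:
        raise ValidationError("saturated model: zero residual df")
    dispersion = float(res.deviance / df_resid)
    est = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if spec.family == "quasipoisson":
        se = se * math.sqrt(max(dispersion, np.finfo(float).tiny))
        stat = est / se
        p = 2 * stats.t.sf(np.abs(stat), df_resid)
    else:
        stat = est / se
        p = 2 * stats.norm.sf(np.abs(stat))
    coef = pd.DataFrame({"estimate": est, "se": se, "statistic": stat,
                         "p": p}, index=names)
    return ModelResult(spec, spec.terms, coef, float(res.deviance), df_resid,
                       float(res.llf), dispersion,
                       converged=bool(res.converged), n_obs=len(y))


def dispersion_check(result: ModelResult,
                     threshold: float | None = None) -> tuple[float, bool]:
    """Residual deviance / residual df, and whether to refit as quasi."""
    if result.df_resid <= 0:
        raise ValidationError("zero residual df: dispersion undefined")
    threshold = (result.spec.dispersion_threshold
                 if threshold is None else threshold)
    return result.dispersion, result.dispersion > threshold


def drop_term_test(full: ModelResult,
                   reduced: ModelResult) -> tuple[float, int, float]:
    """Test for the terms dropped between two nested GLM fits.

    Poisson: likelihood-ratio chi-square (the deviance difference) on the
    parameter-count difference.  Quasi-Poisson: F on scaled deviance,
    denominator df = residual df of the fuller model, using the fuller
    model's deviance dispersion.  Returns (statistic, df, p).
    """
    if not set(reduced.terms) < set(full.terms) and reduced.terms != full.terms:
        raise ValidationError("reduced model is not nested in the full model")
    if reduced.n_obs != full.n_obs:
        raise ValidationError("models were fitted on different data")
    df = reduced.df_resid - full.df_resid
    if df == 0:
        return 0.0, 0, 1.0
    delta = reduced.deviance - full.deviance
    if full.family == "quasipoisson":
        f = (delta / df) / full.dispersion
        return float(f), df, float(stats.f.sf(max(f, 0.0), df, full.df_resid))
    return float(delta), df, float(stats.chi2.sf(max(delta, 0.0), df))


def _droppable(terms: Sequence[Term]) -> list[Term]:
    """Terms not contained in any higher-order term (marginality)."""
    out = []
    for t in terms:
        if not any(set(t) < set(u) for u in terms):
            out.append(t)
    return sorted(out, key=lambda t: (len(t), tuple(_VAR_ORDER.index(v)
                                                    for v in t)))


def stepwise_backward(counts: Sequence[int], covariates: pd.DataFrame,
                      spec: ModelSpec | None = None) -> ModelResult:
    """Backward simplification of a maximal GLM to the minimal adequate model.

    Fits the maximal model, decides the family by the dispersion check
    when ``spec.family`` would be plain Poisson, then repeatedly deletes
    the droppable term with the largest deletion-test p-value while that
    p-value exceeds ``spec.alpha``.  The returned result carries the drop
    log (term, statistic, df, p) of every deleted term.
    """
    spec = spec or ModelSpec()
    current = fit_poisson_glm(counts, covariates, spec)
    if current.degenerate:
        return current
    if spec.family == "poisson":
        _, over = dispersion_check(current)
        if over:
            spec = ModelSpec(spec.terms, "quasipoisson", spec.random,
                             spec.alpha, spec.dispersion_threshold)
            current = fit_poisson_glm(counts, covariates, spec)
    log: list[dict] = []
    while current.terms:
        candidates = []
        for t in _droppable(current.terms):
            rest = tuple(u for u in current.terms if u != t)
            rspec = ModelSpec(rest, spec.family, spec.random, spec.alpha,
                              spec.dispersion_threshold)
            reduced = fit_poisson_glm(counts, covariates, rspec)
            stat, df, p = drop_term_test(current, reduced)
            candidates.append((p, t, reduced, stat, df))
        p, t, reduced, stat, df = max(candidates, key=lambda c: c[0])
        if p <= spec.alpha:
            break
        log.append({"term": term_label(t), "statistic": stat, "df": df,
                    "p": p, "test": "F" if spec.family == "quasipoisson"
                    else "LRT"})
        current = reduced
    current.dropped = log
    return current
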