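"""Statistics for intracultural variation in the indices.

The indices are compared across actor groups (sex, age class, migration
group) with one-way ANOVA on arcsine-square-root transformed responses,
Tukey(-Kramer) post-hoc contrasts, two-sample proportion tests per
use-category, and Spearman rank concordance of the two indices.

Responses for the ANOVA are per-informant quantities in [0, 1]: the
freelist salience directly, and for CI the number of categories an
informant mentioned divided by the number of categories (9), so that both
land in the domain of the arcsine-square-root variance-stabilising
transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_chisquare

from .core_data import (Dataset, USE_CATEGORIES, ValidationError,
                        factor_levels)
from .cultural_importance import _asked, _mention_matrix
from .salience import _saliences

__all__ = [
    "arcsine_sqrt", "one_way_anova", "tukey_hsd",
    "category_proportion_test", "spearman", "significance_stars",
    "AnovaResult", "ProportionTestResult",
    "index_anova_by_species", "category_tests",
]


def arcsine_sqrt(value):
    """Arcsine-square-root transform: asin(sqrt(v)), radians in [0, pi/2]."""
    v = np.asarray(value, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValidationError("arcsine_sqrt requires values in [0, 1]")
    out = np.arcsin(np.sqrt(v))
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Conventional stars: *** <0.001, ** <0.01, * <alpha, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


@dataclass
class AnovaResult:
    factor: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    group_means: dict[str, float]
    degenerate: bool = False
    tukey: pd.DataFrame | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _split_groups(responses: Sequence[float], groups: Sequence[str]):
    responses = np.asarray(responses, dtype=float)
    groups = np.asarray(groups)
    if len(responses) != len(groups):
        raise ValidationError("responses and groups differ in length")
    levels = list(dict.fromkeys(groups))  # first-appearance order
    split = [responses[groups == lv] for lv in levels]
    for lv, vals in zip(levels, split):
        if len(vals) == 0:
            raise ValidationError(f"group level {lv!r} has no observations")
    return levels, split


def one_way_anova(responses: Sequence[float], groups: Sequence[str],
                  factor: str = "group") -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Between/within sums-of-squares decomposition; F = MSB/MSW on
    (k - 1, n - k) degrees of freedom.  A dataset with zero between- and
    zero within-group variance has an undefined F and is flagged
    ``degenerate`` (F reported as 0, p as 1).
    """
    levels, split = _split_groups(responses, groups)
    k = len(levels)
    n = sum(len(g) for g in split)
    if k < 2:
        raise ValidationError("ANOVA needs at least two group levels")
    if n <= k:
        raise ValidationError("ANOVA needs more observations than levels")
    grand = np.concatenate(split).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in split)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in split)
    df_num, df_den = k - 1, n - k
    means = {lv: float(g.mean()) for lv, g in zip(levels, split)}
    if ssw == 0 and ssb == 0:
        return AnovaResult(factor, 0.0, df_num, df_den, 1.0, means,
                           degenerate=True)
    if ssw == 0:
        return AnovaResult(factor, math.inf, df_num, df_den, 0.0, means)
    f = (ssb / df_num) / (ssw / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return AnovaResult(factor, float(f), df_num, df_den, p, means)


def tukey_hsd(responses: Sequence[float], groups: Sequence[str]) -> pd.DataFrame:
    """All-pairs Tukey honestly-significant-difference comparisons.

    Uses the Tukey-Kramer form (studentized-range distribution with the
    harmonic pair adjustment), valid for unbalanced groups.  Returns one
    row per level pair: ``group1``, ``group2``, ``difference`` (mean1 -
    mean2) and ``p_adj``.
    """
    levels, split = _split_groups(responses, groups)
    if len(levels) < 2:
        raise ValidationError("Tukey HSD needs at least two group levels")
    res = stats.tukey_hsd(*split)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append({
                "group1": levels[i], "group2": levels[j],
                "difference": float(split[i].mean() - split[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)


@dataclass
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    statistic: float
    df: int
    p_value: float
    method: str
    species: str | None = None
    use_category: str | None = None
    groups: tuple[str, str] | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def category_proportion_test(x1: int, n1: int, x2: int, n2: int,
                             exact: bool = False) -> ProportionTestResult:
    """Two-sample test of equal mention probability for a use-category.

    Default: 1-df pooled chi-square test on the 2x2 table, no continuity
    correction (the statistic equals n * (p1 - p2)^2 / (pbar * (1 - pbar))
    weighted by group sizes).  ``exact=True`` instead performs a two-sided
    exact binomial test of group 1's count against group 2's observed
    proportion.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValidationError("group size must be >= 1")
        if not 0 <= x <= n:
            raise ValidationError(f"count {x} outside [0, {n}]")
    if exact:
        p2 = x2 / n2
        if p2 in (0.0, 1.0):
            # degenerate reference proportion: exact test against the
            # point mass; p-value is 1 iff the observation matches it
            p = 1.0 if x1 == p2 * n1 else 0.0
        else:
            p = float(stats.binomtest(x1, n1, p2).pvalue)
        return ProportionTestResult(x1, n1, x2, n2, math.nan, 1, p,
                                    "exact_binomial")
    if x1 / n1 == x2 / n2:
        # pooled chi-square is identically 0 (also when both are 0 or n)
        return ProportionTestResult(x1, n1, x2, n2, 0.0, 1, 1.0,
                                    "chi_square")
    chi2, p, _ = proportions_chisquare([x1, x2], [n1, n2])
    return ProportionTestResult(x1, n1, x2, n2, float(chi2), 1, float(p),
                                "chi_square")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; (rho, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValidationError("inputs differ in length")
    if len(x) < 3:
        raise ValidationError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("zero variance in ranks")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Dataset-level drivers
# ---------------------------------------------------------------------------

def _responses(dataset: Dataset, index: str, species_code: str,
               participants: list[str]) -> np.ndarray:
    """Per-informant [0,1] response for one species."""
    if index == "salience":
        return _saliences(dataset, species_code, participants)
    if index == "ci":
        mat = _mention_matrix(dataset, species_code).loc[participants]
        return mat.sum(axis=1).to_numpy() / len(USE_CATEGORIES)
    raise ValidationError(f"unknown index {index!r}; expected salience or ci")


def index_anova_by_species(dataset: Dataset, index: str, grouping: str,
                           assume_all_asked: bool = False,
                           transform: bool = True) -> list[AnovaResult]:
    """ANOVA + Tukey of an index across an actor-group factor, per species.

    ``index`` is ``salience`` or ``ci``; responses are arcsine-square-root
    transformed unless ``transform=False``.  Species whose responses are
    constant everywhere are returned flagged degenerate rather than
    raising, so one flat species does not abort a 14-species run.
    """
    factor_levels(grouping)
    results = []
    for code in dataset.species_codes:
        if index == "ci":
            participants = _asked(dataset, code, assume_all_asked)
        else:
            participants = dataset.participant_ids
        groups = [getattr(dataset.participants[pid], grouping)
                  for pid in participants]
        y = _responses(dataset, index, code, participants)
        if transform:
            y = arcsine_sqrt(y)
        present = [lv for lv in factor_levels(grouping) if lv in groups]
        if len(present) < 2 or len(y) <= len(present):
            res = AnovaResult(grouping, 0.0, max(len(present) - 1, 0),
                              max(len(y) - len(present), 0), 1.0, {},
                              degenerate=True)
        else:
            res = one_way_anova(y, groups, factor=grouping)
            if not res.degenerate and np.ptp(y) > 0:
                res.tukey = tukey_hsd(y, groups)
        res.species = code  # type: ignore[attr-defined]
        results.append(res)
    return results


def category_tests(dataset: Dataset, species_code: str, grouping: str,
                   level1: str, level2: str, exact: bool = False,
                   assume_all_asked: bool = False) -> list[ProportionTestResult]:
    """Per-category proportion tests between two actor-group levels.

    Follow-up to a significant index ANOVA: for each use-category, tests
    whether informants in ``level1`` and ``level2`` mention the category
    for this species with equal probability.
    """
    members = dataset.group_members(grouping)
    asked = set(_asked(dataset, species_code, assume_all_asked))
    g1 = [p for p in members[level1] if p in asked]
    g2 = [p for p in members[level2] if p in asked]
    if not g1 or not g2:
        raise ValidationError(
            f"no informants asked about {species_code} in one of the groups")
    mat = _mention_matrix(dataset, species_code)
    out = []
    for cat in USE_CATEGORIES:
        res = category_proportion_test(
            int(mat.loc[g1, cat].sum()), len(g1),
            int(mat.loc[g2, cat].sum()), len(g2), exact=exact)
        res.species = species_code
        res.use_category = cat
        res.groups = (level1, level2)
        out.append(res)
    return out
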