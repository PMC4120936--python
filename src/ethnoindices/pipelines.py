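"""End-to-end drivers: index tables, group comparisons, and model tables.

These functions tie the modules together the way a full survey analysis
runs: compute both index tables and their rank concordance, test each
index across actor groups per species, fit the per-species stepwise
GLM/quasi-GLM on total use-type counts, and the per-category stepwise
GLMM with crossed informant and species random intercepts.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core_data import Dataset, USE_CATEGORIES
from .count_models import (MAXIMAL_TERMS, ModelResult, ModelSpec,
                           covariates_frame, stepwise_backward, term_label)
from .cultural_importance import ci_table, use_type_counts
from .datasets import CATEGORY_ABBREV
from .glmm import stepwise_backward_glmm
from .group_comparison import index_anova_by_species, spearman
from .salience import salience_table

log = logging.getLogger("ethnoindices")

__all__ = ["indices_summary", "comparison_table", "use_counts_long",
           "species_use_models", "category_use_models", "model_table"]


def indices_summary(dataset: Dataset, grouping: str | None = None,
                    assume_all_asked: bool = False) -> dict:
    """Both index tables plus the Spearman concordance of their totals."""
    sal = salience_table(dataset, grouping)
    ci = ci_table(dataset, grouping, assume_all_asked=assume_all_asked)
    merged = sal.totals.merge(ci.totals, on="species",
                              suffixes=("_sal", "_ci"))
    try:
        rho, p = spearman(merged["composite_s"], merged["ci"])
    except Exception:  # fewer than 3 species, or a constant index
        rho, p = float("nan"), float("nan")
    return {"salience": sal, "ci": ci, "spearman_rho": rho, "spearman_p": p}


def comparison_table(dataset: Dataset, index: str, grouping: str,
                     assume_all_asked: bool = False) -> pd.DataFrame:
    """Tidy per-species ANOVA results for one index and factor."""
    rows = []
    for res in index_anova_by_species(dataset, index, grouping,
                                      assume_all_asked=assume_all_asked):
        rows.append({
            "species": res.species, "index": index, "factor": grouping,
            "F": res.f_statistic, "df_num": res.df_num, "df_den": res.df_den,
            "p": res.p_value,
            "significance": "" if res.degenerate else res.stars,
            "degenerate": res.degenerate,
        })
    return pd.DataFrame(rows)


def use_counts_long(dataset: Dataset) -> pd.DataFrame:
    """Long frame of use-type counts per informant x species x category."""
    frames = []
    for code in dataset.species_codes:
        counts = use_type_counts(dataset, code)
        longf = counts.drop(columns="total").reset_index().melt(
            id_vars="participant_id", var_name="use_category",
            value_name="count")
        longf["species"] = code
        frames.append(longf)
    return pd.concat(frames, ignore_index=True)


def species_use_models(dataset: Dataset,
                       spec: ModelSpec | None = None
                       ) -> dict[str, ModelResult]:
    """Stepwise GLM/quasi-GLM per species on total use-type counts.

    Each species is fitted independently; a species whose fit fails or is
    degenerate is logged and reported as such rather than aborting the run.
    """
    cov = covariates_frame(dataset)
    results: dict[str, ModelResult] = {}
    for code in dataset.species_codes:
        y = use_type_counts(dataset, code)["total"].loc[cov.index]
        try:
            res = stepwise_backward(y.to_numpy(), cov, spec)
        except Exception as err:  # isolation: one species must not kill 13
            log.warning("model for species %s failed: %s", code, err)
            continue
        for entry in res.dropped:
            log.info("%s: dropped %s (%s=%.3f, df=%d, p=%.3f)", code,
                     entry["term"], entry["test"], entry["statistic"],
                     entry["df"], entry["p"])
        results[code] = res
    return results


def category_use_models(dataset: Dataset,
                        spec: ModelSpec | None = None
                        ) -> dict[str, ModelResult]:
    """Stepwise crossed-random-intercept GLMM per use-category."""
    cov = covariates_frame(dataset)
    longf = use_counts_long(dataset)
    results: dict[str, ModelResult] = {}
    for cat in USE_CATEGORIES:
        sub = longf[longf["use_category"] == cat]
        try:
            res = stepwise_backward_glmm(
                sub["count"].to_numpy(),
                cov.loc[sub["participant_id"]].reset_index(drop=True),
                sub["participant_id"].to_numpy(), sub["species"].to_numpy(),
                spec)
        except Exception as err:
            log.warning("model for category %s failed: %s", cat, err)
            continue
        for entry in res.dropped:
            log.info("%s: dropped %s (LRT=%.3f, df=%d, p=%.3f)", cat,
                     entry["term"], entry["statistic"], entry["df"],
                     entry["p"])
        results[cat] = res
    return results


def model_table(results: dict[str, ModelResult],
                abbreviate_categories: bool = False) -> pd.DataFrame:
    """Wide coefficient table: rows = fixed terms, columns = responses.

    Retained terms show the log-scale estimate with significance stars;
    dropped terms show ``ns``, mirroring how minimal adequate models are
    reported.
    """
    cols = {}
    for key, res in results.items():
        label = CATEGORY_ABBREV.get(key, key) if abbreviate_categories else key
        tab = res.term_table(MAXIMAL_TERMS)
        cols[label] = tab.set_index("term")["estimate"]
    out = pd.DataFrame(cols)
    out.index.name = "fixed_effect"
    return out.reset_index()
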