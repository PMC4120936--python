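"""Cultural Importance from use-reports.

Use-reports are grouped per species and informant into the nine
use-categories (mentioned: 1, not mentioned: 0); Cultural Importance (CI)
of a species is the sum over categories of the proportion of informants
mentioning that category.  With nine categories CI ranges from 0 (no
category mentioned by anyone) to 9 (every category mentioned by every
informant).  The number of *distinct* use-types per category — e.g. two
ailments treated with the same plant count as two use-types in
``medicine`` — is the response variable of the count models.

The per-species denominator is the set of informants interviewed about
that species.  Interview coverage is inferred from the reports (informants
with at least one report for the species) unless ``assume_all_asked`` puts
the whole roster in every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import (Dataset, USE_CATEGORIES, ValidationError,
                        factor_levels)

__all__ = ["category_profile", "cultural_importance", "ci_table",
           "use_type_counts", "CITable"]


def category_profile(dataset: Dataset, participant_id: str,
                     species_code: str) -> pd.DataFrame:
    """Distinct use-type counts and 0/1 mentions per category for one pair.

    Returns a frame indexed by the nine use-categories with columns
    ``n_use_types`` (count of distinct normalized use-type labels) and
    ``mentioned`` (1 iff the count is positive).
    """
    types: dict[str, set[str]] = {cat: set() for cat in USE_CATEGORIES}
    for rep in dataset.use_reports:
        if rep.participant_id == participant_id and \
                rep.species_code == species_code:
            types[rep.use_category].add(rep.use_type)
    counts = [len(types[cat]) for cat in USE_CATEGORIES]
    return pd.DataFrame(
        {"n_use_types": counts, "mentioned": [int(c > 0) for c in counts]},
        index=pd.Index(USE_CATEGORIES, name="use_category"))


def _mention_matrix(dataset: Dataset, species_code: str) -> pd.DataFrame:
    """0/1 mention matrix (participants x categories) for one species."""
    pids = dataset.participant_ids
    mat = pd.DataFrame(0, index=pd.Index(pids, name="participant_id"),
                       columns=list(USE_CATEGORIES))
    for rep in dataset.use_reports:
        if rep.species_code == species_code:
            mat.loc[rep.participant_id, rep.use_category] = 1
    return mat


def _asked(dataset: Dataset, species_code: str,
           assume_all_asked: bool) -> list[str]:
    if assume_all_asked:
        return dataset.participant_ids
    with_record = {rep.participant_id for rep in dataset.use_reports
                   if rep.species_code == species_code}
    return [pid for pid in dataset.participant_ids if pid in with_record]


def cultural_importance(dataset: Dataset, species_code: str,
                        participants: Sequence[str] | None = None,
                        assume_all_asked: bool = False) -> float:
    """CI of a species: sum over categories of mention proportions.

    ``participants`` defaults to the informants interviewed about the
    species (see module docstring).  Equal, before rounding, to the number
    of (participant, category) citation pairs divided by the number of
    participants.
    """
    if species_code not in dataset.species:
        raise ValidationError(f"unregistered species code {species_code!r}")
    if participants is None:
        participants = _asked(dataset, species_code, assume_all_asked)
    if len(participants) == 0:
        raise ValidationError("empty participant subset")
    mat = _mention_matrix(dataset, species_code).loc[list(participants)]
    return float(mat.to_numpy().sum() / len(participants))


@dataclass
class CITable:
    """Per-species CI, total and per actor group."""

    grouping: str | None
    totals: pd.DataFrame
    by_group: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.by_group is None:
            return self.totals.copy()
        return self.totals.merge(self.by_group, on="species")


def ci_table(dataset: Dataset, grouping: str | None = None,
             assume_all_asked: bool = False) -> CITable:
    """CI per species with citation bookkeeping, optionally stratified.

    ``totals`` columns: ``n_participants`` (informants asked),
    ``n_citations`` (participant-by-category mention pairs),
    ``n_categories`` (distinct categories cited) and ``ci``; the identity
    ``ci = n_citations / n_participants`` holds exactly.  Per-group columns
    give the mean ± sd of the per-informant number of categories mentioned,
    over the group's members among the informants asked.
    """
    rows, grows = [], []
    levels = factor_levels(grouping) if grouping is not None else ()
    members = dataset.group_members(grouping) if grouping is not None else {}
    for code in dataset.species_codes:
        asked = _asked(dataset, code, assume_all_asked)
        mat = _mention_matrix(dataset, code)
        sub = mat.loc[asked]
        n_cit = int(sub.to_numpy().sum())
        rows.append({
            "species": code,
            "n_participants": len(asked),
            "n_citations": n_cit,
            "n_categories": int((sub.sum(axis=0) > 0).sum()),
            "ci": n_cit / len(asked) if asked else np.nan,
        })
        if grouping is not None:
            per_part = sub.sum(axis=1)  # categories mentioned per informant
            row: dict[str, float | str] = {"species": code}
            for lv in levels:
                vals = per_part.loc[[p for p in members[lv] if p in asked]]
                row[f"{lv}_mean"] = float(vals.mean()) if len(vals) else np.nan
                row[f"{lv}_sd"] = (float(vals.std(ddof=1))
                                   if len(vals) > 1 else np.nan)
            grows.append(row)
    totals = pd.DataFrame(rows)
    if grouping is None:
        return CITable(None, totals)
    return CITable(grouping, totals, pd.DataFrame(grows))


def use_type_counts(dataset: Dataset, species_code: str) -> pd.DataFrame:
    """Distinct use-type counts per informant for one species.

    One row per informant on the roster; columns are the nine categories
    plus ``total`` (their sum).  This is the response variable of the
    per-species count models.
    """
    if species_code not in dataset.species:
        raise ValidationError(f"unregistered species code {species_code!r}")
    pids = dataset.participant_ids
    types: dict[tuple[str, str], set[str]] = {}
    for rep in dataset.use_reports:
        if rep.species_code == species_code:
            types.setdefault((rep.participant_id, rep.use_category),
                             set()).add(rep.use_type)
    out = pd.DataFrame(0, index=pd.Index(pids, name="participant_id"),
                       columns=list(USE_CATEGORIES))
    for (pid, cat), labels in types.items():
        out.loc[pid, cat] = len(labels)
    out["total"] = out.sum(axis=1)
    return out
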