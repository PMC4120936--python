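"""Freelist salience: per-informant salience and Composite Salience.

An informant who lists a species at 1-based rank ``r`` in a freelist of
length ``L`` assigns it salience ``(L - r + 1) / L`` — 1 for the first
mention, ``1/L`` for the last, 0 if the species is absent.  Composite
Salience of a species is the mean of these per-informant saliences over a
set of informants (informants without any freelist count as 0, keeping the
roster size as the denominator).  The index lives in [0, 1]: 0 when nobody
lists the species, 1 when everybody lists it first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import Dataset, Freelist, ValidationError, factor_levels

__all__ = ["participant_salience", "composite_salience", "salience_table",
           "SalienceTable"]


def participant_salience(freelist: Freelist | None, species_code: str) -> float:
    """Salience of ``species_code`` for one informant's freelist.

    ``(L - r + 1) / L`` for a mention at rank ``r`` in a list of length
    ``L``; 0.0 if the species is not listed or the informant gave no list.
    """
    if freelist is None:
        return 0.0
    r = freelist.rank(species_code)
    if r is None:
        return 0.0
    L = len(freelist)
    return (L - r + 1) / L


def _saliences(dataset: Dataset, species_code: str,
               participants: Sequence[str]) -> np.ndarray:
    if species_code not in dataset.species:
        raise ValidationError(f"unregistered species code {species_code!r}")
    return np.array([
        participant_salience(dataset.freelists.get(pid), species_code)
        for pid in participants
    ])


def composite_salience(dataset: Dataset, species_code: str,
                       participants: Sequence[str] | None = None) -> float:
    """Mean per-informant salience of a species over a participant subset.

    ``participants`` defaults to the full roster; for subgroups the
    denominator is the subgroup size.
    """
    if participants is None:
        participants = dataset.participant_ids
    if len(participants) == 0:
        raise ValidationError("empty participant subset")
    return float(_saliences(dataset, species_code, participants).mean())


@dataclass
class SalienceTable:
    """Per-species Composite Salience, total and per actor group.

    ``totals`` has one row per species with ``n_participants``,
    ``n_citations`` and ``composite_s``; ``by_group`` (absent when no
    grouping was requested) adds per-level mean ± sd columns.
    """

    grouping: str | None
    totals: pd.DataFrame
    by_group: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """Single wide table (species, totals, then <level>_mean/_sd)."""
        if self.by_group is None:
            return self.totals.copy()
        return self.totals.merge(self.by_group, on="species")


def salience_table(dataset: Dataset,
                   grouping: str | None = None) -> SalienceTable:
    """Composite Salience per species, optionally stratified by a factor.

    ``grouping`` is one of ``sex``, ``age_class``, ``migration_group`` or
    None.  Per-group columns report the mean and standard deviation of the
    per-informant saliences within each group level (denominator = group
    size).
    """
    roster = dataset.participant_ids
    rows = []
    per_species: dict[str, np.ndarray] = {}
    for code in dataset.species_codes:
        s = _saliences(dataset, code, roster)
        per_species[code] = s
        rows.append({
            "species": code,
            "n_participants": len(roster),
            "n_citations": int((s > 0).sum()),
            "composite_s": float(s.mean()) if len(roster) else np.nan,
        })
    totals = pd.DataFrame(rows)

    if grouping is None:
        return SalienceTable(None, totals)

    levels = factor_levels(grouping)
    members = dataset.group_members(grouping)
    index_of = {pid: i for i, pid in enumerate(roster)}
    grows = []
    for code in dataset.species_codes:
        s = per_species[code]
        row: dict[str, float | str] = {"species": code}
        for lv in levels:
            idx = [index_of[pid] for pid in members[lv]]
            vals = s[idx]
            row[f"{lv}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{lv}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        grows.append(row)
    return SalienceTable(grouping, totals, pd.DataFrame(grows))
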