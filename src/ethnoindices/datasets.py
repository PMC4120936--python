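"""Reference data from the Bolivian Andes woody-species survey.

The package was designed around a freelisting + semi-structured-interview
study of 14 woody species (trees, shrubs, subshrubs) conducted with 40
Quechua farmers in the Cochabamba highlands.  This module ships the study's
species registry and its published per-species index totals, which serve as
worked-example inputs and as a concordance benchmark for the two indices.
"""

from __future__ import annotations

import pandas as pd

from .core_data import SpeciesRecord

__all__ = [
    "species_registry",
    "published_index_totals",
    "CATEGORY_ABBREV",
]

#: Short labels used in model-output tables for the nine use-categories.
CATEGORY_ABBREV = {
    "construction": "con",
    "environmental": "env",
    "field": "fie",
    "fodder": "fod",
    "food": "food",
    "fuel": "fuel",
    "medicine": "med",
    "other": "oth",
    "tools": "tool",
}

_SPECIES = [
    # code, scientific name, family, life form, origin, vernacular
    ("BD", "Baccharis dracunculifolia", "Asteraceae", "shrub", "native",
     ("t'ola",)),
    ("BeC", "Berberis commutata", "Berberidaceae", "shrub", "native",
     ("churisik'e",)),
    ("BuC", "Buddleja coriacea", "Buddlejaceae", "tree", "native_cultivated",
     ("kishuara",)),
    ("CB", "Clinopodium bolivianum", "Lamiaceae", "subshrub", "native",
     ("chini muña", "muña")),
    ("EG", "Eucalyptus globulus", "Myrtaceae", "tree", "exotic",
     ("eucalipto", "kalisto")),
    ("GP", "Gynoxys psilophylla", "Asteraceae", "tree", "native",
     ("k'apa towi", "loma towi", "k'apa k'apa")),
    ("KS", "Kaunia saltensis", "Asteraceae", "shrub", "native",
     ("jaya towi",)),
    ("LG", "Lepechinia graveolens", "Lamiaceae", "shrub", "native",
     ("raqacho", "raga raga")),
    ("MO", "Minthostachys ovata", "Lamiaceae", "subshrub", "native",
     ("k'oa muña", "muña")),
    ("PS", "Polylepis subtusalbida", "Rosaceae", "tree", "native",
     ("kewiña", "queñua")),
    ("PL", "Prosopis laevigata", "Leguminosae", "tree", "native",
     ("thaqo", "algarrobo")),
    ("SP", "Sambucus peruviana", "Caprifoliaceae", "tree", "exotic",
     ("sauco",)),
    ("SM", "Schinus molle", "Anacardiaceae", "tree", "native",
     ("molle",)),
    ("SA", "Senna aymara", "Leguminosae", "shrub", "native",
     ("motocho", "motochila")),
]

# Published per-species totals: composite salience (over n = 40 informants)
# and cultural importance with its per-species number of informants asked,
# participant-by-category citation pairs, and distinct categories cited.
_TOTALS = {
    #        compS  ci_part ci_cit ci_cat   CI
    "BD":  (0.53, 40, 193, 8, 4.83),
    "BeC": (0.00, 40, 122, 9, 3.05),
    "BuC": (0.03, 40, 68, 6, 1.70),
    "CB":  (0.02, 40, 88, 5, 2.20),
    "EG":  (0.71, 38, 161, 9, 4.24),
    "GP":  (0.01, 36, 67, 6, 1.86),
    "KS":  (0.05, 32, 98, 7, 3.06),
    "LG":  (0.21, 40, 145, 8, 3.63),
    "MO":  (0.02, 39, 103, 5, 2.64),
    "PS":  (0.09, 39, 151, 9, 3.87),
    "PL":  (0.47, 40, 217, 9, 5.43),
    "SP":  (0.07, 40, 162, 9, 4.05),
    "SM":  (0.63, 40, 231, 9, 5.78),
    "SA":  (0.20, 37, 100, 9, 2.70),
}


def species_registry() -> dict[str, SpeciesRecord]:
    """The 14-species registry of the reference survey, keyed by code."""
    return {
        code: SpeciesRecord(code=code, scientific_name=name, family=family,
                            life_form=life_form, origin=origin,
                            vernacular_names=vern)
        for code, name, family, life_form, origin, vern in _SPECIES
    }


def published_index_totals() -> pd.DataFrame:
    """Published per-species index totals of the reference survey.

    Columns: ``species`` (registry code), ``composite_s`` (Composite
    Salience over the 40 informants), ``ci_n_participants`` (informants
    interviewed about the species), ``ci_n_citations``
    (participant-by-category mention pairs), ``ci_n_categories`` (distinct
    use-categories cited) and ``ci`` (Cultural Importance).
    """
    rows = [
        {"species": code, "composite_s": v[0], "ci_n_participants": v[1],
         "ci_n_citations": v[2], "ci_n_categories": v[3], "ci": v[4]}
        for code, v in _TOTALS.items()
    ]
    return pd.DataFrame(rows)
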