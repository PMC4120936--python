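"""Typed records and long-format CSV input/output for interview data.

The data model mirrors how quantitative-ethnobotany surveys are recorded:
a participant roster (sex, continuous age, migration status), one ordered
freelist of species codes per participant, and long-format use-reports,
each a (participant, species, use-category, use-type) mention.  Species
are referenced everywhere by short registry codes; resolving vernacular
names against vouchers happens upstream of this package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SEXES",
    "AGE_CLASSES",
    "AGE_BIN_EDGES",
    "MIGRATION_STATUSES",
    "MIGRATION_GROUPS",
    "LIFE_FORMS",
    "ORIGINS",
    "USE_CATEGORIES",
    "Participant",
    "SpeciesRecord",
    "Freelist",
    "UseReport",
    "Dataset",
    "ValidationError",
    "derive_age_class",
    "derive_migration_group",
    "derive_actor_groups",
    "normalize_use_type",
    "load_dataset",
    "write_dataset",
    "write_index_table",
    "read_index_table",
]

SEXES = ("female", "male")
#: Age classes used for stratification; bins are half-open, lower-inclusive,
#: so boundary ages 20/40/60 fall in the upper class and the last class is
#: closed below (>= 60).
AGE_CLASSES = ("<20", "20-39", "40-59", ">=60")
AGE_BIN_EDGES = (20.0, 40.0, 60.0)
MIGRATION_STATUSES = ("none", "temporary", "permanent")
#: Actor groups for the migration factor.  Non-migrants are split at age 40
#: (no_young / no_old); in the study design every migrant is under 40.
MIGRATION_GROUPS = ("no_young", "no_old", "temp", "perm")
LIFE_FORMS = ("tree", "shrub", "subshrub")
ORIGINS = ("native", "native_cultivated", "exotic")
#: The nine use-categories of the semi-structured interviews.
USE_CATEGORIES = (
    "construction",
    "environmental",
    "field",
    "fodder",
    "food",
    "fuel",
    "medicine",
    "tools",
    "other",
)

_WS = re.compile(r"\s+")


class ValidationError(ValueError):
    """Raised when interview data violate the schema.

    Carries the offending file and row so transcription errors can be
    located in the source CSVs.
    """

    def __init__(self, message: str, *, filename: str | None = None,
                 row: int | None = None):
        loc = ""
        if filename is not None:
            loc = f" [{filename}" + (f", row {row}" if row is not None else "") + "]"
        super().__init__(message + loc)
        self.filename = filename
        self.row = row


def derive_age_class(age_years: float) -> str:
    """Return the age class containing ``age_years``.

    Bins are [0, 20), [20, 40), [40, 60), [60, inf); ages must be positive.
    """
    if not age_years > 0:
        raise ValidationError(f"age_years must be positive, got {age_years!r}")
    for label, upper in zip(AGE_CLASSES, AGE_BIN_EDGES):
        if age_years < upper:
            return label
    return AGE_CLASSES[-1]


def derive_migration_group(age_years: float, migration_status: str) -> str:
    """Actor group for the migration factor.

    Temporary/permanent migrants map to ``temp``/``perm``; non-migrants
    are split into ``no_young`` (< 40 years) and ``no_old`` (>= 40).
    """
    if migration_status == "temporary":
        return "temp"
    if migration_status == "permanent":
        return "perm"
    if migration_status == "none":
        return "no_young" if age_years < 40 else "no_old"
    raise ValidationError(f"unknown migration_status {migration_status!r}")


def normalize_use_type(label: str) -> str:
    """Case-fold and whitespace-normalize a free-text use-type label."""
    return _WS.sub(" ", label.strip()).casefold()


@dataclass(frozen=True)
class Participant:
    """One interviewee; ``age_class`` and ``migration_group`` are derived."""

    id: str
    sex: str
    age_years: float
    migration_status: str
    age_class: str = field(init=False)
    migration_group: str = field(init=False)

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r} for participant {self.id}")
        if self.migration_status not in MIGRATION_STATUSES:
            raise ValidationError(
                f"unknown migration_status {self.migration_status!r} "
                f"for participant {self.id}")
        object.__setattr__(self, "age_class", derive_age_class(self.age_years))
        object.__setattr__(
            self, "migration_group",
            derive_migration_group(self.age_years, self.migration_status))

    @property
    def is_migrant(self) -> bool:
        return self.migration_status != "none"


def derive_actor_groups(participant: Participant) -> tuple[str, str]:
    """Return ``(age_class, migration_group)`` for a participant."""
    return participant.age_class, participant.migration_group


@dataclass(frozen=True)
class SpeciesRecord:
    code: str
    scientific_name: str
    family: str = ""
    life_form: str = "shrub"
    origin: str = "native"
    vernacular_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.life_form not in LIFE_FORMS:
            raise ValidationError(
                f"unknown life_form {self.life_form!r} for species {self.code}")
        if self.origin not in ORIGINS:
            raise ValidationError(
                f"unknown origin {self.origin!r} for species {self.code}")


@dataclass(frozen=True)
class Freelist:
    """Ordered, duplicate-free sequence of species codes for one participant.

    The salience of the mention at 1-based rank ``r`` in a list of length
    ``L`` is ``(L - r + 1) / L``; both quantities live here.
    """

    participant_id: str
    mentions: tuple[str, ...]

    def __post_init__(self):
        if len(self.mentions) < 1:
            raise ValidationError(
                f"freelist for {self.participant_id} is empty")
        if len(set(self.mentions)) != len(self.mentions):
            raise ValidationError(
                f"duplicate mention in freelist for {self.participant_id}")

    def __len__(self) -> int:
        return len(self.mentions)

    def rank(self, species_code: str) -> int | None:
        """1-based position of ``species_code``, or None if absent."""
        try:
            return self.mentions.index(species_code) + 1
        except ValueError:
            return None


@dataclass(frozen=True)
class UseReport:
    """One (participant, species, use-category, use-type) mention.

    ``use_type`` is stored normalized (case-folded, whitespace-collapsed)
    because labels come from free-text interview transcriptions.
    """

    participant_id: str
    species_code: str
    use_category: str
    use_type: str

    def __post_init__(self):
        if self.use_category not in USE_CATEGORIES:
            raise ValidationError(
                f"unknown use_category {self.use_category!r} "
                f"({self.participant_id}, {self.species_code})")
        object.__setattr__(self, "use_type", normalize_use_type(self.use_type))


@dataclass
class Dataset:
    """A validated interview dataset: roster, registry, freelists, reports."""

    participants: dict[str, Participant]
    species: dict[str, SpeciesRecord]
    freelists: dict[str, Freelist]
    use_reports: list[UseReport]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for pid, fl in self.freelists.items():
            if pid != fl.participant_id:
                raise ValidationError(f"freelist keyed {pid} belongs to "
                                      f"{fl.participant_id}")
            if pid not in self.participants:
                raise ValidationError(f"freelist for unknown participant {pid!r}")
            for code in fl.mentions:
                if code not in self.species:
                    raise ValidationError(
                        f"freelist of {pid} cites unregistered species {code!r}")
        for rep in self.use_reports:
            if rep.participant_id not in self.participants:
                raise ValidationError(
                    f"use-report for unknown participant {rep.participant_id!r}")
            if rep.species_code not in self.species:
                raise ValidationError(
                    f"use-report cites unregistered species {rep.species_code!r}")

    @property
    def participant_ids(self) -> list[str]:
        return list(self.participants)

    @property
    def species_codes(self) -> list[str]:
        return list(self.species)

    def roster_frame(self) -> pd.DataFrame:
        """Roster as a DataFrame with derived actor-group columns."""
        rows = [
            {"id": p.id, "sex": p.sex, "age_years": p.age_years,
             "migration_status": p.migration_status,
             "age_class": p.age_class, "migration_group": p.migration_group,
             "is_migrant": p.is_migrant}
            for p in self.participants.values()
        ]
        return pd.DataFrame(rows)

    def group_members(self, grouping: str) -> dict[str, list[str]]:
        """Participant ids per level of a stratification factor."""
        levels = factor_levels(grouping)
        out: dict[str, list[str]] = {lv: [] for lv in levels}
        for p in self.participants.values():
            out[getattr(p, grouping)].append(p.id)
        return out


#: Stratification factors recognised by the index tables.
FACTORS: dict[str, tuple[str, ...]] = {
    "sex": SEXES,
    "age_class": AGE_CLASSES,
    "migration_group": MIGRATION_GROUPS,
}


def factor_levels(grouping: str) -> tuple[str, ...]:
    try:
        return FACTORS[grouping]
    except KeyError:
        raise ValidationError(
            f"unknown grouping factor {grouping!r}; "
            f"expected one of {sorted(FACTORS)}") from None


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_FILES = {
    "participants": ("id", "sex", "age_years", "migration_status"),
    "species": ("code", "scientific_name", "family", "life_form", "origin",
                "vernacular"),
    "freelists": ("participant_id", "rank", "species_code"),
    "use_reports": ("participant_id", "species_code", "use_category",
                    "use_type"),
}


def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s) {missing}", filename=path.name)
    return df


def load_dataset(directory: str | Path | Mapping[str, str | Path]) -> Dataset:
    """Load and validate the four interview CSVs.

    ``directory`` is either a folder containing ``participants.csv``,
    ``species.csv``, ``freelists.csv`` and ``use_reports.csv``, or a
    mapping from those stem names to explicit paths.  Every error names
    the file and (1-based, header excluded) row that caused it.
    """
    if isinstance(directory, (str, Path)):
        base = Path(directory)
        paths = {k: base / f"{k}.csv" for k in _FILES}
    else:
        paths = {k: Path(v) for k, v in directory.items()}
    for key in _FILES:
        if key not in paths or not paths[key].exists():
            raise ValidationError(f"missing input file for {key!r}",
                                  filename=str(paths.get(key, key)))

    frames = {k: _read_csv(paths[k], _FILES[k][:4] if k != "species" else
                           _FILES[k][:5]) for k in _FILES}

    species: dict[str, SpeciesRecord] = {}
    for i, row in frames["species"].iterrows():
        code = row["code"].strip()
        if code in species:
            raise ValidationError(f"duplicate species code {code!r}",
                                  filename=paths["species"].name, row=i + 1)
        vern = tuple(v.strip() for v in row.get("vernacular", "").split(";")
                     if v.strip())
        try:
            species[code] = SpeciesRecord(
                code=code, scientific_name=row["scientific_name"],
                family=row["family"], life_form=row["life_form"],
                origin=row["origin"], vernacular_names=vern)
        except ValidationError as err:
            raise ValidationError(str(err), filename=paths["species"].name,
                                  row=i + 1) from None

    participants: dict[str, Participant] = {}
    for i, row in frames["participants"].iterrows():
        pid = row["id"].strip()
        if pid in participants:
            raise ValidationError(f"duplicate participant id {pid!r}",
                                  filename=paths["participants"].name, row=i + 1)
        try:
            participants[pid] = Participant(
                id=pid, sex=row["sex"], age_years=float(row["age_years"]),
                migration_status=row["migration_status"])
        except (ValidationError, ValueError) as err:
            raise ValidationError(str(err), filename=paths["participants"].name,
                                  row=i + 1) from None

    mentions: dict[str, list[tuple[int, str]]] = {}
    for i, row in frames["freelists"].iterrows():
        pid = row["participant_id"].strip()
        code = row["species_code"].strip()
        if pid not in participants:
            raise ValidationError(f"freelist row for unknown participant {pid!r}",
                                  filename=paths["freelists"].name, row=i + 1)
        if code not in species:
            raise ValidationError(
                f"freelist row cites unregistered species code {code!r}",
                filename=paths["freelists"].name, row=i + 1)
        try:
            rank = int(row["rank"])
        except ValueError:
            raise ValidationError(f"non-integer rank {row['rank']!r}",
                                  filename=paths["freelists"].name,
                                  row=i + 1) from None
        mentions.setdefault(pid, []).append((rank, code))

    freelists: dict[str, Freelist] = {}
    for pid, entries in mentions.items():
        entries.sort()
        ranks = [r for r, _ in entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError(
                f"freelist ranks for {pid} are not 1..L: {ranks}",
                filename=paths["freelists"].name)
        try:
            freelists[pid] = Freelist(pid, tuple(code for _, code in entries))
        except ValidationError as err:
            raise ValidationError(str(err),
                                  filename=paths["freelists"].name) from None

    reports: list[UseReport] = []
    seen: set[tuple[str, str, str, str]] = set()
    for i, row in frames["use_reports"].iterrows():
        try:
            rep = UseReport(row["participant_id"].strip(),
                            row["species_code"].strip(),
                            row["use_category"].strip(),
                            row["use_type"])
        except ValidationError as err:
            raise ValidationError(str(err), filename=paths["use_reports"].name,
                                  row=i + 1) from None
        key = (rep.participant_id, rep.species_code, rep.use_category,
               rep.use_type)
        if key in seen:
            continue  # duplicate transcription of the same mention
        seen.add(key)
        reports.append(rep)

    try:
        return Dataset(participants, species, freelists, reports)
    except ValidationError as err:
        raise ValidationError(str(err), filename=str(paths["use_reports"].parent))


def write_dataset(dataset: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write the four CSVs; inverse of :func:`load_dataset`."""
    base = Path(directory)
    base.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    rows = [{"id": p.id, "sex": p.sex, "age_years": p.age_years,
             "migration_status": p.migration_status}
            for p in dataset.participants.values()]
    out["participants"] = base / "participants.csv"
    pd.DataFrame(rows, columns=list(_FILES["participants"])).to_csv(
        out["participants"], index=False)

    rows = [{"code": s.code, "scientific_name": s.scientific_name,
             "family": s.family, "life_form": s.life_form, "origin": s.origin,
             "vernacular": ";".join(s.vernacular_names)}
            for s in dataset.species.values()]
    out["species"] = base / "species.csv"
    pd.DataFrame(rows, columns=list(_FILES["species"])).to_csv(
        out["species"], index=False)

    rows = [{"participant_id": fl.participant_id, "rank": r + 1,
             "species_code": code}
            for fl in dataset.freelists.values()
            for r, code in enumerate(fl.mentions)]
    out["freelists"] = base / "freelists.csv"
    pd.DataFrame(rows, columns=list(_FILES["freelists"])).to_csv(
        out["freelists"], index=False)

    rows = [{"participant_id": r.participant_id, "species_code": r.species_code,
             "use_category": r.use_category, "use_type": r.use_type}
            for r in dataset.use_reports]
    out["use_reports"] = base / "use_reports.csv"
    pd.DataFrame(rows, columns=list(_FILES["use_reports"])).to_csv(
        out["use_reports"], index=False)
    return out


def write_index_table(table: pd.DataFrame, path: str | Path,
                      decimals: int = 6) -> Path:
    """Write a per-species index table (one row per species) to CSV.

    Numeric columns are rounded to ``decimals`` places; the file
    round-trips through :func:`read_index_table` at that precision.
    """
    path = Path(path)
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    out.to_csv(path, index=False)
    return path


def read_index_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
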