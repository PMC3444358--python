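"""Typed data model for linked administrative registry tables.

The case-finding rules scan three event streams — hospital contacts with
ICD-10 diagnosis codes, redeemed prescriptions with ATC codes, and
spirometry (lung-function test) services — linked to a person table by a
shared opaque person identifier, the stand-in for a national personal
identification number.

Tables travel as comma-separated text with a header row, ISO-8601 dates
and UTF-8 encoding:

    persons.csv      person_id,birth_date,sex,death_date
    episodes.csv     person_id,contact_date,diagnosis_code,setting,diagnosis_role
    redemptions.csv  person_id,dispense_date,atc_code
    spirometry.csv   person_id,service_date,provider

``death_date`` may be empty (person alive). Closed vocabularies:
``sex`` ∈ {female, male}; ``setting`` ∈ {inpatient, outpatient, emergency};
``diagnosis_role`` ∈ {primary, secondary}; ``provider`` ∈ {GP, specialist}.

Diagnosis/drug code matching is prefix-based after normalization
(strip punctuation and spaces, uppercase), the standard convention for
ICD-10 and ATC code lists: pattern ``J44`` matches ``J44``, ``J449`` and
``J44.9``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, IntegrityError, SchemaError

__all__ = [
    "PersonRecord",
    "HospitalEpisode",
    "PrescriptionRedemption",
    "SpirometryRecord",
    "CodeList",
    "RegistryBundle",
    "match_code",
    "normalize_code",
    "load_bundle",
    "save_bundle",
    "TABLE_SCHEMAS",
]

SEXES = frozenset({"female", "male"})
SETTINGS = frozenset({"inpatient", "outpatient", "emergency"})
DIAGNOSIS_ROLES = frozenset({"primary", "secondary"})
PROVIDERS = frozenset({"GP", "specialist"})

#: ATC code syntax: anatomical letter, 2-digit therapeutic level, then the
#: optional pharmacological / chemical letter levels and 2-digit substance.
ATC_RE = re.compile(r"^[A-Z]\d{2}([A-Z]([A-Z](\d{2})?)?)?$")

TABLE_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "persons": ("person_id", "birth_date", "sex", "death_date"),
    "episodes": ("person_id", "contact_date", "diagnosis_code", "setting", "diagnosis_role"),
    "redemptions": ("person_id", "dispense_date", "atc_code"),
    "spirometry": ("person_id", "service_date", "provider"),
}

DATE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "persons": ("birth_date", "death_date"),
    "episodes": ("contact_date",),
    "redemptions": ("dispense_date",),
    "spirometry": ("service_date",),
}

EVENT_DATE_COLUMN: Mapping[str, str] = {
    "episodes": "contact_date",
    "redemptions": "dispense_date",
    "spirometry": "service_date",
}


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PersonRecord:
    person_id: str
    birth_date: date
    sex: str
    death_date: date | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataError(f"persons: sex {self.sex!r} not in {sorted(SEXES)}")
        if self.death_date is not None and self.death_date < self.birth_date:
            raise DataError(
                f"persons: death_date {self.death_date} precedes birth_date "
                f"{self.birth_date} for {self.person_id!r}"
            )


@dataclass(frozen=True)
class HospitalEpisode:
    person_id: str
    contact_date: date
    diagnosis_code: str
    setting: str = "inpatient"
    diagnosis_role: str = "primary"

    def __post_init__(self) -> None:
        if not self.diagnosis_code:
            raise DataError("episodes: empty diagnosis_code")
        if self.setting not in SETTINGS:
            raise DataError(f"episodes: setting {self.setting!r} not in {sorted(SETTINGS)}")
        if self.diagnosis_role not in DIAGNOSIS_ROLES:
            raise DataError(
                f"episodes: diagnosis_role {self.diagnosis_role!r} not in {sorted(DIAGNOSIS_ROLES)}"
            )


@dataclass(frozen=True)
class PrescriptionRedemption:
    person_id: str
    dispense_date: date
    atc_code: str

    def __post_init__(self) -> None:
        if not ATC_RE.match(self.atc_code or ""):
            raise DataError(f"redemptions: invalid ATC code {self.atc_code!r}")


@dataclass(frozen=True)
class SpirometryRecord:
    person_id: str
    service_date: date
    provider: str = "GP"

    def __post_init__(self) -> None:
        if self.provider not in PROVIDERS:
            raise DataError(f"spirometry: provider {self.provider!r} not in {sorted(PROVIDERS)}")


# ---------------------------------------------------------------------------
# Code lists and matching
# ---------------------------------------------------------------------------

def normalize_code(code: str) -> str:
    """Uppercase a code and strip punctuation/whitespace (``j44.9`` → ``J449``)."""
    return re.sub(r"[^0-9A-Za-z]", "", code).upper()


@dataclass(frozen=True)
class CodeList:
    """A named list of code prefixes with prefix-match semantics."""

    name: str
    patterns: tuple[str, ...]

    def __init__(self, name: str, patterns: Sequence[str]):
        if not patterns:
            raise DataError(f"code list {name!r}: patterns must be non-empty")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "patterns", tuple(normalize_code(p) for p in patterns))

    def matches(self, code: str) -> bool:
        return match_code(code, self)

    def match_series(self, codes: pd.Series) -> pd.Series:
        """Vectorized prefix match over a string Series."""
        norm = codes.fillna("").str.replace(r"[^0-9A-Za-z]", "", regex=True).str.upper()
        return norm.str.startswith(self.patterns)


def match_code(code: str, code_list: CodeList) -> bool:
    """True iff the normalized code starts with any normalized pattern."""
    if not code:
        raise ValueError("match_code: code must be non-empty")
    norm = normalize_code(code)
    return any(norm.startswith(p) for p in code_list.patterns)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class RegistryBundle:
    """The four linked tables, held as pandas DataFrames.

    Construct via :meth:`from_frames` (validating), :meth:`from_records`
    or :func:`load_bundle`; direct construction skips validation.
    """

    persons: pd.DataFrame
    episodes: pd.DataFrame
    redemptions: pd.DataFrame
    spirometries: pd.DataFrame

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_events(self) -> int:
        return len(self.episodes) + len(self.redemptions) + len(self.spirometries)

    def events(self, table: str) -> pd.DataFrame:
        return {"episodes": self.episodes, "redemptions": self.redemptions,
                "spirometry": self.spirometries}[table]

    @classmethod
    def empty(cls) -> "RegistryBundle":
        return cls(*(_empty_table(t) for t in TABLE_SCHEMAS))

    @classmethod
    def from_frames(
        cls,
        persons: pd.DataFrame,
        episodes: pd.DataFrame,
        redemptions: pd.DataFrame,
        spirometries: pd.DataFrame,
        *,
        on_pre_birth: str = "error",
    ) -> "RegistryBundle":
        bundle = cls(
            persons.reset_index(drop=True),
            episodes.reset_index(drop=True),
            redemptions.reset_index(drop=True),
            spirometries.reset_index(drop=True),
        )
        _validate_bundle(bundle, on_pre_birth=on_pre_birth)
        return bundle

    @classmethod
    def from_records(
        cls,
        persons: Iterable[PersonRecord],
        episodes: Iterable[HospitalEpisode] = (),
        redemptions: Iterable[PrescriptionRedemption] = (),
        spirometries: Iterable[SpirometryRecord] = (),
        *,
        on_pre_birth: str = "error",
    ) -> "RegistryBundle":
        def frame(records, table):
            cols = TABLE_SCHEMAS[table]
            rows = [[getattr(r, c) for c in cols] for r in records]
            df = pd.DataFrame(rows, columns=list(cols))
            if df.empty:
                return _empty_table(table)
            for c in DATE_COLUMNS[table]:
                df[c] = pd.to_datetime(df[c])
            return df

        return cls.from_frames(
            frame(persons, "persons"),
            frame(episodes, "episodes"),
            frame(redemptions, "redemptions"),
            frame(spirometries, "spirometry"),
            on_pre_birth=on_pre_birth,
        )

    def equals(self, other: "RegistryBundle") -> bool:
        return all(
            self.events_or_persons(t).equals(other.events_or_persons(t))
            for t in TABLE_SCHEMAS
        )

    def events_or_persons(self, table: str) -> pd.DataFrame:
        return self.persons if table == "persons" else self.events(table)


def _empty_table(table: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_SCHEMAS[table]})
    for c in DATE_COLUMNS[table]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    return df


def _validate_bundle(bundle: RegistryBundle, *, on_pre_birth: str = "error") -> None:
    if on_pre_birth not in ("error", "ignore"):
        raise ValueError("on_pre_birth must be 'error' or 'ignore'")
    persons = bundle.persons
    dup = persons["person_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"persons: duplicate person_id values: {sorted(persons.loc[dup, 'person_id'].unique())[:10]}"
        )
    bad_sex = ~persons["sex"].isin(SEXES)
    if bad_sex.any():
        raise DataError(f"persons: invalid sex values at rows {list(persons.index[bad_sex][:10])}")
    has_death = persons["death_date"].notna()
    bad_death = has_death & (persons["death_date"] < persons["birth_date"])
    if bad_death.any():
        raise DataError(
            f"persons: death_date precedes birth_date for "
            f"{sorted(persons.loc[bad_death, 'person_id'])[:10]}"
        )

    known = set(persons["person_id"])
    birth = persons.set_index("person_id")["birth_date"]
    for table, vocab_col, vocab in (
        ("episodes", "setting", SETTINGS),
        ("episodes", "diagnosis_role", DIAGNOSIS_ROLES),
        ("spirometry", "provider", PROVIDERS),
    ):
        df = bundle.events(table)
        bad = ~df[vocab_col].isin(vocab)
        if bad.any():
            raise DataError(
                f"{table}: invalid {vocab_col} values at rows {list(df.index[bad][:10])}"
            )
    empty_dx = bundle.episodes["diagnosis_code"].fillna("") == ""
    if empty_dx.any():
        raise DataError(
            f"episodes: empty diagnosis_code at rows {list(bundle.episodes.index[empty_dx][:10])}"
        )
    bad_atc = ~bundle.redemptions["atc_code"].fillna("").str.match(ATC_RE)
    if bad_atc.any():
        raise DataError(
            f"redemptions: invalid ATC codes at rows {list(bundle.redemptions.index[bad_atc][:10])}"
        )

    for table, datecol in EVENT_DATE_COLUMN.items():
        df = bundle.events(table)
        orphan = ~df["person_id"].isin(known)
        if orphan.any():
            raise IntegrityError(
                f"{table}: person_id not found in persons at rows "
                f"{list(df.index[orphan][:10])} "
                f"(ids {sorted(df.loc[orphan, 'person_id'].unique())[:10]})"
            )
        if on_pre_birth == "error" and len(df):
            pre = df[datecol] < df["person_id"].map(birth)
            if pre.any():
                raise DataError(
                    f"{table}: event predates person's birth_date at rows {list(df.index[pre][:10])}"
                )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

DEFAULT_FILENAMES: Mapping[str, str] = {
    "persons": "persons.csv",
    "episodes": "episodes.csv",
    "redemptions": "redemptions.csv",
    "spirometry": "spirometry.csv",
}


def _read_table(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise DataError(f"{table}: file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing} in {path.name}")
    df = df[list(TABLE_SCHEMAS[table])]
    for c in DATE_COLUMNS[table]:
        raw = df[c]
        parsed = pd.to_datetime(raw.replace("", None), format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & (raw != "")
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = [int(i) + 2 for i in df.index[bad][:10]]
            raise DataError(
                f"{table}: unparseable date(s) in column {c!r} at line(s) {lines} of {path.name}"
            )
        df[c] = parsed
    return df


def load_bundle(
    paths: Mapping[str, Path | str] | Path | str,
    *,
    on_pre_birth: str = "error",
) -> RegistryBundle:
    """Load and validate a registry bundle.

    ``paths`` is either a directory containing the standard file names or a
    mapping ``{table: path}`` for the four tables. Validation enforces the
    documented schemas, ISO-8601 dates, closed vocabularies, referential
    integrity of every event's ``person_id``, and (by default) that no event
    predates its person's birth (``on_pre_birth="ignore"`` relaxes that).
    """
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        paths = {t: root / fn for t, fn in DEFAULT_FILENAMES.items()}
    frames = {t: _read_table(Path(paths[t]), t) for t in TABLE_SCHEMAS}
    return RegistryBundle.from_frames(
        frames["persons"], frames["episodes"], frames["redemptions"], frames["spirometry"],
        on_pre_birth=on_pre_birth,
    )


def save_bundle(bundle: RegistryBundle, directory: Path | str) -> dict[str, Path]:
    """Write the four tables as CSV with ISO-8601 dates; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for table, fn in DEFAULT_FILENAMES.items():
        df = bundle.events_or_persons(table).copy()
        for c in DATE_COLUMNS[table]:
            df[c] = df[c].dt.strftime("%Y-%m-%d").fillna("")
        path = directory / fn
        df.to_csv(path, index=False)
        written[table] = path
    return written
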