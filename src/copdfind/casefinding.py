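"""Time-windowed case-finding criteria and candidate-algorithm selection.

A criterion is a count predicate over one event stream inside a lookback
window ending at an index date: the window is half-open,
``(index_date − lookback_days, index_date]``, so the index date itself is
included. The chosen COPD algorithm combines three criteria by OR:

    a) ≥1 hospital contact with a chronic lung-disease diagnosis in the
       preceding 5 years (1826 days);
    b) ≥2 redeemed prescriptions of obstructive-airway drugs in the
       preceding 12 months (365 days) — repeat same-day dispensings count;
    c) ≥2 spirometries on *different dates* in the preceding 12 months.

A person is eligible only if aged 35 or above (completed years at the
index date) and alive at the index date; ineligible persons are never
identified regardless of their events.

Candidate algorithms are all OR-combinations of two to four criteria from
a pool; the selected algorithm maximizes positive predictive value against
a clinician-supplied reference list, breaking ties by fewer criteria, then
by name.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .registry import (
    CodeList,
    RegistryBundle,
    EVENT_DATE_COLUMN,
)

__all__ = [
    "HOSPITAL_DX",
    "PRESCRIPTION",
    "SPIROMETRY",
    "Criterion",
    "CaseAlgorithm",
    "CohortResult",
    "SelectionReport",
    "CandidateResult",
    "completed_years",
    "evaluate_criterion",
    "identify_cohort",
    "enumerate_algorithms",
    "select_algorithm",
    "criteria_pattern_counts",
]

HOSPITAL_DX = "hospital_dx"
PRESCRIPTION = "prescription"
SPIROMETRY = "spirometry"
CRITERION_KINDS = (HOSPITAL_DX, PRESCRIPTION, SPIROMETRY)

#: event stream (registry table) each criterion kind scans
KIND_TABLE = {HOSPITAL_DX: "episodes", PRESCRIPTION: "redemptions", SPIROMETRY: "spirometry"}
KIND_CODE_COLUMN = {HOSPITAL_DX: "diagnosis_code", PRESCRIPTION: "atc_code"}


@dataclass(frozen=True)
class Criterion:
    """A count predicate over one event stream within a lookback window.

    ``settings`` / ``diagnosis_roles`` optionally restrict hospital
    contacts to a subset of contact settings or diagnosis roles; by default
    every contact (inpatient, outpatient, emergency) and any diagnosis
    position counts.
    """

    label: str
    kind: str
    lookback_days: int
    min_count: int = 1
    distinct_dates: bool = False
    code_list: CodeList | None = None
    settings: tuple[str, ...] | None = None
    diagnosis_roles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in CRITERION_KINDS:
            raise ConfigurationError(f"criterion {self.label!r}: unknown kind {self.kind!r}")
        if self.min_count < 1:
            raise ConfigurationError(f"criterion {self.label!r}: min_count must be ≥ 1")
        if self.lookback_days < 1:
            raise ConfigurationError(f"criterion {self.label!r}: lookback_days must be ≥ 1")
        if self.kind in KIND_CODE_COLUMN and self.code_list is None:
            raise ConfigurationError(
                f"criterion {self.label!r}: kind {self.kind!r} requires a code_list"
            )


@dataclass(frozen=True)
class CaseAlgorithm:
    """An OR-combination of criteria with an eligibility rule."""

    name: str
    criteria: tuple[Criterion, ...]
    min_age_years: int = 35
    require_alive: bool = True

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ConfigurationError(f"algorithm {self.name!r}: needs at least one criterion")
        labels = [c.label for c in self.criteria]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"algorithm {self.name!r}: duplicate criterion labels")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.criteria)


@dataclass
class CohortResult:
    """Per-person evaluation of an algorithm at an index date.

    ``table`` has one row per person in the bundle: ``person_id``,
    ``age_years``, ``eligible``, one boolean column ``crit_<label>`` per
    criterion, and ``identified`` (= eligible AND any criterion).
    ``matches`` (optional) maps criterion label → matched event row
    indices per person for audit.
    """

    index_date: pd.Timestamp
    algorithm: CaseAlgorithm
    table: pd.DataFrame
    matches: dict[str, pd.Series] | None = None

    @property
    def identified_ids(self) -> list:
        return self.table.loc[self.table["identified"], "person_id"].tolist()

    @property
    def n_identified(self) -> int:
        return int(self.table["identified"].sum())

    def criterion_column(self, label: str) -> pd.Series:
        return self.table[f"crit_{label}"]


def completed_years(birth_dates: pd.Series, at: pd.Timestamp) -> pd.Series:
    """Whole years of age at ``at`` (birthday-based, not calendar-year)."""
    birth = pd.DatetimeIndex(birth_dates)
    years = at.year - birth.year
    not_yet = (birth.month > at.month) | ((birth.month == at.month) & (birth.day > at.day))
    return pd.Series(years - not_yet.astype(int), index=birth_dates.index)


def _window_mask(dates: pd.Series, index_date: pd.Timestamp, lookback_days: int) -> pd.Series:
    start = index_date - pd.Timedelta(days=lookback_days)
    return (dates > start) & (dates <= index_date)


def _criterion_event_mask(events: pd.DataFrame, criterion: Criterion,
                          index_date: pd.Timestamp) -> pd.Series:
    """Row mask of events that count toward the criterion."""
    datecol = EVENT_DATE_COLUMN[KIND_TABLE[criterion.kind]]
    mask = _window_mask(events[datecol], index_date, criterion.lookback_days)
    if criterion.kind in KIND_CODE_COLUMN:
        mask &= criterion.code_list.match_series(events[KIND_CODE_COLUMN[criterion.kind]])
    if criterion.kind == HOSPITAL_DX:
        if criterion.settings is not None:
            mask &= events["setting"].isin(criterion.settings)
        if criterion.diagnosis_roles is not None:
            mask &= events["diagnosis_role"].isin(criterion.diagnosis_roles)
    return mask


def evaluate_criterion(
    events: pd.DataFrame,
    criterion: Criterion,
    index_date: date | pd.Timestamp,
) -> tuple[bool, pd.DataFrame]:
    """Evaluate one criterion on one person's events from the relevant stream.

    Returns ``(satisfied, matched_events)``; the matched rows are the
    audit trail of which events carried the decision. Counting uses
    distinct calendar dates when ``criterion.distinct_dates`` is set,
    raw event count otherwise.
    """
    index_date = pd.Timestamp(index_date)
    if len(events) and events["person_id"].nunique() > 1:
        raise ValueError("evaluate_criterion expects events for a single person")
    mask = _criterion_event_mask(events, criterion, index_date) if len(events) else \
        pd.Series(dtype=bool)
    matched = events[mask] if len(events) else events
    datecol = EVENT_DATE_COLUMN[KIND_TABLE[criterion.kind]]
    count = matched[datecol].nunique() if criterion.distinct_dates else len(matched)
    return count >= criterion.min_count, matched


def identify_cohort(
    bundle: RegistryBundle,
    algorithm: CaseAlgorithm,
    index_date: date | pd.Timestamp,
    *,
    collect_matches: bool = False,
) -> CohortResult:
    """Apply a case-finding algorithm to every person in a bundle.

    Vectorized over persons; with ``collect_matches`` the per-criterion
    matched event indices are retained (slower, for audit).
    """
    index_date = pd.Timestamp(index_date)
    persons = bundle.persons
    out = pd.DataFrame({"person_id": persons["person_id"]})
    if len(persons):
        out["age_years"] = completed_years(persons["birth_date"], index_date)
        alive = persons["death_date"].isna() | (persons["death_date"] >= index_date)
        eligible = out["age_years"] >= algorithm.min_age_years
        if algorithm.require_alive:
            eligible &= alive
        out["eligible"] = eligible
    else:
        out["age_years"] = pd.Series(dtype=int)
        out["eligible"] = pd.Series(dtype=bool)

    matches: dict[str, pd.Series] = {}
    any_crit = pd.Series(False, index=out.index)
    for crit in algorithm.criteria:
        events = bundle.events(KIND_TABLE[crit.kind])
        col = f"crit_{crit.label}"
        if len(events) == 0 or len(persons) == 0:
            out[col] = pd.Series(False, index=out.index, dtype=bool)
        else:
            mask = _criterion_event_mask(events, crit, index_date)
            sel = events[mask]
            datecol = EVENT_DATE_COLUMN[KIND_TABLE[crit.kind]]
            if crit.distinct_dates:
                counts = sel.groupby("person_id")[datecol].nunique()
            else:
                counts = sel.groupby("person_id").size()
            out[col] = (
                out["person_id"].map(counts).fillna(0).astype(int) >= crit.min_count
            )
            if collect_matches:
                matches[crit.label] = sel.groupby("person_id").apply(
                    lambda df: df.index.tolist()
                )
        any_crit |= out[col]
    out["identified"] = out["eligible"] & any_crit
    return CohortResult(index_date, algorithm, out, matches if collect_matches else None)


# ---------------------------------------------------------------------------
# Candidate enumeration and selection
# ---------------------------------------------------------------------------

def enumerate_algorithms(
    criterion_pool: Sequence[Criterion],
    min_size: int = 2,
    max_size: int = 4,
    *,
    min_age_years: int = 35,
    require_alive: bool = True,
) -> list[CaseAlgorithm]:
    """All OR-combinations of ``min_size``–``max_size`` criteria from a pool.

    Candidates are deterministically named by their sorted criterion labels
    (``"a+c"``) and ordered by size then name.
    """
    if len(criterion_pool) < min_size:
        raise ValueError(
            f"criterion pool has {len(criterion_pool)} entries; need ≥ {min_size}"
        )
    labels = [c.label for c in criterion_pool]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("criterion pool labels must be unique")
    pool = sorted(criterion_pool, key=lambda c: c.label)
    out: list[CaseAlgorithm] = []
    for size in range(min_size, min(max_size, len(pool)) + 1):
        for combo in itertools.combinations(pool, size):
            out.append(
                CaseAlgorithm(
                    name="+".join(c.label for c in combo),
                    criteria=tuple(combo),
                    min_age_years=min_age_years,
                    require_alive=require_alive,
                )
            )
    return out


@dataclass(frozen=True)
class CandidateResult:
    name: str
    n_criteria: int
    n_identified: int
    n_true_positive: int
    ppv: "object | None"  # ProportionEstimate; None when no one is identified

    @property
    def ppv_value(self) -> float | None:
        return None if self.ppv is None else self.ppv.estimate


@dataclass
class SelectionReport:
    """PPV-ranked comparison of candidate algorithms against a reference list."""

    candidates: list[CandidateResult]
    chosen: CaseAlgorithm

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": c.name,
                "n_criteria": c.n_criteria,
                "n_identified": c.n_identified,
                "n_true_positive": c.n_true_positive,
                "ppv": c.ppv_value,
                "ppv_ci_low": None if c.ppv is None else c.ppv.ci_low,
                "ppv_ci_high": None if c.ppv is None else c.ppv.ci_high,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(rows)


def select_algorithm(
    candidates: Sequence[CaseAlgorithm],
    bundle: RegistryBundle,
    reference_positive_ids: Iterable,
    index_date: date | pd.Timestamp,
) -> SelectionReport:
    """Rank candidates by PPV against a reference case list and pick the best.

    PPV = |identified ∩ reference| / |identified|, with an exact binomial
    CI. Ranking: PPV descending, then fewer criteria, then name; a
    candidate identifying nobody has undefined PPV and ranks last. The
    chosen algorithm is the top-ranked candidate — the highest-PPV
    algorithm, favouring the simplest on ties.
    """
    from .stats import exact_binomial_ci  # local import to avoid cycle

    reference = set(reference_positive_ids)
    unknown = reference - set(bundle.persons["person_id"])
    if unknown:
        raise ValueError(
            f"reference ids not present in bundle: {sorted(unknown)[:10]}"
        )
    if not candidates:
        raise ValueError("no candidate algorithms supplied")

    results: list[CandidateResult] = []
    for algo in candidates:
        cohort = identify_cohort(bundle, algo, index_date)
        ids = set(cohort.identified_ids)
        n_id = len(ids)
        tp = len(ids & reference)
        ppv = exact_binomial_ci(tp, n_id) if n_id else None
        results.append(CandidateResult(algo.name, len(algo.criteria), n_id, tp, ppv))

    def key(c: CandidateResult):
        undefined = c.ppv is None
        return (undefined, -(c.ppv_value if not undefined else 0.0), c.n_criteria, c.name)

    order = sorted(range(len(results)), key=lambda i: key(results[i]))
    results = [results[i] for i in order]
    chosen = {a.name: a for a in candidates}[results[0].name]
    return SelectionReport(results, chosen)


def criteria_pattern_counts(cohort: CohortResult) -> pd.Series:
    """Counts of identified persons by exact criterion-combination pattern.

    Keys are concatenations of the satisfied criterion labels in algorithm
    order (e.g. ``a``, ``b``, ``ab``, ``abc``); the cells partition the
    identified set, so the counts sum to the identified total.
    """
    labels = cohort.algorithm.labels
    t = cohort.table[cohort.table["identified"]]
    pattern = pd.Series("", index=t.index, dtype=object)
    for lab in labels:
        pattern = pattern + np.where(t[f"crit_{lab}"], lab, "")
    keys = [
        "".join(combo)
        for size in range(1, len(labels) + 1)
        for combo in itertools.combinations(labels, size)
    ]
    counts = pattern.value_counts() if len(t) else pd.Series(dtype=int)
    return pd.Series({k: int(counts.get(k, 0)) for k in keys}, name="count")
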