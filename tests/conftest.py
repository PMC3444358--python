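"""Shared fixtures: hand-built bundles, a random-bundle generator, and an
independent brute-force evaluator used as the oracle for the vectorized
cohort identification."""

from __future__ import annotations

import random
from datetime import date, timedelta

import pandas as pd
import pytest

from copdfind import (
    CaseAlgorithm,
    CodeList,
    Criterion,
    HospitalEpisode,
    PersonRecord,
    PrescriptionRedemption,
    RegistryBundle,
    SpirometryRecord,
)
from copdfind.config import RunConfig

INDEX_DATE = date(2007, 1, 1)

ICD_LUNG = CodeList("icd10_lung", ["J40", "J41", "J42", "J43", "J44", "J45", "J46", "J47", "J96"])
ATC_LUNG = CodeList("atc_lung", ["R03"])

CRIT_A = Criterion("a", "hospital_dx", 1826, 1, False, ICD_LUNG)
CRIT_B = Criterion("b", "prescription", 365, 2, False, ATC_LUNG)
CRIT_C = Criterion("c", "spirometry", 365, 2, True)
DEFAULT_ALGORITHM = CaseAlgorithm("copd_three_criterion", (CRIT_A, CRIT_B, CRIT_C))


@pytest.fixture
def index_date():
    return INDEX_DATE

@pytest.fixture
def algorithm():
    return DEFAULT_ALGORITHM

@pytest.fixture
def run_config():
    return RunConfig()


def person(pid, age=60, sex="female", death=None, index=INDEX_DATE):
    """A person aged exactly `age` completed years at the index date."""
    birth = date(index.year - age, index.month, index.day) - timedelta(days=100)
    return PersonRecord(pid, birth, sex, death)


def days_before(n, index=INDEX_DATE):
    return index - timedelta(days=n)


@pytest.fixture
def tiny_bundle():
    """Three persons, five events, all well-formed."""
    return RegistryBundle.from_records(
        persons=[person("P1"), person("P2"), person("P3")],
        episodes=[HospitalEpisode("P1", days_before(400), "J44.9", "inpatient", "primary")],
        redemptions=[
            PrescriptionRedemption("P2", days_before(90), "R03AC02"),
            PrescriptionRedemption("P2", days_before(270), "R03BB04"),
        ],
        spirometries=[
            SpirometryRecord("P3", days_before(30), "GP"),
            SpirometryRecord("P3", days_before(60), "specialist"),
        ],
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracle (pure-python, datetime-based)
# ---------------------------------------------------------------------------

def _bf_norm(code: str) -> str:
    return "".join(ch for ch in code if ch.isalnum()).upper()


def bf_match(code: str, patterns) -> bool:
    c = _bf_norm(code)
    return any(c.startswith(_bf_norm(p)) for p in patterns)


def bf_criterion(events, criterion, index):
    """events: list of (date, code-or-None) tuples for one person."""
    hits = []
    for d, code in events:
        delta = (index - d).days
        if not (0 <= delta < criterion.lookback_days):
            continue
        if criterion.code_list is not None and not bf_match(code, criterion.code_list.patterns):
            continue
        hits.append(d)
    count = len(set(hits)) if criterion.distinct_dates else len(hits)
    return count >= criterion.min_count


def bf_identify(bundle: RegistryBundle, algorithm: CaseAlgorithm, index: date):
    """Per-person identification flags recomputed by explicit loops."""
    stream_table = {"hospital_dx": ("episodes", "contact_date", "diagnosis_code"),
                    "prescription": ("redemptions", "dispense_date", "atc_code"),
                    "spirometry": ("spirometry", "service_date", None)}
    out = {}
    for _, p in bundle.persons.iterrows():
        birth = p["birth_date"].date()
        age = index.year - birth.year - ((index.month, index.day) < (birth.month, birth.day))
        alive = pd.isna(p["death_date"]) or p["death_date"].date() >= index
        eligible = age >= algorithm.min_age_years and (alive or not algorithm.require_alive)
        flags = {}
        for crit in algorithm.criteria:
            table, datecol, codecol = stream_table[crit.kind]
            df = bundle.events(table)
            ev = [
                (r[datecol].date(), r[codecol] if codecol else None)
                for _, r in df[df["person_id"] == p["person_id"]].iterrows()
            ]
            flags[crit.label] = bf_criterion(ev, crit, index)
        out[p["person_id"]] = {
            "eligible": eligible,
            "flags": flags,
            "identified": eligible and any(flags.values()),
        }
    return out


# ---------------------------------------------------------------------------
# Random small bundles for property checks
# ---------------------------------------------------------------------------

ICD_POOL = ["J449", "J44.9", "j45", "J96", "I251", "E119", "K21.9", "J20"]
ATC_POOL = ["R03AC02", "R03BB04", "r03ak06", "N02BE01", "C09AA05", "A02BC01"]


def random_bundle(rng: random.Random, max_persons=50, max_events=20,
                  index=INDEX_DATE) -> RegistryBundle:
    n = rng.randint(1, max_persons)
    persons, episodes, redemptions, spirometries = [], [], [], []
    for i in range(n):
        pid = f"R{i:03d}"
        age = rng.randint(20, 95)
        birth = date(index.year - age, index.month, index.day) - timedelta(days=rng.randint(0, 364))
        death = None
        if rng.random() < 0.08:
            death = index + timedelta(days=rng.randint(-400, 400))
            if death < birth:
                death = birth
        persons.append(PersonRecord(pid, birth, rng.choice(["female", "male"]), death))
        for _ in range(rng.randint(0, max_events)):
            # dates may fall inside or outside the windows, and after death
            d = index - timedelta(days=rng.randint(0, 2200))
            if d < birth:
                continue
            stream = rng.choice(["hosp", "rx", "spiro"])
            if stream == "hosp":
                episodes.append(HospitalEpisode(
                    pid, d, rng.choice(ICD_POOL),
                    rng.choice(["inpatient", "outpatient", "emergency"]),
                    rng.choice(["primary", "secondary"]),
                ))
            elif stream == "rx":
                redemptions.append(PrescriptionRedemption(pid, d, rng.choice(ATC_POOL).upper()))
            else:
                spirometries.append(SpirometryRecord(pid, d, rng.choice(["GP", "specialist"])))
    return RegistryBundle.from_records(persons, episodes, redemptions, spirometries)
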