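"""Criteria engine: windowed predicates, eligibility, enumeration, selection."""

import itertools
import math
import random
from datetime import date, timedelta

import pandas as pd
import pytest

from copdfind import (
    CaseAlgorithm,
    Criterion,
    HospitalEpisode,
    PrescriptionRedemption,
    RegistryBundle,
    SpirometryRecord,
    criteria_pattern_counts,
    enumerate_algorithms,
    evaluate_criterion,
    identify_cohort,
    select_algorithm,
)
from copdfind.errors import ConfigurationError

from conftest import (
    ATC_LUNG,
    CRIT_A,
    CRIT_B,
    CRIT_C,
    DEFAULT_ALGORITHM,
    INDEX_DATE,
    bf_identify,
    days_before,
    person,
    random_bundle,
)


def one_person_bundle(episodes=(), redemptions=(), spirometries=(), age=60, death=None):
    return RegistryBundle.from_records(
        [person("P1", age=age, death=death)], episodes, redemptions, spirometries
    )


class TestEvaluateCriterion:
    def test_two_redemptions_within_year_satisfy_prescription_criterion(self):
        b = one_person_bundle(redemptions=[
            PrescriptionRedemption("P1", days_before(90), "R03AC02"),   # ~3 months
            PrescriptionRedemption("P1", days_before(270), "R03BB04"),  # ~9 months
        ])
        ok, matched = evaluate_criterion(b.redemptions, CRIT_B, INDEX_DATE)
        assert ok and len(matched) == 2

    def test_zero_events_fail_every_criterion(self):
        b = one_person_bundle()
        for crit, table in ((CRIT_A, b.episodes), (CRIT_B, b.redemptions),
                            (CRIT_C, b.spirometries)):
            ok, matched = evaluate_criterion(table, crit, INDEX_DATE)
            assert not ok and len(matched) == 0

    def test_same_day_spirometries_do_not_count_twice(self):
        d = days_before(100)
        b = one_person_bundle(spirometries=[
            SpirometryRecord("P1", d, "GP"), SpirometryRecord("P1", d, "specialist"),
        ])
        ok, matched = evaluate_criterion(b.spirometries, CRIT_C, INDEX_DATE)
        assert not ok and len(matched) == 2  # both matched, but one distinct date

    def test_distinct_date_count_matches_brute_force(self):
        """Oracle: enumerate distinct dates explicitly over random event sets."""
        rng = random.Random(11)
        for _ in range(50):
            dates = [days_before(rng.randint(0, 500)) for _ in range(rng.randint(0, 6))]
            b = one_person_bundle(
                spirometries=[SpirometryRecord("P1", d, "GP") for d in dates]
            )
            distinct_in_window = len({d for d in dates if 0 <= (INDEX_DATE - d).days < 365})
            ok, _ = evaluate_criterion(b.spirometries, CRIT_C, INDEX_DATE)
            assert ok == (distinct_in_window >= 2)

    def test_window_is_half_open_on_the_far_side(self):
        # exactly lookback_days before index is outside; index date itself inside
        inside = one_person_bundle(episodes=[
            HospitalEpisode("P1", INDEX_DATE, "J44", "inpatient", "primary")])
        outside = one_person_bundle(episodes=[
            HospitalEpisode("P1", days_before(1826), "J44", "inpatient", "primary")])
        assert evaluate_criterion(inside.episodes, CRIT_A, INDEX_DATE)[0]
        assert not evaluate_criterion(outside.episodes, CRIT_A, INDEX_DATE)[0]

    def test_same_day_redemptions_do_count_twice(self):
        # "at least twice" for prescriptions has no distinct-date requirement
        d = days_before(50)
        b = one_person_bundle(redemptions=[
            PrescriptionRedemption("P1", d, "R03AC02"),
            PrescriptionRedemption("P1", d, "R03AC02"),
        ])
        assert evaluate_criterion(b.redemptions, CRIT_B, INDEX_DATE)[0]

    def test_code_list_required_for_coded_streams(self):
        with pytest.raises(ConfigurationError):
            Criterion("x", "prescription", 365, 2)


class TestIdentifyCohort:
    def test_under_35_never_identified(self):
        b = one_person_bundle(
            age=34,
            episodes=[HospitalEpisode("P1", days_before(10), "J44", "inpatient", "primary")],
            redemptions=[PrescriptionRedemption("P1", days_before(10), "R03AC02"),
                         PrescriptionRedemption("P1", days_before(20), "R03AC02")],
            spirometries=[SpirometryRecord("P1", days_before(10), "GP"),
                          SpirometryRecord("P1", days_before(20), "GP")],
        )
        row = identify_cohort(b, DEFAULT_ALGORITHM, INDEX_DATE).table.iloc[0]
        assert row["crit_a"] and row["crit_b"] and row["crit_c"]
        assert not row["eligible"] and not row["identified"]

    def test_dead_before_index_never_identified(self):
        b = one_person_bundle(
            death=INDEX_DATE - timedelta(days=30),
            episodes=[HospitalEpisode("P1", days_before(100), "J44", "inpatient", "primary")],
        )
        assert identify_cohort(b, DEFAULT_ALGORITHM, INDEX_DATE).n_identified == 0

    def test_death_on_index_date_counts_as_alive(self):
        b = one_person_bundle(
            death=INDEX_DATE,
            episodes=[HospitalEpisode("P1", days_before(100), "J44", "inpatient", "primary")],
        )
        assert identify_cohort(b, DEFAULT_ALGORITHM, INDEX_DATE).n_identified == 1

    def test_empty_bundle_gives_empty_cohort(self):
        cohort = identify_cohort(RegistryBundle.empty(), DEFAULT_ALGORITHM, INDEX_DATE)
        assert len(cohort.table) == 0 and cohort.n_identified == 0

    def test_planted_fixture_matches_brute_force(self):
        """Ten persons with planted events: flags equal an independent
        per-person re-evaluation."""
        rng = random.Random(101)
        b = random_bundle(rng, max_persons=10, max_events=15)
        cohort = identify_cohort(b, DEFAULT_ALGORITHM, INDEX_DATE)
        expected = bf_identify(b, DEFAULT_ALGORITHM, INDEX_DATE)
        for _, row in cohort.table.iterrows():
            exp = expected[row["person_id"]]
            assert row["eligible"] == exp["eligible"]
            assert row["identified"] == exp["identified"]
            for lab in "abc":
                assert row[f"crit_{lab}"] == exp["flags"][lab], (row["person_id"], lab)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_bundles_match_brute_force(self, seed):
        rng = random.Random(1000 + seed)
        b = random_bundle(rng)
        cohort = identify_cohort(b, DEFAULT_ALGORITHM, INDEX_DATE)
        expected = bf_identify(b, DEFAULT_ALGORITHM, INDEX_DATE)
        got = dict(zip(cohort.table["person_id"], cohort.table["identified"]))
        assert got == {pid: v["identified"] for pid, v in expected.items()}

    def test_adding_events_never_unidentifies(self):
        """Monotonicity: more events can only keep or add identifications."""
        rng = random.Random(55)
        for trial in range(10):
            b = random_bundle(rng, max_persons=15, max_events=8)
            before = identify_cohort(b, DEFAULT_ALGORITHM, INDEX_DATE)
            extra = b.redemptions.copy()
            pid = b.persons["person_id"].iloc[rng.randrange(len(b.persons))]
            birth = b.persons.set_index("person_id")["birth_date"][pid]
            d = max(pd.Timestamp(days_before(rng.randint(0, 400))), birth)
            extra.loc[len(extra)] = [pid, d, "R03AC02"]
            b2 = RegistryBundle.from_frames(b.persons, b.episodes, extra, b.spirometries)
            after = identify_cohort(b2, DEFAULT_ALGORITHM, INDEX_DATE)
            assert set(before.identified_ids) <= set(after.identified_ids)

    def test_adding_criterion_never_shrinks_identified_set(self):
        rng = random.Random(77)
        for trial in range(10):
            b = random_bundle(rng, max_persons=20)
            two = CaseAlgorithm("ab", (CRIT_A, CRIT_B))
            three = CaseAlgorithm("abc", (CRIT_A, CRIT_B, CRIT_C))
            assert (set(identify_cohort(b, two, INDEX_DATE).identified_ids)
                    <= set(identify_cohort(b, three, INDEX_DATE).identified_ids))


class TestEnumeration:
    def make_pool(self, k):
        return [
            Criterion(chr(ord("a") + i), "prescription", 365, i + 1, False, ATC_LUNG)
            for i in range(k)
        ]

    @pytest.mark.parametrize("pool_size,expected", [(2, 1), (3, 4), (4, 11)])
    def test_candidate_counts(self, pool_size, expected):
        assert len(enumerate_algorithms(self.make_pool(pool_size))) == expected

    def test_pool_of_five_against_exhaustive_subsets(self):
        pool = self.make_pool(5)
        algos = enumerate_algorithms(pool)
        labels = [c.label for c in pool]
        subsets = {
            frozenset(s)
            for r in (2, 3, 4)
            for s in itertools.combinations(labels, r)
        }
        assert len(algos) == len(subsets) == 25
        assert {frozenset(a.labels) for a in algos} == subsets

    def test_counts_equal_binomial_sums(self):
        for k in range(2, 8):
            expected = sum(math.comb(k, r) for r in range(2, min(4, k) + 1))
            assert len(enumerate_algorithms(self.make_pool(k))) == expected

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            enumerate_algorithms(self.make_pool(1))

    def test_deterministic_naming_and_order(self):
        algos = enumerate_algorithms(self.make_pool(3))
        assert [a.name for a in algos] == ["a+b", "a+c", "b+c", "a+b+c"]


class TestSelection:
    def build_selection_bundle(self):
        """Persons engineered so a 3-criterion candidate uniquely maximizes
        PPV among sizes 2-3 and ties with the 4-criterion superset.

        Criteria w/x/y/z match ATC prefixes R03A/R03B/R03C/R03X; nobody
        redeems an R03X drug, so any candidate ∪ {z} ties with the
        candidate itself. Hand tally with reference {P1,P2,P3,P5,P6}:
        pairs top out at PPV 0.80 (w+y), w+x+y = 5/6 ≈ 0.833, and
        w+x+y+z ties it with one more criterion.
        """
        from copdfind import CodeList
        pool = [
            Criterion(lab, "prescription", 365, 1, False, CodeList(lab, [pat]))
            for lab, pat in (("w", "R03A"), ("x", "R03B"), ("y", "R03C"), ("z", "R03X"))
        ]
        code_for = {"w": "R03AC02", "x": "R03BB04", "y": "R03CC02"}
        hits = {
            "P1": "w", "P2": "w",        # true, hospital-drug w only
            "P3": "x",                   # true
            "P4": "wxy",                 # the one false positive, hit by all three
            "P5": "y", "P6": "y",        # true
        }
        persons, rx = [], []
        for pid, streams in hits.items():
            persons.append(person(pid))
            for s in streams:
                rx.append(PrescriptionRedemption(pid, days_before(30), code_for[s]))
        bundle = RegistryBundle.from_records(persons, redemptions=rx)
        reference = ["P1", "P2", "P3", "P5", "P6"]
        return bundle, pool, reference

    def test_tie_broken_by_fewer_criteria(self):
        bundle, pool, reference = self.build_selection_bundle()
        candidates = enumerate_algorithms(pool, 2, 4)
        report = select_algorithm(candidates, bundle, reference, INDEX_DATE)
        by_name = {c.name: c for c in report.candidates}
        assert by_name["w+x+y"].ppv_value == pytest.approx(5 / 6)
        assert by_name["w+x+y+z"].ppv_value == pytest.approx(5 / 6)
        assert by_name["w+y"].ppv_value == pytest.approx(4 / 5)
        assert report.chosen.name == "w+x+y"
        # report is sorted by PPV desc then simplicity
        ppvs = [c.ppv_value for c in report.candidates if c.ppv_value is not None]
        assert ppvs == sorted(ppvs, reverse=True)

    def test_single_candidate_chosen_trivially(self):
        bundle, pool, reference = self.build_selection_bundle()
        only = enumerate_algorithms(pool[:2], 2, 2)
        report = select_algorithm(only, bundle, reference, INDEX_DATE)
        assert report.chosen.name == only[0].name

    def test_invariant_to_candidate_order(self):
        bundle, pool, reference = self.build_selection_bundle()
        candidates = enumerate_algorithms(pool, 2, 4)
        base = select_algorithm(candidates, bundle, reference, INDEX_DATE)
        rng = random.Random(5)
        for _ in range(5):
            shuffled = candidates[:]
            rng.shuffle(shuffled)
            rep = select_algorithm(shuffled, bundle, reference, INDEX_DATE)
            assert [c.name for c in rep.candidates] == [c.name for c in base.candidates]
            assert rep.chosen.name == base.chosen.name

    def test_inert_criterion_changes_nothing(self):
        # z alone never fires, so x+z identifies exactly x's set
        bundle, pool, reference = self.build_selection_bundle()
        report = select_algorithm(
            enumerate_algorithms(pool, 2, 2), bundle, reference, INDEX_DATE
        )
        xz = next(c for c in report.candidates if c.name == "x+z")
        assert xz.n_identified == 2  # P3, P4 via x

    def test_empty_candidate_has_undefined_ppv_and_ranks_last(self):
        bundle, pool, reference = self.build_selection_bundle()
        empty = CaseAlgorithm("z+z2", (pool[3],))  # matches nobody
        candidates = enumerate_algorithms(pool[:3], 2, 3) + [empty]
        report = select_algorithm(candidates, bundle, reference, INDEX_DATE)
        assert report.candidates[-1].name == "z+z2"
        assert report.candidates[-1].ppv is None
        assert report.chosen.name != "z+z2"

    def test_unknown_reference_ids_rejected(self):
        bundle, pool, _ = self.build_selection_bundle()
        with pytest.raises(ValueError):
            select_algorithm(enumerate_algorithms(pool, 2, 2), bundle, ["NOPE"], INDEX_DATE)


class TestPatternCounts:
    def test_all_single_criterion_cohort(self):
        b = RegistryBundle.from_records(
            [person(f"P{i}") for i in range(5)],
            redemptions=[
                r for i in range(5)
                for r in (PrescriptionRedemption(f"P{i}", days_before(30), "R03AC02"),
                          PrescriptionRedemption(f"P{i}", days_before(60), "R03AC02"))
            ],
        )
        counts = criteria_pattern_counts(identify_cohort(b, DEFAULT_ALGORITHM, INDEX_DATE))
        assert counts["b"] == 5 and counts.sum() == 5
        single = counts[["a", "b", "c"]].sum()
        assert single / counts.sum() == 1.0

    def test_planted_patterns_match_hand_tally(self):
        rng = random.Random(303)
        b = random_bundle(rng, max_persons=40)
        cohort = identify_cohort(b, DEFAULT_ALGORITHM, INDEX_DATE)
        counts = criteria_pattern_counts(cohort)
        # hand tally from the brute-force oracle
        expected = {}
        for pid, res in bf_identify(b, DEFAULT_ALGORITHM, INDEX_DATE).items():
            if not res["identified"]:
                continue
            key = "".join(lab for lab in "abc" if res["flags"][lab])
            expected[key] = expected.get(key, 0) + 1
        assert {k: v for k, v in counts.items() if v} == expected
        assert counts.sum() == cohort.n_identified
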