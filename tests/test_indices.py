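"""Consensus factor and fidelity level, against an independent oracle."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from ethnoquant import (
    SurveyTable,
    UseRecord,
    audit_printed_fl,
    compute_fl,
    compute_icf,
    fl_100_census,
)
from ethnoquant.indices import round_half_away

from conftest import oracle_fl, oracle_icf, random_table


def single_species_table(disorder="a", name="Alpha primus Auth.", mentions=5):
    return SurveyTable(
        records=[
            UseRecord(
                disorder=disorder,
                scientific_name=name,
                mentions=mentions,
                kind="plant",
                used_parts=frozenset({"leaf"}),
                preparations=frozenset({"tea"}),
            )
        ],
        name_aliases={},
    )


class TestRounding:
    @pytest.mark.parametrize(
        "value, ndigits, expected",
        [
            (Fraction(6, 7), 2, 0.86),       # 0.857...
            (Fraction(1, 8), 2, 0.13),       # ties go away from zero
            (Fraction(466, 490), 2, 0.95),
            (Fraction(400, 39), 1, 10.3),
            (Fraction(171, 200), 2, 0.86),   # 0.855 exactly at the tie
        ],
    )
    def test_half_away_from_zero(self, value, ndigits, expected):
        assert round_half_away(value, ndigits) == expected


class TestICF:
    def test_fixture_display_values(self, survey):
        got = {dc.disorder: dc.icf for dc in compute_icf(survey)}
        assert got == {
            "Jaundice": 0.95,
            "Liver-related ailments": 0.93,
            "Fatigue recovery": 0.93,
            "Hepatitis": 0.87,
            "Hangover": 0.86,
            "Liver cancer": 0.61,
            "Liver cirrhosis": 0.61,
        }

    def test_fixture_bookkeeping(self, survey):
        by = {dc.disorder: dc for dc in compute_icf(survey)}
        assert (by["Jaundice"].n_ur, by["Jaundice"].n_t) == (491, 25)
        assert (by["Hangover"].n_ur, by["Hangover"].n_t) == (8, 2)
        assert by["Hangover"].icf_exact == Fraction(6, 7)

    def test_single_report_is_undefined(self):
        table = single_species_table(mentions=1)
        (dc,) = compute_icf(table)
        assert not dc.defined and dc.icf is None

    def test_zero_when_every_report_cites_a_different_species(self):
        records = [
            UseRecord(
                disorder="a",
                scientific_name=f"Taxon unicus {i:02d} Test.",
                mentions=1,
                kind="plant",
                used_parts=frozenset({"leaf"}),
                preparations=frozenset({"tea"}),
            )
            for i in range(5)
        ]
        (dc,) = compute_icf(SurveyTable(records=records, name_aliases={}))
        assert dc.n_ur == dc.n_t == 5 and dc.icf_exact == 0

    def test_one_when_single_species(self):
        (dc,) = compute_icf(single_species_table(mentions=7))
        assert dc.icf_exact == 1

    def test_empty_table(self):
        assert compute_icf(SurveyTable(records=[], name_aliases={})) == []


class TestFL:
    @pytest.mark.parametrize(
        "name, disorder, n_p, n_total, display",
        [
            ("Oenanthe javanica (Blume) DC.", "Hangover", 4, 39, 10.3),
            ("Sedum sarmentosum Bunge", "Liver-related ailments", 62, 80, 77.5),
            ("Protaetia brevitarsis seulensis (Kolbe)", "Hepatitis", 10, 46, 21.7),
            ("Hovenia dulcis Thunb.", "Hangover", 4, 125, 3.2),
            ("Taraxacum platycarpum Dahlst.", "Liver-related ailments", 192, 192, 100.0),
        ],
    )
    def test_fixture_examples(self, survey, name, disorder, n_p, n_total, display):
        by = {(f.scientific_name, f.disorder): f for f in compute_fl(survey)}
        f = by[(name, disorder)]
        assert (f.n_p, f.n_total) == (n_p, n_total)
        assert f.fl == display

    def test_single_disorder_species_is_100(self):
        (f,) = compute_fl(single_species_table())
        assert f.fl_exact == 100 and f.is_exclusive

    def test_conservation_on_fixture(self, survey):
        per_species: dict[str, Fraction] = {}
        for f in compute_fl(survey):
            per_species[f.scientific_name] = (
                per_species.get(f.scientific_name, Fraction(0))
                + Fraction(f.n_p, f.n_total)
            )
        assert all(total == 1 for total in per_species.values())


class TestCensus:
    def test_fixture_counts(self, survey):
        census = fl_100_census(compute_fl(survey))
        assert census.per_disorder["Liver-related ailments"] == 43
        assert census.per_disorder["Jaundice"] == 16

    def test_census_is_on_exact_values(self, survey):
        # Plantago asiatica prints 100.0 for both hepatitis and jaundice,
        # which cannot hold; its exact FL is 50 in each and it must not
        # be censused.
        census = fl_100_census(compute_fl(survey))
        exclusive = [
            f.scientific_name for f in compute_fl(survey) if f.is_exclusive
        ]
        assert "Plantago asiatica L." not in exclusive
        assert census.total == sum(census.per_disorder.values())

    def test_single_record_counts_one(self):
        census = fl_100_census(compute_fl(single_species_table()))
        assert census.per_disorder == {"a": 1} and census.total == 1


class TestAudit:
    def test_flags_impossible_printed_values(self, survey):
        flagged = audit_printed_fl(survey, tolerance=0.05)
        assert {(d.scientific_name, d.disorder) for d in flagged} == {
            ("Plantago asiatica L.", "Hepatitis"),
            ("Plantago asiatica L.", "Jaundice"),
        }
        assert all(d.printed == 100.0 and d.recomputed == 50.0 for d in flagged)

    def test_huge_tolerance_swallows_everything(self, survey):
        assert audit_printed_fl(survey, tolerance=100) == []

    def test_self_consistent_printed_column_is_clean(self, survey):
        fls = {(f.disorder, f.scientific_name): f.fl for f in compute_fl(survey)}
        records = [
            UseRecord(
                disorder=rec.disorder,
                scientific_name=rec.scientific_name,
                mentions=rec.mentions,
                kind=rec.kind,
                used_parts=rec.used_parts,
                preparations=rec.preparations,
                application=rec.application,
                local_name=rec.local_name,
                fl_printed=fls[(rec.disorder, rec.scientific_name)],
            )
            for rec in survey.records
        ]
        clean = SurveyTable(records=records, name_aliases=dict(survey.name_aliases))
        assert audit_printed_fl(clean, tolerance=0.05) == []


class TestOracleEquivalence:
    """Both indices agree with per-report enumeration on random tables."""

    def test_random_tables(self):
        rng = np.random.default_rng(20130908)
        for _ in range(50):
            table = random_table(rng)
            expected_icf = oracle_icf(table)
            for dc in compute_icf(table):
                assert dc.icf_exact == expected_icf[dc.disorder]
            expected_fl = oracle_fl(table)
            for f in compute_fl(table):
                assert f.fl_exact == expected_fl[(f.scientific_name, f.disorder)]

    def test_icf_bounds_and_endpoints(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            table = random_table(rng)
            for dc in compute_icf(table):
                assert dc.n_t <= dc.n_ur
                if dc.defined:
                    assert 0 <= dc.icf_exact <= 1
                    assert (dc.icf_exact == 0) == (dc.n_ur == dc.n_t)
                    assert (dc.icf_exact == 1) == (dc.n_t == 1)
                else:
                    assert dc.n_ur == 1

    def test_fl_conservation_random(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            table = random_table(rng)
            totals: dict[str, Fraction] = {}
            for f in compute_fl(table):
                assert 1 <= f.n_p <= f.n_total
                totals[f.scientific_name] = (
                    totals.get(f.scientific_name, Fraction(0))
                    + Fraction(f.n_p, f.n_total)
                )
            assert all(v == 1 for v in totals.values())
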