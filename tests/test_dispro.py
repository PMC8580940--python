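"""Contingency construction and the IC / PRR statistics.

Worked-example values are frozen from independent evaluation of the
closed forms:

* PRR for (a,b,c,d) = (10,90,10,990): point 10 exactly since
  (10/100)/(10/1000); se² = 1/10 − 1/100 + 1/10 − 1/1000 = 0.189,
  bounds exp(ln 10 ∓ 1.959964·√0.189) = (4.2652798…, 23.4451205…).
* IC for O = 14, E = 0.5 (margins (14,0,0,378)):
  IC = log2(14.5/1.0) = 3.8579809…, penalty 3.3/√14.5 + 2/14.5^1.5,
  IC025 = 2.9551360….
"""

import math
import random

import pytest

from pvsignal import (
    ContingencyTable,
    GeneratorConfig,
    IntegrityError,
    ReactionEntry,
    SignalSpec,
    analyze_stratum,
    build_tables,
    default_pt_vocabulary,
    generate,
    ic_with_credibility,
    prr_with_ci,
    select_cases,
    SelectionCriteria,
    split_arms,
)
from conftest import make_report


def table(a, b, c, d, pt="pt", stratum="all"):
    return ContingencyTable(pt=pt, stratum=stratum, a=a, b=b, c=c, d=d)


class TestBuildTables:
    def test_direct_counts(self, report_factory):
        target = [report_factory("T1"), report_factory("T2")]
        comparator = [
            report_factory(f"C{i}", reactions=[ReactionEntry("nausea")])
            for i in range(3)
        ]
        tables = build_tables(target, comparator)
        by_pt = {t.pt: t for t in tables}
        assert (by_pt["atrial fibrillation"].a, by_pt["atrial fibrillation"].b,
                by_pt["atrial fibrillation"].c, by_pt["atrial fibrillation"].d) == (2, 0, 0, 3)
        assert (by_pt["nausea"].a, by_pt["nausea"].c) == (0, 3)

    def test_duplicate_pt_on_one_report_counts_once(self, report_factory):
        twice = [ReactionEntry("rash"), ReactionEntry("rash", "skin")]
        target = [report_factory("T1", reactions=twice)]
        comparator = [report_factory("C1", reactions=[ReactionEntry("nausea")])]
        by_pt = {t.pt: t for t in build_tables(target, comparator)}
        assert by_pt["rash"].a == 1

    def test_empty_stratum_gives_empty_list(self, report_factory):
        target = [report_factory("T1", age=80.0)]
        comparator = [report_factory("C1", age=82.0)]
        assert build_tables(target, comparator, stratum="under_75") == []

    def test_overlapping_arms_rejected(self, report_factory):
        shared = report_factory("X1")
        with pytest.raises(IntegrityError, match="X1"):
            build_tables([shared], [shared])

    def test_margins_constant_across_pts(self):
        db = generate(GeneratorConfig(n_reports=2000, seed=12, missing_age_rate=0.0))
        target, comparator = split_arms(db)
        tables = build_tables(target, comparator, stratum="under_75")
        assert len({t.a + t.b for t in tables}) == 1
        assert len({t.c + t.d for t in tables}) == 1

    def test_all_stratum_cells_are_sum_of_age_strata(self):
        db = generate(GeneratorConfig(n_reports=2000, seed=14, missing_age_rate=0.0))
        target, comparator = split_arms(db)
        pts = sorted({pt for r in db for pt in r.pt_set()})
        under = {t.pt: t for t in build_tables(target, comparator, "under_75", pts)}
        over = {t.pt: t for t in build_tables(target, comparator, "at_least_75", pts)}
        both = {t.pt: t for t in build_tables(target, comparator, "all", pts)}
        for pt in pts:
            if pt == "no adverse event":
                continue
            for cell in "abcd":
                assert getattr(both[pt], cell) == getattr(under[pt], cell) + getattr(
                    over[pt], cell
                )


class TestPrr:
    def test_point_estimate(self):
        prr, _low, _high = prr_with_ci(table(10, 90, 10, 990))
        assert prr == pytest.approx(10.0, abs=1e-12)

    def test_confidence_interval_frozen_values(self):
        _prr, low, high = prr_with_ci(table(10, 90, 10, 990))
        assert low == pytest.approx(4.26527983609159, abs=1e-9)
        assert high == pytest.approx(23.445120564852118, abs=1e-9)

    @pytest.mark.parametrize("cells", [(0, 100, 10, 990), (10, 90, 0, 1000)])
    def test_zero_cell_not_estimable(self, cells):
        assert prr_with_ci(table(*cells)) is None

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            prr_with_ci(table(0, 0, 10, 90))

    def test_monotone_in_a_with_fixed_margins(self):
        """For fixed a+b, c and d, a larger a gives a larger PRR."""
        previous = 0.0
        for a in range(1, 100):
            prr, _lo, _hi = prr_with_ci(table(a, 100 - a, 10, 990))
            assert prr > previous
            previous = prr


class TestIc:
    def test_observed_equals_expected_gives_zero(self):
        # margins (20,80,180,720): E = 100*200/1000 = 20 = a
        ic, ic025, expected = ic_with_credibility(table(20, 80, 180, 720))
        assert expected == pytest.approx(20.0)
        assert ic == pytest.approx(0.0, abs=1e-12)
        assert ic025 < 0

    def test_zero_observed_zero_expected_gives_zero(self):
        ic, _ic025, expected = ic_with_credibility(table(0, 100, 0, 900))
        assert expected == pytest.approx(0.0)
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_frozen_worked_example(self):
        # margins (14,0,0,378): E = 14*14/392 = 0.5 exactly
        ic, ic025, expected = ic_with_credibility(table(14, 0, 0, 378))
        assert expected == pytest.approx(0.5, abs=1e-12)
        assert ic == pytest.approx(3.8579809951275723, abs=1e-9)
        assert ic025 == pytest.approx(2.955136074016239, abs=1e-9)

    def test_credibility_bound_below_point(self):
        for a, b, c, d in [(1, 9, 1, 9), (50, 50, 50, 50), (0, 10, 5, 85)]:
            ic, ic025, _e = ic_with_credibility(table(a, b, c, d))
            assert ic025 < ic

    def test_monotone_in_a_with_fixed_margins(self):
        values = [
            ic_with_credibility(table(a, 100 - a, 50, 850))[0] for a in range(0, 101)
        ]
        assert all(later > earlier for earlier, later in zip(values, values[1:]))

    def test_shrinkage_vanishes_for_large_counts(self):
        """With O and E large at fixed ratio, IC approaches log2(O/E)."""
        ic, _ic025, expected = ic_with_credibility(table(4000, 6000, 16000, 74000))
        assert expected == pytest.approx(2000.0, rel=1e-9)
        assert ic == pytest.approx(1.0, abs=1e-3)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            table(-1, 10, 10, 10)


class TestAnalyzeStratum:
    def test_report_order_invariance(self):
        db = generate(GeneratorConfig(n_reports=1500, seed=15, missing_age_rate=0.0))
        target, comparator = split_arms(db)
        forward = analyze_stratum(target, comparator, "all")
        backward = analyze_stratum(list(reversed(target)), list(reversed(comparator)), "all")
        assert forward == backward

    def test_results_sorted_by_pt(self):
        db = generate(GeneratorConfig(n_reports=800, seed=16, missing_age_rate=0.0))
        target, comparator = split_arms(db)
        results = analyze_stratum(target, comparator, "all")
        assert [r.pt for r in results] == sorted(r.pt for r in results)

    def test_pt_universe_yields_zero_count_row(self, report_factory):
        target = [report_factory("T1")]
        comparator = [report_factory("C1", reactions=[ReactionEntry("nausea")])]
        results = analyze_stratum(
            target, comparator, "all", pt_universe=["absent event"]
        )
        (row,) = results
        assert row.n_obs == 0
        assert math.isfinite(row.ic)
        assert row.prr is None

    def test_injected_pair_has_maximum_ic_in_its_stratum(self):
        """A strong injected association should out-rank every baseline
        pair, per the generator's ground truth."""
        vocabulary = default_pt_vocabulary()
        pt, _soc, _b = min(vocabulary, key=lambda row: abs(row[2] - 5e-4))
        config = GeneratorConfig(
            n_reports=50_000,
            seed=19,
            signals=[SignalSpec("ibrutinib", pt, 10.0)],
        )
        included = select_cases(generate(config), SelectionCriteria()).included
        target, comparator = split_arms(included)
        results = analyze_stratum(target, comparator, "all")
        best = max(results, key=lambda r: r.ic)
        assert best.pt == pt


class TestBruteForceEquivalence:
    def test_statistics_match_raw_recount_on_random_databases(self):
        """IC and PRR from the module equal a from-scratch recount of the
        raw report lists (no contingency shortcut) on small databases."""
        z = 1.959964
        for seed in range(8):
            config = GeneratorConfig(
                n_reports=300,
                seed=seed,
                pt_vocabulary=default_pt_vocabulary(n_pts=25),
                missing_age_rate=0.0,
                no_adverse_event_rate=0.02,
            )
            db = generate(config)
            target, comparator = split_arms(db)
            for stratum in ("under_75", "at_least_75", "all"):
                results = analyze_stratum(target, comparator, stratum)
                if stratum == "under_75":
                    t_in = [r for r in target if r.age_years < 75]
                    c_in = [r for r in comparator if r.age_years < 75]
                elif stratum == "at_least_75":
                    t_in = [r for r in target if r.age_years >= 75]
                    c_in = [r for r in comparator if r.age_years >= 75]
                else:
                    t_in, c_in = list(target), list(comparator)
                for row in results:
                    a = sum(1 for r in t_in if row.pt in {x.pt for x in r.reactions})
                    c = sum(1 for r in c_in if row.pt in {x.pt for x in r.reactions})
                    b, d = len(t_in) - a, len(c_in) - c
                    n_total = a + b + c + d
                    expected = (a + b) * (a + c) / n_total
                    ic = math.log2((a + 0.5) / (expected + 0.5))
                    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2 * (a + 0.5) ** -1.5
                    assert row.n_obs == a
                    assert row.expected == pytest.approx(expected, abs=1e-9)
                    assert row.ic == pytest.approx(ic, abs=1e-9)
                    assert row.ic025 == pytest.approx(ic025, abs=1e-9)
                    if a == 0 or c == 0:
                        assert row.prr is None
                    else:
                        prr = (a / (a + b)) / (c / (c + d))
                        se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
                        assert row.prr == pytest.approx(prr, abs=1e-9)
                        assert row.prr_low == pytest.approx(
                            math.exp(math.log(prr) - z * se), abs=1e-9
                        )
                        assert row.prr_high == pytest.approx(
                            math.exp(math.log(prr) + z * se), abs=1e-9
                        )
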