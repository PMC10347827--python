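"""Recategorization events, variant-months accounting, and rate comparisons."""
import datetime as dt

import numpy as np
import pytest

from oracle_utils import fisher_2x2_oracle
from varaudit import (
    VariantKey,
    compare_ancestry_rates,
    downsample_monthly,
    extract_events,
    first_last_transition,
    reclass_rate,
    variant_months,
)
from varaudit.core import CLINVAR_LADDER, HGMD_LADDER, ladder_index
from varaudit.recat import MonthlySeries, monthly_series
from varaudit.ingest import ClassificationTimeline, SnapshotEntry

D = dt.date
KEY = VariantKey("chr1", 1100, "A", "G")


def series(points, database="clinvar"):
    return MonthlySeries(KEY, database, tuple(points))


class TestDownsampling:
    def test_weekly_snapshots_collapse_to_last_of_month(self):
        dates = [D(2019, 3, 2), D(2019, 3, 9), D(2019, 3, 16), D(2019, 3, 30)]
        assert downsample_monthly(dates) == [D(2019, 3, 30)]
        assert downsample_monthly(dates, "first") == [D(2019, 3, 2)]

    def test_already_monthly_is_unchanged(self):
        dates = [D(2019, 1, 15), D(2019, 2, 15), D(2019, 4, 15)]
        assert downsample_monthly(dates) == dates  # month gap preserved

    def test_nearest_to_month_end(self):
        dates = [D(2019, 3, 2), D(2019, 3, 20)]
        assert downsample_monthly(dates, "nearest-to-month-end") == [D(2019, 3, 20)]

    def test_empty_input(self):
        assert downsample_monthly([]) == []


class TestEvents:
    def test_constant_category_yields_no_event(self):
        s = series([(D(2019, 1, 15), "P/LP 1*"), (D(2019, 2, 15), "P/LP 1*")])
        assert extract_events(s) == []

    def test_star_gain_is_recategorization_not_reclassification(self):
        s = series([(D(2019, 1, 15), "P/LP 1*"), (D(2019, 2, 15), "P/LP 2*")])
        (e,) = extract_events(s)
        assert e.direction == "toward_pathogenic"
        assert not e.is_reclassification
        assert e.confidence_change == "neither"

    def test_plp_to_conflicting_is_decreasing_reclassification(self):
        s = series([(D(2019, 1, 15), "P/LP 1*"), (D(2019, 2, 15), "Conflicting")])
        (e,) = extract_events(s)
        assert e.is_reclassification
        assert e.confidence_change == "decreasing"
        assert e.direction == "toward_benign"

    def test_vus_to_blb_is_increasing(self):
        s = series([(D(2019, 1, 15), "VUS"), (D(2019, 2, 15), "B/LB 2*")])
        (e,) = extract_events(s)
        assert e.confidence_change == "increasing"

    def test_removal_emits_nothing_reentry_under_new_category_emits_one(self):
        s = series([(D(2019, 1, 15), "P/LP 1*"),
                    # removed for two months, re-enters as VUS
                    (D(2019, 4, 15), "VUS")])
        (e,) = extract_events(s)
        assert (e.from_category, e.to_category) == ("P/LP 1*", "VUS")
        assert e.confidence_change == "decreasing"
        assert e.date == D(2019, 4, 15)

    def test_reentry_under_same_category_is_not_an_event(self):
        s = series([(D(2019, 1, 15), "P/LP 1*"), (D(2019, 4, 15), "P/LP 1*")])
        assert extract_events(s) == []

    def test_pre_cutover_clinvar_changes_not_considered(self):
        s = series([(D(2015, 1, 15), "P/LP 1*"), (D(2015, 5, 15), "VUS"),
                    (D(2015, 7, 15), "Conflicting")])
        events = extract_events(s)
        assert [(e.from_category, e.to_category) for e in events] \
            == [("VUS", "Conflicting")]

    def test_hgmd_every_change_is_reclassification(self):
        s = series([(D(2016, 3, 1), "DM"), (D(2018, 3, 1), "DM?")],
                   database="hgmd")
        (e,) = extract_events(s)
        assert e.is_reclassification
        assert e.direction == "toward_benign"

    def test_hgmd_absence_becomes_retired(self):
        tl = ClassificationTimeline(KEY, "hgmd")
        tl.add(D(2016, 3, 1), SnapshotEntry(clazz="DM"))
        grid = [D(2016, 3, 1), D(2018, 3, 1), D(2020, 3, 1)]
        s = monthly_series(tl, grid)
        assert s.points == ((D(2016, 3, 1), "DM"), (D(2018, 3, 1), "R"),
                            (D(2020, 3, 1), "R"))
        (e,) = extract_events(s)
        assert (e.from_category, e.to_category) == ("DM", "R")

    def test_direction_matches_ladder_index_sign(self):
        """Property over random category paths on both ladders."""
        rng = np.random.default_rng(5)
        for database, ladder in (("clinvar", CLINVAR_LADDER), ("hgmd", HGMD_LADDER)):
            labels = [ladder[i] for i in rng.integers(0, len(ladder), size=60)]
            points = [(D(2016, 1, 1) + dt.timedelta(days=31 * i), lab)
                      for i, lab in enumerate(labels)]
            months = downsample_monthly([p[0] for p in points])
            pts = [p for p in points if p[0] in months]
            for e in extract_events(series(pts, database)):
                sign = ladder_index(e.to_category, database) \
                    - ladder_index(e.from_category, database)
                assert (e.direction == "toward_pathogenic") == (sign > 0)

    def test_first_last_collapses_multihop_paths(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            labels = [CLINVAR_LADDER[i]
                      for i in rng.integers(0, 10, size=rng.integers(1, 8))]
            pts = [(D(2016, 1 + i, 15), lab) for i, lab in enumerate(labels)]
            s = series(pts)
            first, last = first_last_transition(s)
            assert first == labels[0] and last == labels[-1]
            n_collapsed = 0 if first == last else 1
            assert n_collapsed <= len(extract_events(s))


class TestVariantMonths:
    WINDOW = (D(2016, 1, 1), D(2020, 12, 31))

    def test_defining_example(self):
        s1 = series([(D(2019, 1, 15), "P/LP 1*")], )
        s2 = MonthlySeries(VariantKey("chr1", 1200, "C", "T"), "clinvar",
                           ((D(2019, 1, 15), "P/LP 1*"),))
        two_for_one_month = variant_months([s1, s2], {"P/LP 1*"}, self.WINDOW)
        one_for_two_months = variant_months(
            [series([(D(2019, 1, 15), "P/LP 1*"), (D(2019, 2, 15), "P/LP 1*")])],
            {"P/LP 1*"}, self.WINDOW)
        assert two_for_one_month == one_for_two_months == 2

    def test_empty_filter_and_window_edges(self):
        s = series([(D(2019, 1, 15), "VUS")])
        assert variant_months([s], set(), self.WINDOW) == 0
        assert variant_months([s], {"VUS"}, (D(2019, 2, 1), D(2019, 3, 1))) == 0

    def test_partition_conservation(self):
        """Summing variant-months over a partition of all categories equals
        the total classified variant-months."""
        rng = np.random.default_rng(23)
        serieses = []
        for i in range(40):
            labels = [CLINVAR_LADDER[j]
                      for j in rng.integers(0, 10, size=rng.integers(1, 10))]
            pts = [(D(2016, 1 + k % 12, 15) + dt.timedelta(days=365 * (k // 12)),
                    lab) for k, lab in enumerate(labels)]
            serieses.append(
                MonthlySeries(VariantKey("chr1", 2000 + i, "A", "G"),
                              "clinvar", tuple(pts)))
        total = variant_months(serieses, set(CLINVAR_LADDER), self.WINDOW)
        parts = [{"P/LP 0*", "P/LP 1*", "P/LP 2*", "P/LP 3*"},
                 {"VUS", "Conflicting"},
                 {"B/LB 0*", "B/LB 1*", "B/LB 2*", "B/LB 3*"}]
        assert sum(variant_months(serieses, p, self.WINDOW) for p in parts) == total


class TestRates:
    def test_zero_events(self):
        r = reclass_rate(0, 1000)
        assert (r.rate, r.ci_low, r.ci_high) == (0.0, 0.0, 0.0)

    def test_wald_formula(self):
        r = reclass_rate(5, 1000)
        import math
        half = 1.96 * math.sqrt(0.005 * 0.995 / 1000)
        assert r.rate == pytest.approx(0.005)
        assert r.ci_low == pytest.approx(0.005 - half)
        assert r.ci_high == pytest.approx(0.005 + half)

    def test_doubling_preserves_rate_and_narrows_ci(self):
        r1, r2 = reclass_rate(5, 1000), reclass_rate(10, 2000)
        assert r1.rate == r2.rate
        assert (r2.ci_high - r2.ci_low) < (r1.ci_high - r1.ci_low)

    def test_zero_exposure_is_undefined(self):
        import math
        assert math.isnan(reclass_rate(3, 0).rate)


class TestAncestryComparison:
    def test_null_rates_not_significant(self):
        events = {a: 10 for a in ("AFR", "AMR", "EAS", "EUR", "SAS")}
        vm = {a: 5000 for a in events}
        cmp = compare_ancestry_rates(events, vm)
        assert cmp.omnibus.p_value > 0.5
        assert all(p > 0.05 for _, _, p in cmp.pairwise)

    def test_planted_twofold_elevation_detected(self):
        events = {"AFR": 40, "AMR": 40, "EAS": 40, "EUR": 80, "SAS": 40}
        vm = {a: 10000 for a in events}
        cmp = compare_ancestry_rates(events, vm)
        assert cmp.omnibus.p_value < 2.2e-4
        sig = {(a, b) for a, b, p in cmp.pairwise if p < 2.2e-4}
        assert sig == {("EUR", a) for a in ("AFR", "AMR", "EAS", "SAS")}

    def test_pairwise_table_matches_hypergeometric_oracle(self):
        events = {"AFR": 3, "EUR": 8}
        vm = {"AFR": 40, "EUR": 35}
        cmp = compare_ancestry_rates(events, vm)
        p = dict(((a, b), p) for a, b, p in cmp.pairwise)
        assert p[("EUR", "AFR")] == pytest.approx(
            fisher_2x2_oracle([[8, 35], [3, 40]], "greater"), rel=1e-9)

    def test_zero_exposure_ancestry_excluded(self):
        cmp = compare_ancestry_rates({"AFR": 1, "EUR": 1},
                                     {"AFR": 100, "EUR": 100, "EAS": 0})
        assert {a for a, _ in cmp.rates} == {"AFR", "EUR"}
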