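"""Featurization: calendars, weekly matrices, clustering, facility
regrouping, window extraction, phi/age scaling, labeling, rebalancing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attendcast.features import (FacilityCatalog, ScalingConfig, WeekCalendar,
                                 build_weekly_matrices, cluster_provisions,
                                 collapse_columns, extract_windows,
                                 label_window, provision_features,
                                 rank_facilities, rebalance_windows,
                                 scale_age, scale_phi)
from conftest import make_bookings, make_history


class TestWeekCalendar:
    def test_week_count_by_ceil(self):
        assert WeekCalendar("2014-01-01", "2014-01-07").n_weeks == 1
        assert WeekCalendar("2014-01-01", "2014-01-08").n_weeks == 2
        # five civil years = 1826 days -> 261 weeks
        assert WeekCalendar("2014-01-01", "2018-12-31").n_weeks == 261

    def test_week_index_day_eight_is_week_two(self, calendar):
        assert calendar.week_index(["2014-01-08"])[0] == 2
        assert calendar.week_index(["2014-01-01"])[0] == 1
        assert calendar.week_index(["2014-01-07"])[0] == 1

    def test_out_of_period_date_rejected(self, calendar):
        with pytest.raises(ValueError, match="outside calendar"):
            calendar.week_index(["2013-12-31"])


class TestWeeklyMatrices:
    def test_single_appointment_placement(self, calendar):
        df = make_bookings([("p", 0, 40, "2014-01-01", "2014-01-01",
                             "Valid", "f1", "v1")])
        hists, provs, facs = build_weekly_matrices(df, calendar)
        h = hists["p"]
        assert h.P_full[0, provs.index("v1")] == 1
        assert h.F_full[0, facs.index("f1")] == 1
        assert h.P_full.sum() == h.F_full.sum() == 1

    def test_same_week_two_provisions(self, calendar):
        df = make_bookings([
            ("p", 0, 40, "2014-01-01", "2014-01-02", "Valid", "f1", "v1"),
            ("p", 0, 40, "2014-01-01", "2014-01-03", "Valid", "f1", "v2")])
        hists, provs, facs = build_weekly_matrices(df, calendar)
        h = hists["p"]
        assert h.F_full[0].sum() == 2
        assert h.P_full[0, provs.index("v1")] == 1
        assert h.P_full[0, provs.index("v2")] == 1

    def test_counts_conserved_per_patient(self, calendar):
        rng = np.random.default_rng(5)
        days = rng.integers(0, 1000, size=30)
        df = make_bookings([
            ("p", 0, 40, "2014-01-01",
             (pd.Timestamp("2014-01-01") + pd.Timedelta(int(d), "D"))
             .strftime("%Y-%m-%d"), "Valid", f"f{d % 3}", f"v{d % 5}")
            for d in days])
        hists, _, _ = build_weekly_matrices(df, calendar)
        assert hists["p"].P_full.sum() == 30
        assert hists["p"].F_full.sum() == 30


class TestProvisionClustering:
    def test_identical_patterns_identical_features(self, calendar):
        rows = []
        for prov in ("a", "b"):
            rows += [("p1", 0, 40, "2014-01-01", "2014-01-05", "Valid",
                      "f1", prov),
                     ("p2", 1, 60, "2014-02-01", "2014-02-05", "Valid",
                      "f1", prov)]
        feats = provision_features(make_bookings(rows), calendar)
        np.testing.assert_allclose(feats.loc["a"], feats.loc["b"])

    def test_k_equals_n_gives_singletons(self, calendar):
        rows = [("p", 0, 30 + 10 * i, "2014-01-01",
                 f"2014-0{i+1}-05", "Valid", "f", f"v{i}") for i in range(4)]
        feats = provision_features(make_bookings(rows), calendar)
        clus = cluster_provisions(feats, k=4, seed=0)
        assert sorted(clus.assignment.values()) == [1, 2, 3, 4]

    def test_k_above_n_rejected(self, calendar):
        rows = [("p", 0, 40, "2014-01-01", "2014-01-05", "Valid", "f", "v")]
        feats = provision_features(make_bookings(rows), calendar)
        with pytest.raises(ValueError):
            cluster_provisions(feats, k=2)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.05, (10, 3)),
                       rng.normal(8, 0.05, (12, 3))])
        feats = pd.DataFrame(X, index=[f"v{i}" for i in range(22)])
        clus = cluster_provisions(feats, k=2, seed=1)
        labels = np.array([clus.assignment[f"v{i}"] for i in range(22)])
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, (8, 2)),
                       rng.normal(5, 0.1, (8, 2))])
        idx = [f"v{i}" for i in range(16)]
        feats = pd.DataFrame(X, index=idx)
        a = cluster_provisions(feats, k=2, seed=3).assignment
        perm = np.random.default_rng(4).permutation(16)
        b = cluster_provisions(feats.iloc[perm], k=2, seed=3).assignment
        same_a = {(a[i] == a[j]) for i in idx for j in idx}
        for i in idx:
            for j in idx:
                assert (a[i] == a[j]) == (b[i] == b[j])


class TestRankFacilities:
    def _totals(self, n, start=100):
        return pd.Series({f"f{i:02d}": start - i for i in range(n)})

    def test_rank_and_district_columns(self):
        totals = self._totals(12)
        district_of = {f"f{i:02d}": f"d{i % 8}" for i in range(12)}
        cat = rank_facilities(totals, district_of)
        assert cat.top_facilities == [f"f{i:02d}" for i in range(10)]
        assert [cat.column_of[f] for f in cat.top_facilities] == \
            list(range(1, 11))
        assert cat.n_district_groups == 8 and cat.n_columns == 19
        # f10 is in district d2, one of the top-10 districts -> group column
        assert 11 <= cat.column_of["f10"] <= 18

    def test_tie_broken_by_lexicographic_id(self):
        totals = pd.Series({"fb": 5, "fa": 5, **{f"x{i}": 4 - 0 for i in
                                                 range(10)}})
        totals[[f"x{i}" for i in range(10)]] = 3
        cat = rank_facilities(totals, {f: "d0" for f in totals.index})
        assert cat.top_facilities[0] == "fa" and cat.top_facilities[1] == "fb"

    def test_foreign_district_goes_to_rest_column(self):
        totals = self._totals(13)
        district_of = {f"f{i:02d}": f"d{i}" for i in range(10)}
        district_of["f10"] = "d3"       # top district
        district_of["f11"] = "elsewhere"
        district_of["f12"] = "d0"
        cat = rank_facilities(totals, district_of)
        assert cat.n_district_groups == 10  # ten distinct top districts
        assert cat.column_of["f11"] == cat.n_columns  # rest-of-universe

    def test_fewer_than_eight_districts_shrinks_layout(self):
        totals = self._totals(14)
        cat = rank_facilities(totals, {f: "d0" for f in totals.index})
        assert cat.n_district_groups == 1
        assert cat.n_columns == 12


def brute_force_windows(weekly_totals, window_len=52, horizon=9,
                        min_active=4):
    """Independent per-start-week checker used as the extraction oracle."""
    T = len(weekly_totals)
    kept = []
    for w in range(1, T - window_len - horizon + 2):
        hist = weekly_totals[w - 1: w - 1 + window_len]
        fut = weekly_totals[w - 1 + window_len: w - 1 + window_len + horizon]
        if (np.asarray(hist) > 0).sum() >= min_active and sum(fut) >= 1:
            kept.append(w)
    return kept


class TestExtractWindows:
    def test_hand_worked_example(self):
        h = make_history([1, 10, 20, 30, 55], T=70)
        starts = extract_windows(h)
        assert 1 in starts      # 4 active weeks in 1-52, week 55 in 53-61
        assert 2 not in starts  # only 3 active weeks in 2-53

    def test_sparse_history_yields_nothing(self):
        h = make_history([1, 2, 3], T=70)
        assert extract_windows(h) == []

    def test_dense_history_keeps_every_start(self):
        T = 70
        h = make_history(list(range(1, T + 1)), T=T)
        assert extract_windows(h) == list(range(1, T - 60 + 1))

    def test_too_short_period(self):
        assert extract_windows(make_history([1], T=30)) == []

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(61, 80), st.integers(0, 30), st.integers(0, 2 ** 31))
    def test_matches_brute_force_oracle(self, T, n_bookings, seed):
        rng = np.random.default_rng(seed)
        weeks = rng.integers(1, T + 1, size=n_bookings)
        totals = np.bincount(weeks, minlength=T + 1)[1:]
        h = make_history(list(weeks), T=T)
        assert extract_windows(h) == brute_force_windows(list(totals))


class TestCollapseColumns:
    def _setup(self):
        from attendcast.features import ProvisionClustering
        clustering = ProvisionClustering(
            assignment={"a": 1, "b": 1, "c": 2}, k=2)
        catalog = FacilityCatalog(
            top_facilities=["f1"], district_of={},
            column_of={"f1": 1, "f2": 2, "f3": 2}, n_district_groups=0)
        return clustering, catalog

    def test_same_cluster_columns_add(self):
        clustering, catalog = self._setup()
        P_raw = np.zeros((52, 3))
        P_raw[4, 0] = P_raw[4, 1] = 1  # provisions a, b -> cluster 1
        F_raw = np.zeros((52, 3))
        Ft_raw = np.zeros((9, 3))
        Ft_raw[2, 0] = 1
        P, F, Ft = collapse_columns(P_raw, F_raw, Ft_raw, clustering, catalog,
                                    ["a", "b", "c"], ["f1", "f2", "f3"])
        assert P[4, 0] == 2 and P.sum() == 2
        assert Ft[2, 0] == 1

    def test_counts_conserved(self):
        clustering, catalog = self._setup()
        rng = np.random.default_rng(1)
        P_raw = rng.integers(0, 3, (52, 3))
        F_raw = rng.integers(0, 3, (52, 3))
        Ft_raw = rng.integers(0, 3, (9, 3))
        P, F, Ft = collapse_columns(P_raw, F_raw, Ft_raw, clustering, catalog,
                                    ["a", "b", "c"], ["f1", "f2", "f3"])
        assert P.sum() == P_raw.sum()
        assert F.sum() == F_raw.sum()
        assert Ft.sum() == Ft_raw.sum()

    def test_unmapped_id_named_in_error(self):
        clustering, catalog = self._setup()
        with pytest.raises(KeyError, match="zzz"):
            collapse_columns(np.zeros((52, 1)), np.zeros((52, 1)),
                             np.zeros((9, 1)), clustering, catalog,
                             ["zzz"], ["f1"])


class TestScaling:
    def test_phi_zero_is_zero(self):
        assert scale_phi(0) == 0.0

    def test_phi_rejects_negative(self):
        with pytest.raises(ValueError):
            scale_phi(-1)

    def test_phi_strictly_increasing_decreasing_increments(self):
        v = scale_phi(np.arange(0, 30))
        d = np.diff(v)
        assert (d > 0).all()
        assert (np.diff(d) < 0).all()

    def test_phi_lambda_must_exceed_one(self):
        with pytest.raises(ValueError):
            ScalingConfig(lam=1.0)

    @pytest.mark.parametrize("age,expected",
                             [(0, 0.0), (120, 1.0), (60, 0.5), (150, 1.0)])
    def test_age_min_max_with_clamp(self, age, expected):
        assert scale_age(age) == pytest.approx(expected)


class TestLabelWindow:
    def test_single_top_facility_entry(self):
        Ft = np.zeros((9, 19))
        Ft[2, 6] = 2  # column 7, 1-based
        y = label_window(Ft)
        expected = np.zeros(11)
        expected[6] = 1
        np.testing.assert_array_equal(y, expected)

    def test_non_top_column_sets_last_label(self):
        Ft = np.zeros((9, 19))
        Ft[0, 14] = 1
        y = label_window(Ft)
        assert y[10] == 1 and y[:10].sum() == 0

    def test_mixed_columns(self):
        Ft = np.zeros((9, 19))
        Ft[1, 1] = 1
        Ft[5, 11] = 3
        y = label_window(Ft)
        assert y[1] == 1 and y[10] == 1 and y.sum() == 2

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31))
    def test_matches_set_definition_cellwise(self, seed):
        rng = np.random.default_rng(seed)
        Ft = (rng.random((9, 19)) < 0.05) * rng.integers(1, 4, (9, 19))
        y = label_window(Ft)
        for j in range(10):
            assert y[j] == int(any(Ft[i, j] > 0 for i in range(9)))
        assert y[10] == int(any(Ft[i, j] > 0 for i in range(9)
                                for j in range(10, 19)))

    def test_never_all_zero_after_extraction(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            Ft = (rng.random((9, 19)) < 0.03) * 1
            if Ft.sum() >= 1:  # extraction condition (b)
                assert label_window(Ft).sum() >= 1


class TestRebalance:
    def _labels(self, n_pos, n_other):
        y = np.zeros((n_pos + n_other, 11), dtype=np.int8)
        y[:n_pos, 0] = 1
        y[n_pos:, 10] = 1
        return y

    def test_arithmetic_300_700(self):
        idx = rebalance_windows(self._labels(300, 700), seed=0)
        assert len(idx) == 400

    def test_no_label11_only_windows(self):
        idx = rebalance_windows(self._labels(25, 0), seed=0)
        assert len(idx) == 25

    def test_deterministic_given_seed(self):
        y = self._labels(50, 210)
        a = rebalance_windows(y, seed=9)
        b = rebalance_windows(y, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_positive_label_frequencies_increase(self):
        rng = np.random.default_rng(3)
        n = 2000
        y = np.zeros((n, 11), dtype=np.int8)
        y[:, 10] = 1
        top = rng.random((n, 10)) < 0.04
        y[:, :10] = top
        before = y.mean(axis=0)
        idx = rebalance_windows(y, seed=1)
        after = y[idx].mean(axis=0)
        assert (after[:10] >= before[:10]).all()
        assert after[:10].sum() > before[:10].sum()
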