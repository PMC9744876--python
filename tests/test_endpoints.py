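import itertools
import math

import numpy as np
import pandas as pd
import pytest

from xenomet.endpoints import (
    BurdenSeries,
    auc_trapezoid,
    incidence_call,
    km_estimate,
    logrank_test,
    mann_whitney,
    normalize_burden,
    percent_change,
    pfs_time,
    resistance_time,
    tumor_volume,
)


def series(time, burden, start=0.0, threshold=None):
    return BurdenSeries(
        animal_id="a1",
        time=np.array(time, dtype=float),
        burden=np.array(burden, dtype=float),
        treatment_start=start,
        detection_threshold=threshold,
    )


class TestPercentChange:
    def test_equal_burdens_zero(self):
        s = series([0, 10], [50, 50])
        assert percent_change(s, 0, 10) == 0.0

    def test_decline(self):
        s = series([0, 10], [50, 30])
        assert percent_change(s, 0, 10) == pytest.approx(-40.0)

    def test_doubling(self):
        s = series([0, 10], [50, 100])
        assert percent_change(s, 0, 10) == pytest.approx(100.0)

    def test_unobserved_timepoint_errors(self):
        with pytest.raises(ValueError):
            percent_change(series([0, 10], [50, 30]), 0, 5)


class TestNormalizeBurden:
    def test_day_zero_maps_to_one(self):
        s = normalize_burden(series([0, 7, 30], [100, 50, 500], start=0))
        assert s.burden[0] == 1.0

    def test_division_by_baseline(self):
        s = normalize_burden(series([0, 7, 30], [100, 50, 500], start=0))
        assert np.allclose(s.burden, [1.0, 0.5, 5.0])

    def test_idempotent(self):
        s1 = normalize_burden(series([0, 7], [100, 50], start=0))
        s2 = normalize_burden(s1)
        assert np.allclose(s1.burden, s2.burden)


class TestAuc:
    def test_trapezoid(self):
        assert auc_trapezoid(series([0, 2], [1, 3])) == pytest.approx(4.0)

    def test_constant(self):
        assert auc_trapezoid(series([0, 5, 10], [2, 2, 2])) == pytest.approx(20.0)

    def test_window_additivity(self):
        s = series([0, 3, 7, 12], [1, 5, 2, 8])
        whole = auc_trapezoid(s, 0, 12)
        assert auc_trapezoid(s, 0, 7) + auc_trapezoid(s, 7, 12) == pytest.approx(whole)

    def test_single_point_window_errors(self):
        with pytest.raises(ValueError):
            auc_trapezoid(series([0, 2, 9], [1, 3, 1]), 5, 10)


def mw_oracle(a, b):
    """Exhaustive two-sided permutation p for the U statistic."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_of(xs, ys):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in xs for y in ys
        )

    mid = n_a * len(b) / 2
    obs = abs(u_of(a, b) - mid)
    hits = total = 0
    for pick in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in pick]
        ys = [pooled[i] for i in range(len(pooled)) if i not in pick]
        if abs(u_of(xs, ys) - mid) >= obs - 1e-12:
            hits += 1
        total += 1
    return u_of(a, b), hits / total


class TestMannWhitney:
    def test_hand_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_half_credit(self):
        u, _ = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(9 / 2)

    def test_u_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.integers(0, 10, size=rng.integers(1, 8))
            b = rng.integers(0, 10, size=rng.integers(1, 8))
            u_a, _ = mann_whitney(a, b)
            u_b, _ = mann_whitney(b, a)
            assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = rng.integers(0, 6, size=rng.integers(2, 6)).tolist()
            b = rng.integers(0, 6, size=rng.integers(2, 6)).tolist()
            u, p = mann_whitney(a, b)
            u_exp, p_exp = mw_oracle(a, b)
            assert u == pytest.approx(u_exp)
            assert p == pytest.approx(p_exp)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        b = rng.normal(1.0, size=40)
        _, p = mann_whitney(a, b)
        from scipy import stats

        _, p_scipy = stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic", use_continuity=False)
        assert p == pytest.approx(p_scipy, rel=1e-6)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKaplanMeier:
    def test_single_death_among_four(self):
        records = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 0, 0, 0]})
        km = km_estimate(records)
        assert km.loc[0, "survival"] == pytest.approx(0.75)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=40)
        records = pd.DataFrame({"time": t, "event": 1})
        km = km_estimate(records)
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean())

    def test_all_censored_flat_at_one(self):
        records = pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0]})
        km = km_estimate(records)
        assert len(km) == 0  # no drops: curve stays at 1

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        t = rng.exponential(10, size=60)
        e = rng.integers(0, 2, size=60)
        if e.sum() == 0:
            e[0] = 1
        km = km_estimate(pd.DataFrame({"time": t, "event": e}))
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        for _, row in km.iterrows():
            expected = float(kmf.survival_function_at_times(row["time"]).iloc[0])
            assert row["survival"] == pytest.approx(expected, rel=1e-9)


class TestLogRank:
    def _records(self, ta, tb, ea=None, eb=None):
        ea = [1] * len(ta) if ea is None else ea
        eb = [1] * len(tb) if eb is None else eb
        return pd.DataFrame(
            {
                "time": list(ta) + list(tb),
                "event": list(ea) + list(eb),
                "group": ["A"] * len(ta) + ["B"] * len(tb),
            }
        )

    def test_identical_groups_statistic_zero(self):
        rec = self._records([1, 2, 3], [1, 2, 3])
        chi2, p = logrank_test(rec)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_six_subject_grid(self):
        # groups A={1,3,5}, B={2,4,6}, all events; O-E table worked by hand:
        # E_B = 0.5 + 0.6 + 0.5 + 2/3 + 0.5 + 1 = 3.766667, V = 1.212222
        rec = self._records([1, 3, 5], [2, 4, 6])
        chi2, _ = logrank_test(rec)
        expected = (3 - (0.5 + 0.6 + 0.5 + 2 / 3 + 0.5 + 1)) ** 2 / (
            0.25 + 0.24 + 0.25 + (2 / 3) * (1 / 3) + 0.25
        )
        assert chi2 == pytest.approx(expected, rel=1e-9)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        rec = self._records(
            rng.exponential(10, size=25),
            rng.exponential(20, size=25),
            rng.integers(0, 2, size=25).tolist(),
            rng.integers(0, 2, size=25).tolist(),
        )
        chi2, p = logrank_test(rec)
        mask = rec["group"] == "A"
        res = lifelines.statistics.logrank_test(
            rec.loc[mask, "time"], rec.loc[~mask, "time"],
            rec.loc[mask, "event"], rec.loc[~mask, "event"],
        )
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
        assert p == pytest.approx(res.p_value, rel=1e-9)

    def test_no_events_warns_p_one(self):
        rec = self._records([1, 2], [3, 4], [0, 0], [0, 0])
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test(rec)
        assert (chi2, p) == (0.0, 1.0)

    def test_permutation_null_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(6)
        t = rng.exponential(10, size=30)
        ps = []
        for _ in range(200):
            labels = rng.permutation(["A"] * 15 + ["B"] * 15)
            rec = pd.DataFrame({"time": t, "event": 1, "group": labels})
            ps.append(logrank_test(rec)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPfs:
    def test_first_crossing_of_double_baseline(self):
        s = series([0, 7, 14, 21], [100, 120, 180, 210], start=0)
        assert pfs_time(s) == (21.0, True)

    def test_never_crossing_censored_at_last_day(self):
        s = series([0, 7, 14], [100, 80, 60], start=0)
        assert pfs_time(s) == (14.0, False)

    def test_exactly_double_is_event(self):
        s = series([0, 7], [100, 200], start=0)
        assert pfs_time(s) == (7.0, True)

    def test_no_pretreatment_point_errors(self):
        with pytest.raises(ValueError):
            pfs_time(series([5, 10], [100, 300], start=0))


class TestResistance:
    def test_running_nadir_scan(self):
        s = series([1, 2, 3, 4], [100, 10, 50, 120], start=0)
        assert resistance_time(s) == (4.0, True)

    def test_monotone_decline_never_resistant(self):
        s = series([1, 2, 3], [100, 50, 25], start=0)
        assert resistance_time(s) == (None, False)

    def test_exactly_tenfold_is_resistant(self):
        s = series([1, 2, 3], [100, 10, 100], start=0)
        assert resistance_time(s) == (3.0, True)


class TestIncidence:
    def test_three_consecutive_above_threshold(self):
        s = series([14, 21, 28], [5, 6, 7], threshold=1.0)
        assert incidence_call(s) == (True, 14.0)

    def test_isolated_spike_not_incident(self):
        s = series([7, 14, 21, 28], [0.5, 5.0, 0.5, 0.5], threshold=1.0)
        assert incidence_call(s) == (False, None)

    def test_two_timepoints_then_below_not_incident(self):
        s = series([14, 21, 28], [5.0, 5.0, 0.5], threshold=1.0)
        assert incidence_call(s) == (False, None)

    def test_too_few_timepoints_warns(self):
        s = series([14, 21], [5.0, 5.0], threshold=1.0)
        with pytest.warns(UserWarning):
            assert incidence_call(s) == (False, None)


class TestTumorVolume:
    def test_formula(self):
        assert tumor_volume(10, 5) == pytest.approx(130.0)

    def test_unit_sphere_like(self):
        assert tumor_volume(1, 1) == pytest.approx(0.52)

    def test_cubic_scaling(self):
        assert tumor_volume(20, 10) == pytest.approx(8 * tumor_volume(10, 5))

    def test_nonpositive_axis_errors(self):
        with pytest.raises(ValueError):
            tumor_volume(0, 1)

    def test_swapped_axes_warn(self):
        with pytest.warns(UserWarning):
            tumor_volume(5, 10)
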