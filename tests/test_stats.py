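"""Normalization, min-max scaling and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vesselquant import stats_report as sr


def _table(rows):
    return pd.DataFrame(rows, columns=sr.TABLE_COLUMNS)


class TestNormalizeToControl:
    def test_simple_arithmetic(self):
        t = _table(
            [
                ("e1", "d1", "control", "diam", 2.0),
                ("e1", "d2", "control", "diam", 4.0),
                ("e1", "d3", "treated", "diam", 3.0),
                ("e1", "d4", "treated", "diam", 6.0),
            ]
        )
        out = sr.normalize_to_control(t, "diam", "control")
        treated = out[out["condition"] == "treated"]["value"].tolist()
        assert treated == [1.0, 2.0]

    def test_control_normalizes_to_unit_mean_per_experiment(self):
        t = _table(
            [
                ("e1", "d1", "control", "diam", 2.0),
                ("e1", "d2", "control", "diam", 6.0),
                ("e2", "d3", "control", "diam", 10.0),
                ("e2", "d4", "control", "diam", 30.0),
            ]
        )
        out = sr.normalize_to_control(t, "diam", "control")
        for _, grp in out.groupby("experiment_id"):
            assert grp["value"].mean() == pytest.approx(1.0)

    def test_matches_per_experiment_division_oracle(self, rng):
        rows = []
        for e in ("e1", "e2"):
            for d in range(6):
                cond = "control" if d < 3 else "treated"
                rows.append((e, f"d{d}", cond, "cov", float(rng.uniform(1, 10))))
        t = _table(rows)
        out = sr.normalize_to_control(t, "cov", "control")
        for e in ("e1", "e2"):
            sub = t[t["experiment_id"] == e]
            ctrl_mean = sub[sub["condition"] == "control"]["value"].mean()
            expected = sub["value"] / ctrl_mean
            got = out[out["experiment_id"] == e]["value"]
            assert np.allclose(got.to_numpy(), expected.to_numpy())

    def test_missing_control_names_the_experiment(self):
        t = _table(
            [
                ("e1", "d1", "control", "diam", 2.0),
                ("e2", "d2", "treated", "diam", 3.0),
            ]
        )
        with pytest.raises(ValueError, match="e2"):
            sr.normalize_to_control(t, "diam", "control")


class TestMinMaxScale:
    def test_three_point_row(self):
        out, flags = sr.minmax_scale(np.array([[10.0, 20.0, 30.0]]))
        assert np.allclose(out, [[0.0, 0.5, 1.0]])
        assert flags == []

    def test_row_max_maps_to_one(self, rng):
        m = rng.uniform(0, 100, (5, 7))
        out, _ = sr.minmax_scale(m)
        assert np.allclose(out.max(axis=1), 1.0)
        assert np.allclose(out.min(axis=1), 0.0)

    def test_constant_row_flagged_and_mid_level(self):
        out, flags = sr.minmax_scale(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert np.allclose(out[0], 0.5)
        assert flags == [0]

    def test_matches_elementwise_oracle(self, rng):
        m = rng.uniform(-10, 10, (8, 5))
        out, _ = sr.minmax_scale(m)
        for i in range(8):
            lo, hi = m[i].min(), m[i].max()
            for j in range(5):
                assert out[i, j] == pytest.approx((m[i, j] - lo) / (hi - lo))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=6),
            min_size=1,
            max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_output_bounded_and_order_preserving(self, rows):
        m = np.array(rows)
        out, _ = sr.minmax_scale(m)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)
        for i in range(m.shape[0]):
            order = np.argsort(m[i], kind="stable")
            assert np.all(np.diff(out[i][order]) >= -1e-12)


class TestCompareGroups:
    def _two_group_table(self, a, b):
        rows = [("e1", f"a{i}", "ctl", "m", v) for i, v in enumerate(a)]
        rows += [("e1", f"b{i}", "trt", "m", v) for i, v in enumerate(b)]
        return _table(rows)

    def test_identical_groups_are_null(self):
        t = self._two_group_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = sr.compare_groups(t, "m", design="ttest")
        assert res.p_value == pytest.approx(1.0)
        res_a = sr.compare_groups(t, "m", design="anova")
        assert res_a.statistic == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_are_significant(self, rng):
        a = rng.normal(0.0, 0.01, 5)
        b = 10.0 + rng.normal(0.0, 0.01, 5)
        res = sr.compare_groups(self._two_group_table(a, b), "m", design="anova")
        assert res.p_value < 1e-6
        assert res.stars == "****"
        assert res.tukey is not None

    def test_paired_design(self):
        t = self._two_group_table([1.0, 2.0, 3.0], [2.1, 3.2, 4.0])
        res = sr.compare_groups(t, "m", design="paired")
        assert res.test == "paired t-test"
        assert res.p_value < 0.05

    def test_degenerate_groups_are_named(self):
        t = _table(
            [
                ("e1", "d1", "ctl", "m", 1.0),
                ("e1", "d2", "ctl", "m", 2.0),
                ("e1", "d3", "trt", "m", 3.0),
            ]
        )
        with pytest.raises(ValueError, match="trt"):
            sr.compare_groups(t, "m")

    def test_device_is_the_replication_unit(self):
        # three fields of view per device collapse to one value
        rows = [("e1", "d1", "ctl", "m", v) for v in (1.0, 2.0, 3.0)]
        rows += [("e1", "d2", "ctl", "m", v) for v in (4.0, 5.0, 6.0)]
        per_device = sr.device_means(_table(rows), "m")
        assert sorted(per_device["value"]) == [2.0, 5.0]

    def test_anova_type_one_error_is_calibrated(self):
        """Simulated global null: rejection rate at alpha=0.05 must sit in
        the binomial band around 0.05."""
        rng = np.random.default_rng(20260930)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = rng.normal(0.0, 1.0, (3, 5))
            from scipy.stats import f_oneway

            _, p = f_oneway(*groups)
            rej += p < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_tukey_familywise_error_under_global_null(self):
        """Balanced one-way layout: the Tukey HSD family-wise error rate
        equals P(studentized range > q_crit); checked by direct
        simulation, with statsmodels agreeing on a handful of cases."""
        from scipy.stats import studentized_range
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        k, n, n_rep = 3, 5, 1000
        df = k * (n - 1)
        q_crit = studentized_range.ppf(0.95, k, df)
        rng = np.random.default_rng(77)
        x = rng.normal(0.0, 1.0, (n_rep, k, n))
        means = x.mean(axis=2)
        mse = x.var(axis=2, ddof=1).mean(axis=1)
        q_obs = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(mse / n)
        fwer = float(np.mean(q_obs > q_crit))
        assert fwer <= 0.07
        # dual route: statsmodels decides identically on a few replicates
        labels = np.repeat([f"g{i}" for i in range(k)], n)
        for i in range(5):
            res = pairwise_tukeyhsd(x[i].ravel(), labels, alpha=0.05)
            assert bool(np.any(res.reject)) == bool(q_obs[i] > q_crit)


class TestReport:
    def test_mean_and_sem_formula(self):
        t = _table([("e1", f"d{i}", "ctl", "m", v) for i, v in enumerate([1.0, 2.0, 3.0])])
        out = sr.report(t)
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))

    def test_single_value_has_no_sem_and_is_flagged(self):
        t = _table([("e1", "d1", "ctl", "m", 4.0)])
        row = sr.report(t).iloc[0]
        assert np.isnan(row["sem"])
        assert row["flags"] == "single_value"

    def test_written_report_round_trips(self, tmp_path):
        t = _table(
            [
                ("e1", "d1", "ctl", "m", 1.0),
                ("e1", "d2", "ctl", "m", 3.0),
                ("e1", "d3", "trt", "m", 5.0),
                ("e1", "d4", "trt", "m", 7.0),
            ]
        )
        out = sr.report(t)
        path = tmp_path / "summary.csv"
        out.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert np.allclose(back["mean"], out["mean"])
        assert np.allclose(back["sem"], out["sem"])

    def test_normalization_idempotent_once_controls_are_unit(self):
        t = _table(
            [
                ("e1", "d1", "control", "m", 2.0),
                ("e1", "d2", "control", "m", 4.0),
                ("e1", "d3", "treated", "m", 6.0),
            ]
        )
        once = sr.normalize_to_control(t, "m", "control")
        twice = sr.normalize_to_control(once, "m", "control")
        assert np.allclose(once["value"], twice["value"])
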