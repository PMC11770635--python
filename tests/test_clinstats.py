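"""Association battery against hand-computed oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from admixith.clinstats import (assign_quartiles, correlate, cox_hr,
                                er_gene_score, km_logrank, math_score,
                                q1_vs_q4_test, quartile_table, trend_test)


class TestCorrelate:
    def test_identity_is_one(self):
        x = np.array([1.0, 2, 3, 5])
        assert correlate(x, x)[0] == pytest.approx(1.0)

    def test_spearman_hand_value(self):
        rho, _ = correlate([1, 2, 3], [6, 4, 5], "spearman")
        assert rho == pytest.approx(-0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            correlate([1, 2], [1, 2])
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2, 3], "kendall")


class TestQuartiles:
    def test_uniform_split(self):
        labs = assign_quartiles(np.arange(1, 9))
        assert labs.tolist() == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_group_sizes_at_230(self):
        rng = np.random.default_rng(0)
        labs = assign_quartiles(rng.permutation(np.linspace(0, 100, 230)))
        counts = pd.Series(labs).value_counts()
        assert counts.max() - counts.min() <= 1
        assert abs(counts["Q1"] - 57.5) <= 1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        v = rng.random(40)
        perm = rng.permutation(40)
        np.testing.assert_array_equal(assign_quartiles(v)[perm],
                                      assign_quartiles(v[perm]))

    def test_tie_at_threshold_goes_low(self):
        labs = assign_quartiles([1, 1, 1, 2, 3, 4, 5, 6])
        q25 = np.percentile([1, 1, 1, 2, 3, 4, 5, 6], 25)
        assert all(lab == "Q1" for lab, v in zip(labs, [1, 1, 1]) if v <= q25)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles([2.0] * 10)


class TestQ1VsQ4:
    @staticmethod
    def _quartiles(n1, n4):
        return np.array(["Q1"] * n1 + ["Q4"] * n4)

    def test_chi2_hand_value(self):
        # 2x2 table [[10, 40], [30, 20]] -> chi2 = 16.667 without correction
        feature = np.array([1] * 10 + [0] * 40 + [1] * 30 + [0] * 20)
        stat, p = q1_vs_q4_test(feature, self._quartiles(50, 50), "binary")
        assert stat == pytest.approx(16.667, abs=1e-3)
        oracle = 0.0  # textbook sum (O-E)^2/E
        table = np.array([[10, 40], [30, 20]], float)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - exp) ** 2 / exp).sum()
        assert stat == pytest.approx(oracle)

    def test_identical_proportions_zero_statistic(self):
        feature = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        stat, p = q1_vs_q4_test(feature, self._quartiles(4, 4), "binary")
        assert stat == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_chi2_matches_textbook_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n1, n4 = rng.integers(10, 60, size=2)
        f1 = (rng.random(n1) < rng.random()).astype(int)
        f4 = (rng.random(n4) < rng.random()).astype(int)
        table = np.array([[f1.sum(), n1 - f1.sum()], [f4.sum(), n4 - f4.sum()]],
                         dtype=float)
        if 0 in table.sum(0):
            pytest.skip("degenerate margin")
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - exp) ** 2 / exp).sum()
        stat, _ = q1_vs_q4_test(np.concatenate([f1, f4]),
                                self._quartiles(n1, n4), "binary")
        assert stat == pytest.approx(oracle)

    def test_continuous_student_t(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        stat, p = q1_vs_q4_test(np.concatenate([a, b]),
                                self._quartiles(20, 25), "continuous")
        ref = ttest_ind(a, b, equal_var=True)
        assert (stat, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            q1_vs_q4_test(np.ones(8), self._quartiles(4, 4), "continuous")


class TestTrend:
    def test_constant_feature_zero_slope(self):
        q = np.repeat(["Q1", "Q2", "Q3", "Q4"], 5)
        slope, _ = trend_test(np.ones(20), q)
        assert slope == pytest.approx(0.0)

    def test_exact_linear_means_slope_one(self):
        q = np.repeat(["Q1", "Q2", "Q3", "Q4"], 6)
        feature = np.repeat([1.0, 2.0, 3.0, 4.0], 6)
        slope, p = trend_test(feature, q)
        assert slope == pytest.approx(1.0)
        assert p < 1e-12

    def test_single_quartile_rejected(self):
        with pytest.raises(ValueError):
            trend_test(np.arange(4.0), np.array(["Q2"] * 4))


class TestScores:
    def test_er_score_is_mean_of_four_genes(self):
        expr = pd.DataFrame(
            [[8.0], [9.0], [10.0], [9.0]],
            index=["ESR1", "PGR", "BCL2", "SCUBE2"], columns=["c1"])
        assert er_gene_score(expr)["c1"] == pytest.approx(9.0)
        expr2 = expr.copy()
        expr2.loc[:] = 7.0
        assert er_gene_score(expr2)["c1"] == pytest.approx(7.0)

    def test_er_score_missing_gene(self):
        expr = pd.DataFrame([[1.0]], index=["ESR1"], columns=["c1"])
        with pytest.raises(KeyError):
            er_gene_score(expr)

    def test_math_hand_values(self):
        assert math_score([0.2, 0.3, 0.4]) == pytest.approx(0.1 / 0.3)
        assert math_score([0.3, 0.3, 0.3]) == 0.0

    def test_math_errors(self):
        with pytest.raises(ValueError):
            math_score([0.1, 0.2])
        with pytest.raises(ValueError):
            math_score([0.0, 0.0, 0.0])


def _km_oracle(times, events):
    """Hand product-limit: S(t) over sorted distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = {}
    for t in sorted(set(times[events == 1])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / at_risk
        out[t] = s
    return out


class TestSurvival:
    def test_product_limit_hand_values(self):
        curves, _, _ = km_logrank([1, 2, 3], [1, 1, 1], ["g"] * 3)
        np.testing.assert_allclose(curves["g"]["survival"],
                                   [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_product_limit_matches_oracle_on_enumerated_datasets(self):
        for n in (2, 3, 4, 5, 6):
            for times in itertools.combinations_with_replacement([1, 2, 3], n):
                events = [1] * n
                curves, _, _ = km_logrank(list(times), events, ["g"] * n)
                oracle = _km_oracle(times, events)
                for t, s in zip(curves["g"]["time"], curves["g"]["survival"]):
                    assert s == pytest.approx(oracle[t], abs=1e-12)

    def test_identical_groups_null_logrank(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 0, 1, 1, 0]
        _, stat, p = km_logrank(t + t, e + e, ["a"] * 6 + ["b"] * 6)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2], [0, 0], ["a", "b"])

    def test_cox_planted_hr2_recovery(self):
        rng = np.random.default_rng(3)
        n = 500
        group = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.where(group == 1, 2.0, 1.0))
        res = cox_hr(t, np.ones(n, int), group)
        assert 1.6 <= res.hazard_ratio <= 2.5
        assert res.ci_low <= res.hazard_ratio <= res.ci_high

    def test_cox_loghr_error_shrinks_with_n(self):
        errors = []
        for n in (100, 500, 2000):
            devs = []
            for rep in range(8):
                rng = np.random.default_rng(10 * n + rep)
                group = rng.integers(0, 2, n)
                t = rng.exponential(1.0 / np.where(group == 1, 2.0, 1.0))
                res = cox_hr(t, np.ones(n, int), group)
                devs.append(abs(np.log(res.hazard_ratio) - np.log(2.0)))
            errors.append(np.mean(devs))
        assert errors[2] < errors[0]

    def test_time_split_strata(self):
        rng = np.random.default_rng(4)
        n = 400
        group = rng.integers(0, 2, n)
        t = rng.exponential(60, n)
        e = np.ones(n, int)
        early = cox_hr(t, e, group, stratum="0-3y")
        late = cox_hr(t, e, group, stratum=">3y")
        assert early.n == n                      # everyone contributes early
        assert late.n == np.sum(t > 36)          # landmark: at risk beyond 36 mo
        assert early.n_events == np.sum(t <= 36)
        assert late.stratum == ">3y"

    def test_no_events_in_stratum_rejected(self):
        with pytest.raises(ValueError):
            cox_hr([50, 60, 70, 80], [0, 0, 1, 1], [0, 1, 0, 1], stratum="0-3y")


def test_quartile_table_shapes_and_directions():
    rng = np.random.default_rng(5)
    n = 200
    iluma = rng.uniform(0, 100, n)
    cohort = pd.DataFrame({
        "iluma_pct": iluma,
        "quartile": assign_quartiles(iluma),
        "grade3": (rng.random(n) < np.clip(0.5 - iluma / 250, 0.02, 1)).astype(int),
        "age": 60 - 0.05 * iluma + rng.normal(0, 5, n),
    })
    qt = quartile_table(cohort, ["grade3"], ["age"])
    assert set(qt["feature"]) == {"grade3", "age"}
    g = qt[qt.feature == "grade3"].iloc[0]
    assert g["Q1"] > g["Q4"]  # planted inverse association
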