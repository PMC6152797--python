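import numpy as np
import pandas as pd
import pytest
from scipy import stats
from hypothesis import given, settings, strategies as st

from thiolife import (
    compare_conditions,
    cross_condition_spearman,
    fold_change_by_count,
    half_life_ecdf,
    paired_model_test,
    wilcoxon_paired,
)

from ._oracles import wilcoxon_enumerate
from .test_summary import fits_table


class TestPairedModelTest:
    def test_null_center(self):
        c = np.array([2.0, 3.0, 5.0, 4.0])
        assert paired_model_test(c, c, "stabilize") == pytest.approx(0.5)

    def test_matches_closed_form_t_cdf(self):
        control = np.array([2.0, 3.0, 5.0, 4.0])
        treated = np.array([4.0, 6.0, 10.0, 8.0])
        d = treated - control  # {2, 3, 5, 4}
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        expected = float(stats.t.sf(t_stat, df=len(d) - 1))
        assert paired_model_test(control, treated, "stabilize") == pytest.approx(
            expected, rel=1e-12)

    def test_one_sided_complementarity(self):
        control = np.array([2.0, 3.0, 5.0, 4.0])
        treated = np.array([4.0, 6.0, 10.0, 8.0])
        p_up = paired_model_test(control, treated, "stabilize")
        p_down = paired_model_test(control, treated, "destabilize")
        assert p_up + p_down == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("c,t,err", [
        ([1.0], [2.0], "pairs"),
        ([1.0, 2.0], [1.0, 2.0, 3.0], "mismatch"),
    ])
    def test_input_errors(self, c, t, err):
        with pytest.raises(ValueError, match=err):
            paired_model_test(np.asarray(c), np.asarray(t), "stabilize")

    def test_unknown_prediction(self):
        with pytest.raises(ValueError):
            paired_model_test(np.ones(3), np.ones(3) * 2, "sideways")


class TestWilcoxonPaired:
    def test_all_positive_n6_exact(self):
        c = np.arange(1.0, 7.0)
        t = c + np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        assert wilcoxon_paired(c, t) == pytest.approx(2 / 64)

    def test_symmetric_differences_not_significant(self):
        c = np.arange(1.0, 7.0)
        t = c + np.array([1.0, -1.5, 2.0, -2.5, 3.0, -3.5])
        p_obs = wilcoxon_paired(c, t)
        assert p_obs > 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        d = rng.normal(0.3, 1.0, n)
        d = np.where(d == 0, 0.1, d)
        # distinct magnitudes keep the exact method in play
        d = np.sign(d) * (np.abs(d) + np.arange(n) * 1e-6)
        p = wilcoxon_paired(np.zeros(n), d)
        assert p == pytest.approx(wilcoxon_enumerate(d), rel=1e-9)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError):
            wilcoxon_paired(np.ones(6), np.ones(6))


class TestHalfLifeEcdf:
    def test_step_heights(self):
        tbl = half_life_ecdf(fits_table([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(tbl["half_life"], [1, 2, 3])
        np.testing.assert_allclose(tbl["cumulative_frequency"], [1 / 3, 2 / 3, 1.0])

    def test_single_value(self):
        tbl = half_life_ecdf(fits_table([4.2]))
        assert tbl["cumulative_frequency"].tolist() == [1.0]

    def test_monotone_bounded_terminal_one(self):
        rng = np.random.default_rng(2)
        tbl = half_life_ecdf(fits_table(rng.lognormal(1, 0.5, 50)))
        cf = tbl["cumulative_frequency"].to_numpy()
        assert np.all(np.diff(cf) >= 0) and cf[0] >= 0 and cf[-1] == 1.0

    def test_stochastic_dominance(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(1, 0.4, 200)
        control = half_life_ecdf(fits_table(base))
        treated = half_life_ecdf(fits_table(base * 1.7))
        grid = np.linspace(0.5, 30, 100)
        interp = lambda tbl: np.interp(grid, tbl["half_life"], tbl["cumulative_frequency"],
                                       left=0.0, right=1.0)
        assert np.all(interp(treated) <= interp(control) + 1e-12)


class TestCrossConditionSpearman:
    def test_identical(self):
        f = fits_table([1, 2, 3, 4])
        assert cross_condition_spearman(f, f) == pytest.approx(1.0)

    def test_reversed(self):
        assert cross_condition_spearman(fits_table([1, 2, 3]),
                                        fits_table([3, 2, 1])) == pytest.approx(-1.0)

    @given(st.sampled_from([np.exp, np.sqrt, lambda x: x ** 3 + 1]))
    @settings(deadline=None, max_examples=6)
    def test_monotone_transform_invariance(self, fn):
        rng = np.random.default_rng(7)
        th = rng.lognormal(1, 0.5, 30)
        a = fits_table(th)
        b = fits_table(np.asarray(fn(th)))
        assert cross_condition_spearman(a, b) == pytest.approx(
            cross_condition_spearman(a, a))

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = fits_table(rng.lognormal(1, 0.5, 20)), fits_table(rng.lognormal(1, 0.5, 20))
        assert cross_condition_spearman(a, b) == pytest.approx(
            cross_condition_spearman(b, a))


class TestFoldChangeByCount:
    def _series(self, vals, ids=None):
        ids = ids or [f"g{i}" for i in range(len(vals))]
        return pd.Series(np.asarray(vals, float), index=ids)

    def test_group_means(self):
        c = self._series([1, 1, 1, 1])
        t = self._series([2, 2, 4, 4])
        k = self._series([0, 2, 3, 5]).astype(int)
        out = fold_change_by_count(c, t, k, threshold=2)
        assert out.loc["low", "mean_fold"] == 2 and out.loc["high", "mean_fold"] == 4
        assert out.loc["low", "n"] == 2 and out.loc["high", "n"] == 2

    def test_empty_group(self):
        c, t = self._series([1, 1]), self._series([2, 2])
        k = self._series([0, 1]).astype(int)
        out = fold_change_by_count(c, t, k, threshold=2)
        assert out.loc["high", "n"] == 0 and np.isnan(out.loc["high", "mean_fold"])

    def test_threshold_effect_recovered_from_simulation(self):
        rng = np.random.default_rng(11)
        n = 400
        ids = [f"g{i}" for i in range(n)]
        counts = pd.Series(rng.integers(0, 6, n), index=ids)
        control = pd.Series(rng.lognormal(1.2, 0.5, n), index=ids)
        treated = control * (1 + 0.5 * (counts > 2)) * rng.lognormal(0, 0.05, n)
        out = fold_change_by_count(control, treated, counts, threshold=2)
        assert out.loc["high", "mean_fold"] / out.loc["low", "mean_fold"] == pytest.approx(
            1.5, rel=0.05)


class TestCompareConditions:
    def test_full_report_on_shared_ok(self):
        rng = np.random.default_rng(13)
        th = rng.lognormal(1.2, 0.5, 40)
        control = fits_table(th)
        treated = fits_table(th * 1.4 * rng.lognormal(0, 0.1, 40))
        comp = compare_conditions(control, treated, prediction_tp="stabilize",
                                  prediction_sr="destabilize")
        assert comp.p_tp < 0.05 < comp.p_sr
        assert comp.p_tp + comp.p_sr == pytest.approx(1.0, abs=1e-9)
        assert comp.wilcoxon_p < 0.05
        assert 0.5 < comp.spearman_rho <= 1.0

    def test_sr_prediction_optional(self):
        f = fits_table([1, 2, 3, 4])
        comp = compare_conditions(f, f, prediction_tp="destabilize", prediction_sr=None)
        assert comp.p_sr is None and comp.p_tp == pytest.approx(0.5)
        assert comp.wilcoxon_p is None  # identical tables: no shift to test
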