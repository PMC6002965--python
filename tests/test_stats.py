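"""Group statistics against textbook oracles: paired t, chi-square,
Garwood Poisson CIs, rate-ratio z test and adjusted GLMs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hypocgm.errors import DegenerateInputError, InputError
from hypocgm.stats import (
    adjusted_models,
    chi_square_2x2,
    paired_t,
    poisson_rate_ci,
    rate_compare,
)

from oracles import chi2_2x2_by_hand, paired_t_by_hand, poisson_ci_by_tail_inversion


class TestPairedT:
    def test_hand_value(self):
        c = paired_t([1.0, 2.0, 3.0])
        # t = mean / (sd / sqrt(n)) = 2 / (1/sqrt(3)) = 2 sqrt(3)
        assert 2 * sps.t.sf(2 * np.sqrt(3), df=2) == pytest.approx(c.p_value)
        assert c.p_value == pytest.approx(0.0742, abs=2e-4)
        assert c.ci_low <= c.estimate <= c.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_t([2.0, 2.0, 2.0])

    def test_sign_symmetry(self):
        d = [0.5, 1.3, -0.2, 2.2]
        a, b = paired_t(d), paired_t([-x for x in d])
        assert a.p_value == pytest.approx(b.p_value)
        assert a.estimate == pytest.approx(-b.estimate)

    def test_matches_formula_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = rng.normal(0.3, 1.0, size=int(rng.integers(3, 30)))
            t, df = paired_t_by_hand(d)
            c = paired_t(d)
            assert c.p_value == pytest.approx(2 * sps.t.sf(abs(t), df), rel=1e-10)


class TestChiSquare:
    def test_printed_counts(self):
        # 16/17 vs 7/17 subjects with at least one episode
        c = chi_square_2x2(16, 1, 7, 10)
        assert chi2_2x2_by_hand(16, 1, 7, 10) == pytest.approx(10.885, abs=2e-3)
        assert c.p_value < 0.001
        assert c.estimate == pytest.approx(16 / 17 - 7 / 17)

    def test_independence(self):
        c = chi_square_2x2(5, 5, 5, 5)
        assert c.p_value == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        a = chi_square_2x2(12, 4, 6, 9)
        b = chi_square_2x2(6, 9, 12, 4)
        assert a.p_value == pytest.approx(b.p_value)

    def test_empty_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            chi_square_2x2(0, 0, 5, 5)

    def test_matches_hand_formula_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c_, d = (int(x) for x in rng.integers(1, 40, 4))
            got = chi_square_2x2(a, b, c_, d)
            chi2 = chi2_2x2_by_hand(a, b, c_, d)
            assert got.p_value == pytest.approx(sps.chi2.sf(chi2, 1), rel=1e-9)


class TestPoissonCI:
    def test_zero_count_lower_bound(self):
        rate, lo, hi = poisson_rate_ci(0, 1.0)
        assert rate == 0.0 and lo == 0.0 and hi > 0

    def test_k10_quantile_values(self):
        rate, lo, hi = poisson_rate_ci(10, 1.0)
        assert lo == pytest.approx(4.795, abs=0.005)
        assert hi == pytest.approx(18.39, abs=0.01)

    def test_matches_tail_inversion_oracle(self):
        for k in (1, 3, 10, 25):
            _, lo, hi = poisson_rate_ci(k, 1.0)
            olo, ohi = poisson_ci_by_tail_inversion(k)
            assert lo == pytest.approx(olo, rel=1e-6)
            assert hi == pytest.approx(ohi, rel=1e-6)

    def test_exposure_scale_equivariance(self):
        r1, l1, h1 = poisson_rate_ci(7, 1.0)
        r2, l2, h2 = poisson_rate_ci(7, 2.0)
        assert (r2, l2, h2) == pytest.approx((r1 / 2, l1 / 2, h1 / 2))

    def test_negative_events_rejected(self):
        with pytest.raises(InputError):
            poisson_rate_ci(-1, 1.0)

    def test_empirical_coverage(self):
        rng = np.random.default_rng(7)
        for lam in (0.5, 2.0, 10.0):
            cover = 0
            n = 2000
            for k in rng.poisson(lam, n):
                _, lo, hi = poisson_rate_ci(int(k), 1.0)
                cover += lo <= lam <= hi
            assert cover / n >= 0.945  # exact interval: >= 95% coverage


class TestRateCompare:
    def test_null_case(self):
        c = rate_compare(50, 10.0, 50, 10.0)
        assert c.estimate == pytest.approx(1.0)
        assert c.p_value == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        c = rate_compare(100, 1.0, 50, 1.0)
        assert c.estimate == pytest.approx(2.0)

    def test_zero_events_flagged_not_infinite(self):
        c = rate_compare(0, 1.0, 10, 1.0)
        assert c.p_value is None
        assert any("unbounded" in f for f in c.flags)

    def test_type_one_error_under_null(self):
        rng = np.random.default_rng(11)
        lam, n = 30.0, 1000
        rejections = 0
        for _ in range(n):
            k1, k2 = rng.poisson(lam), rng.poisson(lam)
            if k1 == 0 or k2 == 0:
                continue
            c = rate_compare(int(k1), 1.0, int(k2), 1.0)
            rejections += c.p_value < 0.05
        rate = rejections / n
        half = 1.96 * np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half <= rate <= 0.05 + half


class TestAdjustedModels:
    def _binary_frame(self, rng, n=400, log_or=0.9):
        g = rng.integers(0, 2, n)
        logit = -0.5 + log_or * g
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        return pd.DataFrame({"y": y.astype(int), "group_low": g})

    def test_unadjusted_logistic_equals_cross_product_ratio(self):
        rng = np.random.default_rng(2)
        df = self._binary_frame(rng)
        a = int(((df.group_low == 1) & (df.y == 1)).sum())
        b = int(((df.group_low == 1) & (df.y == 0)).sum())
        c_ = int(((df.group_low == 0) & (df.y == 1)).sum())
        d = int(((df.group_low == 0) & (df.y == 0)).sum())
        got = adjusted_models(df, "y", "binary")
        assert got.estimate == pytest.approx(a * d / (b * c_), rel=1e-6)

    def test_saturated_poisson_equals_observed_rate_ratio(self):
        rng = np.random.default_rng(3)
        n = 300
        g = rng.integers(0, 2, n)
        expo = rng.uniform(0.5, 2.0, n)
        y = rng.poisson(expo * np.where(g == 1, 3.0, 1.5))
        df = pd.DataFrame({"y": y, "group_low": g, "expo": expo})
        got = adjusted_models(df, "y", "count", exposure_col="expo")
        obs_ratio = (y[g == 1].sum() / expo[g == 1].sum()) / (
            y[g == 0].sum() / expo[g == 0].sum()
        )
        assert got.estimate == pytest.approx(obs_ratio, rel=1e-6)

    def test_logistic_recovers_known_log_odds_ratio(self):
        true = 0.7
        rng = np.random.default_rng(4)
        ests, ses = [], []
        for _ in range(10):
            n = 2000
            g = rng.integers(0, 2, n)
            x = rng.normal(0, 1, n)
            logit = -0.4 + true * g + 0.3 * x
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
            df = pd.DataFrame({"y": y, "group_low": g, "x": x})
            got = adjusted_models(df, "y", "binary", covariates=("x",))
            ests.append(np.log(got.estimate))
            ses.append((np.log(got.ci_high) - np.log(got.ci_low)) / (2 * 1.96))
        se_mean = np.mean(ses) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - true) < 2 * se_mean

    def test_orthogonal_covariate_leaves_estimate_unchanged(self):
        rng = np.random.default_rng(5)
        n = 4000
        g = rng.integers(0, 2, n)
        z = rng.normal(0, 1, n)  # independent of group and outcome
        y = 1.0 + 0.8 * g + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "group_low": g, "z": z})
        un = adjusted_models(df, "y", "continuous")
        ad = adjusted_models(df, "y", "continuous", covariates=("z",))
        assert ad.estimate == pytest.approx(un.estimate, abs=0.05)

    def test_unknown_kind_and_missing_column(self):
        df = pd.DataFrame({"y": [0, 1], "group_low": [0, 1]})
        with pytest.raises(InputError):
            adjusted_models(df, "y", "weird")
        with pytest.raises(InputError):
            adjusted_models(df, "missing", "binary")
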