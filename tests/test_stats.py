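"""Statistical kernel: closed-form oracles and reference cross-checks."""

import numpy as np
import pytest
from scipy import stats as sps

from neoprior import stats
from neoprior.errors import (
    ConvergenceError,
    DesignError,
    InsufficientDataError,
    ParameterError,
)


class TestChiSquare:
    def test_uncorrected_statistic_closed_form(self):
        # N(ad-bc)^2 / product of margins on [[10,0],[0,10]]
        stat, p = stats.chi_square_2x2(10, 0, 0, 10)
        assert stat == pytest.approx(20.0)

    def test_symmetric_table_is_null(self):
        stat, p = stats.chi_square_2x2(5, 5, 5, 5)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_continuity_correction_changes_small_table(self):
        _, p_plain = stats.chi_square_2x2(3, 2, 0, 5)
        _, p_yates = stats.chi_square_2x2(3, 2, 0, 5, continuity=True)
        assert p_plain == pytest.approx(0.038, abs=5e-4)
        assert p_yates == pytest.approx(0.167, abs=5e-3)

    def test_zero_margin_rejected(self):
        with pytest.raises(ParameterError):
            stats.chi_square_2x2(0, 0, 3, 5)


class TestFisher:
    def test_one_sided_enrichment(self):
        p = stats.fisher_exact_2x2(10, 20, 0, 30, side="greater")
        # hypergeometric tail: P(X >= 10 | margins) with X ~ HG(60, 30, 10)
        oracle = sps.hypergeom.sf(9, 60, 10, 30)
        assert p == pytest.approx(oracle, rel=1e-10)
        assert p < 0.05

    def test_balanced_table(self):
        assert stats.fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)

    def test_row_swap_flips_side(self):
        p_greater = stats.fisher_exact_2x2(8, 2, 3, 7, side="greater")
        p_swapped = stats.fisher_exact_2x2(3, 7, 8, 2, side="less")
        assert p_greater == pytest.approx(p_swapped, rel=1e-12)


class TestBinomial:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (10, 10, 2 * 0.5**10),
            (5, 10, 1.0),
            (0, 2, 0.5),
        ],
    )
    def test_closed_forms(self, k, n, expected):
        assert stats.binomial_two_sided(k, n) == pytest.approx(expected)

    def test_bounds_checked(self):
        with pytest.raises(ParameterError):
            stats.binomial_two_sided(5, 3)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = stats.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_one_tailed(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 30)
        x = y + 10.0
        _, _, p = stats.welch_t(x, y, alternative="greater")
        assert p < 1e-3

    def test_matches_reference_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(0, 1, rng.integers(3, 20))
            y = rng.normal(0.3, 2, rng.integers(3, 20))
            t, df, p = stats.welch_t(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_equal_constants(self):
        t, df, p = stats.welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


class TestPearson:
    def test_perfect_correlations(self):
        x = [0.1, 0.2, 0.3, 0.5]
        assert stats.pearson(x, x)[0] == pytest.approx(1.0)
        assert stats.pearson(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([0.1, 0.4, 0.5])
        y = np.array([0.2, 0.35, 0.55])
        r, _ = stats.pearson(x, y)
        oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(oracle, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _records(times, events, groups):
    return [
        stats.SurvivalRecord(f"s{i}", t, e, g)
        for i, (t, e, g) in enumerate(zip(times, events, groups))
    ]


class TestLogrank:
    def test_identical_groups_null(self):
        recs = _records([5, 8, 12, 5, 8, 12], [1, 1, 0, 1, 1, 0],
                        ["a", "a", "a", "b", "b", "b"])
        stat, p = stats.logrank(recs)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        # times: group a events at 1, 3; group b event at 2, censor at 4
        recs = _records([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 0, 0],
                        ["a", "a", "a", "b", "b", "b"])
        # hand O-E/V: t=1 n=6 n_a=3 d=1 dA=1; t=2 n=5 n_a=2 d=1 dA=0;
        # t=3 n=4 n_a=2 d=1 dA=1
        exp = 3 / 6 + 2 / 5 + 2 / 4
        var = (3 / 6) * (3 / 6) * 1 + (2 / 5) * (3 / 5) * 1 + (2 / 4) * (2 / 4) * 1
        stat, _ = stats.logrank(recs)
        assert stat == pytest.approx((2 - exp) ** 2 / var, rel=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(2)
        t1, t2 = rng.exponential(10, 40), rng.exponential(5, 35)
        e1 = (t1 < 15).astype(int)
        e2 = (t2 < 15).astype(int)
        recs = _records(
            np.concatenate([np.minimum(t1, 15), np.minimum(t2, 15)]),
            np.concatenate([e1, e2]),
            ["a"] * 40 + ["b"] * 35,
        )
        stat, p = stats.logrank(recs)
        ref = logrank_test(np.minimum(t1, 15), np.minimum(t2, 15), e1, e2)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(DesignError):
            stats.logrank(_records([1, 2], [1, 1], ["a", "a"]))


class TestKaplanMeier:
    def test_two_sample_curve(self):
        recs = _records([3.0, 7.0], [1, 1], [None, None])
        km = stats.km_curve(recs)
        assert list(km["time"]) == [3.0, 7.0]
        assert list(km["survival"]) == pytest.approx([0.5, 0.0])

    def test_censoring_holds_curve(self):
        recs = _records([3.0, 7.0], [1, 0], [None, None])
        km = stats.km_curve(recs)
        assert list(km["survival"]) == pytest.approx([0.5])


class TestCox:
    def test_null_covariate_calibration(self):
        rng = np.random.default_rng(3)
        covered = 0
        n_seeds = 200
        for _ in range(n_seeds):
            times = rng.exponential(10, 80)
            x = rng.normal(size=80)
            recs = _records(times, np.ones(80, dtype=int), x)
            fit = stats.cox_univariate(recs)
            if abs(fit["beta"]) < 3 * fit["se"]:
                covered += 1
        assert covered >= 0.95 * n_seeds

    def test_recovers_log_hazard_ratio(self):
        rng = np.random.default_rng(4)
        betas = []
        for _ in range(40):
            x = rng.normal(size=300)
            lam = 0.1 * np.exp(np.log(2) * x)
            times = rng.exponential(1 / lam)
            recs = _records(times, np.ones(300, dtype=int), x)
            betas.append(stats.cox_univariate(recs)["beta"])
        assert abs(np.mean(betas) - np.log(2)) < 0.15

    def test_matches_lifelines_on_untied_data(self):
        # tie-free times: Breslow and Efron partial likelihoods coincide
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        lam = 0.1 * np.exp(0.7 * x)
        times = rng.exponential(1 / lam)
        event = np.ones(60, dtype=int)
        recs = _records(times, event, x)
        fit = stats.cox_univariate(recs)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"T": times, "E": event, "x": x}),
                duration_col="T", event_col="E")
        assert fit["beta"] == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert fit["se"] == pytest.approx(
            float(cph.standard_errors_["x"]), rel=1e-3)

    def test_constant_covariate_rejected(self):
        with pytest.raises(DesignError):
            stats.cox_univariate(_records([1, 2, 3], [1, 1, 1], [1.0, 1.0, 1.0]))

    def test_wald_concordant_with_logrank(self):
        rng = np.random.default_rng(6)
        agree = 0
        n_seeds = 60
        for _ in range(n_seeds):
            x = rng.integers(0, 2, 120)
            lam = 0.1 * np.exp(0.8 * x)
            times = rng.exponential(1 / lam)
            event = np.ones(120, dtype=int)
            cox_p = stats.cox_univariate(
                _records(times, event, x.astype(float)))["p"]
            lr_p = stats.logrank(_records(times, event, x))[1]
            if (cox_p < 0.05) == (lr_p < 0.05):
                agree += 1
        assert agree >= 0.95 * n_seeds


def test_chi_square_fisher_rejection_agreement():
    rng = np.random.default_rng(7)
    agree = total = 0
    while total < 100:
        a, b, c, d = rng.integers(5, 40, size=4)
        total += 1
        chi_p = stats.chi_square_2x2(a, b, c, d)[1]
        f_p = stats.fisher_exact_2x2(a, b, c, d)
        agree += (chi_p < 0.05) == (f_p < 0.05)
    assert agree >= 90
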