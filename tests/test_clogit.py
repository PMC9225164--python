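"""Conditional-logit likelihoods, fitting, and the Wald test."""

from itertools import combinations
from math import comb, log

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from wearva import (
    FitResult, NoInformativeStrataError,
    conditional_loglik_approx, conditional_loglik_exact, fit, fit_design, wald_test,
)


def brute_force_loglik(X, y, beta):
    """Independent oracle: direct sum over all size-m subsets."""
    X = np.atleast_2d(X)
    eta = X @ np.atleast_1d(beta)
    m = int(np.sum(y))
    cases = eta[np.asarray(y, bool)].sum()
    return cases - logsumexp([eta[list(s)].sum() for s in combinations(range(len(eta)), m)])


def random_stratum(rng, n_max=10, p=2):
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(1, n))
    X = rng.normal(size=(n, p))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, m, replace=False)] = 1
    return X, y


class TestExactLikelihood:
    def test_one_case_one_control_closed_form(self):
        for beta in (-1.3, 0.0, 0.7):
            ll = conditional_loglik_exact([[1.0], [0.0]], [1, 0], [beta])
            assert np.isclose(ll, beta - log(np.exp(beta) + 1))

    def test_null_likelihood_is_log_choose(self):
        rng = np.random.default_rng(5)
        for n, m in [(5, 2), (8, 3), (10, 5)]:
            X = rng.normal(size=(n, 2))
            y = np.array([1] * m + [0] * (n - m))
            assert np.isclose(conditional_loglik_exact(X, y, [0.0, 0.0]), -log(comb(n, m)))

    def test_matches_brute_force_subset_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            X, y = random_stratum(rng)
            beta = rng.normal(size=2)
            assert abs(conditional_loglik_exact(X, y, beta)
                       - brute_force_loglik(X, y, beta)) <= 1e-10

    def test_invariant_to_stratum_constant_shift(self):
        rng = np.random.default_rng(23)
        X, y = random_stratum(rng)
        beta = rng.normal(size=2)
        shifted = X + rng.normal(size=(1, 2))  # same constant added to every row
        assert np.isclose(conditional_loglik_exact(X, y, beta),
                          conditional_loglik_exact(shifted, y, beta), atol=1e-10)

    def test_enumeration_bound_directs_to_approximation(self):
        X = np.random.default_rng(1).normal(size=(40, 1))
        y = np.array([1] * 10 + [0] * 30)
        with pytest.raises(ValueError, match="conditional_loglik_approx"):
            conditional_loglik_exact(X, y, [0.1], limit=1000)


class TestApproximateLikelihood:
    def test_exact_for_single_case_strata(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            X = rng.normal(size=(n, 2))
            y = np.zeros(n, int)
            y[rng.integers(n)] = 1
            beta = rng.normal(size=2)
            exact = conditional_loglik_exact(X, y, beta)
            for ties in ("breslow", "efron"):
                assert np.isclose(conditional_loglik_approx(X, y, beta, ties=ties), exact)

    def test_breslow_null_closed_form(self):
        X = np.random.default_rng(2).normal(size=(9, 2))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0])
        assert np.isclose(conditional_loglik_approx(X, y, [0.0, 0.0]), -3 * log(9))

    def test_near_exact_for_small_beta_multi_case(self):
        # the tie approximations differ from the exact likelihood by an
        # almost-constant offset (-m log n vs -log C(n, m)) that cancels in
        # estimation, so compare likelihoods relative to the null: for
        # |beta| <= 0.2 on standard-normal x the relative gap stays tiny
        rng = np.random.default_rng(31)
        zero = np.zeros(1)
        for _ in range(20):
            X = rng.normal(size=(6, 1))
            y = np.array([1, 1, 0, 0, 0, 0])
            beta = rng.uniform(-0.2, 0.2, size=1)
            d_exact = (conditional_loglik_exact(X, y, beta)
                       - conditional_loglik_exact(X, y, zero))
            for ties, tol in (("breslow", 0.02), ("efron", 0.05)):
                d_approx = (conditional_loglik_approx(X, y, beta, ties=ties)
                            - conditional_loglik_approx(X, y, zero, ties=ties))
                assert abs(d_approx - d_exact) < tol


class TestFit:
    def test_matched_pairs_closed_form_or(self):
        # discordant-pair MLE: OR = n10 / n01
        rows = []
        for i in range(6):
            rows += [(f"a{i}", 1, 1.0), (f"a{i}", 0, 0.0)]
        for i in range(3):
            rows += [(f"b{i}", 1, 0.0), (f"b{i}", 0, 1.0)]
        df = pd.DataFrame(rows, columns=["s", "y", "x"])
        fr = fit_design(df[["x"]].to_numpy(), df["y"].to_numpy(), df["s"].to_numpy())
        assert fr.converged and fr.method == "exact"
        assert np.isclose(fr.or_, 2.0, atol=1e-8)

    def test_antisymmetric_strata_give_null_estimate(self):
        df = pd.DataFrame({"s": ["a", "a", "b", "b"], "y": [1, 0, 1, 0],
                           "x": [1.0, 0.0, 0.0, 1.0]})
        fr = fit_design(df[["x"]].to_numpy(), df["y"].to_numpy(), df["s"].to_numpy())
        assert np.isclose(fr.beta, 0.0, atol=1e-8) and np.isclose(fr.or_, 1.0, atol=1e-8)

    def test_agrees_with_reference_implementation(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit
        rng = np.random.default_rng(42)
        Xs, ys, ss = [], [], []
        for s in range(12):
            X, y = random_stratum(rng, n_max=14)
            Xs.append(X), ys.append(y), ss.append(np.full(len(y), s))
        X, y, strata = np.vstack(Xs), np.concatenate(ys), np.concatenate(ss)
        fr = fit_design(X, y, strata)
        ref = ConditionalLogit(y, X, groups=strata).fit(method="newton", tol=1e-12, disp=0)
        assert np.all(np.abs(fr.params - ref.params) / np.abs(ref.params) < 1e-4)
        assert np.all(np.abs(fr.se_all - ref.bse) / ref.bse < 1e-4)

    def test_large_strata_fall_back_to_tie_approximation(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 1))
        y = np.zeros(60, int)
        y[rng.choice(60, 6, replace=False)] = 1
        fr = fit_design(X, y, np.zeros(60), exact_limit=100)
        assert fr.method == "breslow" and fr.converged

    def test_non_informative_strata_dropped_and_counted(self):
        df = pd.DataFrame({
            "s": ["a"] * 4 + ["b"] * 3 + ["c"] * 2,
            "y": [1, 0, 0, 0] + [0, 0, 0] + [1, 0],
            "x": [1.0, 0.2, 0.1, 0.0, 5.0, 5.0, 5.0, 0.8, 0.3],
        })
        fr = fit_design(df[["x"]].to_numpy(), df["y"].to_numpy(), df["s"].to_numpy())
        assert fr.n_strata == 2 and fr.n_case == 2 and fr.n_control == 4

    def test_all_concordant_strata_is_an_error(self):
        df = pd.DataFrame({"s": ["a", "a", "b"], "y": [0, 0, 1], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(NoInformativeStrataError):
            fit_design(df[["x"]].to_numpy(), df["y"].to_numpy(), df["s"].to_numpy())

    def test_within_stratum_constant_exposure_is_an_error(self):
        df = pd.DataFrame({"s": ["a", "a", "b", "b"], "y": [1, 0, 1, 0],
                           "x": [2.0, 2.0, 7.0, 7.0]})
        with pytest.raises(NoInformativeStrataError, match="constant"):
            fit_design(df[["x"]].to_numpy(), df["y"].to_numpy(), df["s"].to_numpy())

    def test_separation_is_flagged_not_silent(self):
        rows = []
        for i in range(5):  # every case has the larger exposure: MLE at infinity
            rows += [(f"s{i}", 1, 1.0), (f"s{i}", 0, 0.0)]
        df = pd.DataFrame(rows, columns=["s", "y", "x"])
        fr = fit_design(df[["x"]].to_numpy(), df["y"].to_numpy(), df["s"].to_numpy())
        assert not fr.converged
        assert fr.message != ""

    def test_formula_covariates_enter_the_design(self, small_cohort):
        from wearva import ValidityScenario, build_observations
        obs = build_observations(small_cohort, ValidityScenario(1, 4, 0.5), 1, "Steps")
        fr1 = fit(obs, formula=1)
        fr2 = fit(obs, formula=2)
        fr3 = fit(obs, formula=3)
        assert fr3.param_names[0] == "exposure"
        assert "weekday_status[weekend]" in fr1.param_names
        assert "day_of_week[2]" in fr2.param_names
        assert all(np.isfinite(f.beta) for f in (fr1, fr2, fr3))


class TestWald:
    def test_null_estimate_gives_p_one(self):
        fr = FitResult(beta=0.0, se=0.5, or_=1.0, p=1.0, n_strata=1, n_case=1,
                       n_control=1, converged=True, method="exact", n_iter=1, loglik=0.0)
        z, p = wald_test(fr)
        assert z == 0.0 and p == 1.0

    def test_1p96_se_gives_p_near_0p05(self):
        fr = FitResult(beta=1.96, se=1.0, or_=np.exp(1.96), p=np.nan, n_strata=1,
                       n_case=1, n_control=1, converged=True, method="exact",
                       n_iter=1, loglik=0.0)
        assert np.isclose(wald_test(fr)[1], 0.05, atol=1e-3)

    def test_matches_normal_cdf_recomputation(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            b, s = rng.normal(), rng.uniform(0.1, 2.0)
            fr = FitResult(beta=b, se=s, or_=np.exp(b), p=np.nan, n_strata=1,
                           n_case=1, n_control=1, converged=True, method="exact",
                           n_iter=1, loglik=0.0)
            z, p = wald_test(fr)
            assert np.isclose(p, 2 * (1 - norm.cdf(abs(b / s))))

    def test_zero_se_is_an_error(self):
        fr = FitResult(beta=1.0, se=0.0, or_=np.e, p=np.nan, n_strata=1, n_case=1,
                       n_control=1, converged=True, method="exact", n_iter=1, loglik=0.0)
        with pytest.raises(ValueError):
            wald_test(fr)
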