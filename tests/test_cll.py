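"""CLL transform, OLS fit and backward-forward AIC selection."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mossmap import (cll_transform, inverse_cll, fit_cll, stepwise_aic,
                     RankDeficientError)
from mossmap.cll import DomainError
from conftest import make_table


def regression_frame(rng, n, p, beta=None, sigma=0.0, alpha=0.1):
    X = rng.normal(0, 1, (n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta)
    eta = alpha + X @ beta + rng.normal(0, sigma, n)
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    df["site_id"] = [f"s{i}" for i in range(n)]
    df["x"], df["y"], df["zone"] = 0.0, 0.0, "Z"
    df["moss_species"], df["tree_cover"] = "Hc", "deciduous"
    df["cd"] = 1.5 * np.exp(-np.exp(eta))
    return make_table(df, covariates=[f"x{j}" for j in range(p)])


class TestTransform:
    def test_analytic_points(self):
        assert cll_transform(1.5 / np.e, 1.5) == pytest.approx(0.0, abs=1e-12)
        assert cll_transform(1.5 * np.exp(-np.e), 1.5) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_bounds_raises_naming_position(self):
        with pytest.raises(DomainError, match=r"\[2\]"):
            cll_transform([0.5, 0.7, 1.6], 1.5)
        with pytest.raises(DomainError):
            cll_transform(0.0, 1.5)

    def test_strictly_decreasing(self):
        y = np.linspace(0.01, 1.49, 200)
        z = cll_transform(y, 1.5)
        assert np.all(np.diff(z) < 0)

    def test_inverse_limits(self):
        assert inverse_cll(50.0, 1.5) == pytest.approx(0.0, abs=1e-12)
        assert inverse_cll(-50.0, 1.5) == pytest.approx(1.5, abs=1e-12)
        assert inverse_cll(0.0, 1.5) == pytest.approx(1.5 / np.e)

    @settings(deadline=None, max_examples=200)
    @given(st.floats(1e-6, 1.0 - 1e-6), st.floats(0.1, 10.0))
    def test_round_trip(self, frac, cd_max):
        y = frac * cd_max
        back = inverse_cll(cll_transform(y, cd_max), cd_max)
        assert back == pytest.approx(y, rel=1e-10)


class TestFit:
    def test_intercept_only_is_mean_of_transformed(self, toy_regression_table):
        fit = fit_cll(toy_regression_table, [])
        z = cll_transform(toy_regression_table.data["cd"].to_numpy(), 1.5)
        assert fit.alpha == pytest.approx(z.mean(), abs=1e-12)
        assert fit.k_params == 1

    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(2)
        t = regression_frame(rng, 40, 3, beta=[0.5, -0.3, 0.2], sigma=0.0)
        fit = fit_cll(t, ["x0", "x1", "x2"])
        assert fit.alpha == pytest.approx(0.1, abs=1e-8)
        assert fit.betas["x0"] == pytest.approx(0.5, abs=1e-8)
        assert fit.sigma2_hat * fit.n_obs < 1e-16 * fit.n_obs + 1e-16

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = regression_frame(rng, 30, 4, beta=rng.normal(0, 0.3, 4),
                                 sigma=0.3)
            fit = fit_cll(t, [f"x{j}" for j in range(4)])
            # brute-force oracle: solve X'X b = X'z directly
            z = cll_transform(t.data["cd"].to_numpy(), 1.5)
            X = np.column_stack([np.ones(30)] +
                                [t.data[f"x{j}"] for j in range(4)])
            b = np.linalg.solve(X.T @ X, X.T @ z)
            assert fit.alpha == pytest.approx(b[0], abs=1e-9)
            for j in range(4):
                assert fit.betas[f"x{j}"] == pytest.approx(b[j + 1], abs=1e-9)

    def test_aic_convention_and_ranking(self, toy_regression_table):
        fits = [fit_cll(toy_regression_table, v)
                for v in ([], ["a"], ["b"], ["a", "b"])]
        for f in fits:
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * (f.k_params + 1))
        # ranking must agree with RSS-based -2loglik + 2p on equal-M fits
        alt = [f.n_obs * np.log(f.sigma2_hat) + 2 * (f.k_params + 1)
               for f in fits]
        assert np.argsort([f.aic for f in fits]).tolist() == \
            np.argsort(alt).tolist()

    def test_rank_deficient_lists_aliased_columns(self, toy_regression_table):
        t = toy_regression_table
        t.data["a_copy"] = t.data["a"]
        t.covariates.append("a_copy")
        with pytest.raises(RankDeficientError) as exc:
            fit_cll(t, ["a", "b", "a_copy"])
        assert "a" in exc.value.aliased and "a_copy" in exc.value.aliased

    def test_more_params_than_rows_raises(self):
        rng = np.random.default_rng(4)
        t = regression_frame(rng, 5, 6, sigma=0.1)
        with pytest.raises(ValueError, match="observations"):
            fit_cll(t, [f"x{j}" for j in range(6)])

    def test_categorical_reference_levels(self, small_sites):
        fit = fit_cll(small_sites, ["moss_species", "tree_cover"])
        ref, levels = fit.design_info.categorical["moss_species"]
        assert ref == "Hc" and "Hc" not in levels
        ref_t, _ = fit.design_info.categorical["tree_cover"]
        assert ref_t == "deciduous"
        assert "moss_species[Pp]" in fit.betas


class TestStepwise:
    def test_accepted_moves_strictly_decrease_aic(self, small_sites):
        from mossmap import screen
        rep = screen(small_sites)
        fit, trace = stepwise_aic(small_sites,
                                  ["moss_species", "tree_cover"] + rep.retained)
        for _, _, before, after in trace.steps:
            assert after < before
        assert trace.final_aic == pytest.approx(fit.aic)

    def test_recovers_single_active_covariate(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(10):
            t = regression_frame(rng, 200, 6,
                                 beta=[0.8, 0, 0, 0, 0, 0], sigma=0.15)
            fit, _ = stepwise_aic(t, [f"x{j}" for j in range(6)])
            hits += "x0" in fit.variables
        assert hits >= 9

    def test_parsimony_under_pure_noise(self):
        # under the null each noise variable survives AIC selection with
        # probability P(chi2_1 > 2) ~= 0.157, so the intercept-only model
        # is chosen at rate ~0.843^5 ~= 0.43 and on average fewer than one
        # of the five noise variables is retained
        rng = np.random.default_rng(7)
        intercept_only, kept = 0, 0
        reps = 30
        for _ in range(reps):
            t = regression_frame(rng, 200, 5, sigma=0.3)
            fit, _ = stepwise_aic(t, [f"x{j}" for j in range(5)])
            intercept_only += len(fit.variables) == 0
            kept += len(fit.variables)
        assert 0.2 * reps <= intercept_only <= 0.7 * reps
        assert kept / reps < 1.6

    def test_matches_exhaustive_subset_minimum(self):
        rng = np.random.default_rng(8)
        t = regression_frame(rng, 60, 5, beta=[0.6, -0.4, 0, 0, 0],
                             sigma=0.25)
        names = [f"x{j}" for j in range(5)]
        fit, trace = stepwise_aic(t, names)
        best = min(fit_cll(t, list(sub)).aic
                   for r in range(6)
                   for sub in itertools.combinations(names, r))
        start_aic = fit_cll(t, names).aic
        assert fit.aic <= start_aic + 1e-9
        assert fit.aic == pytest.approx(best, abs=1e-9)

    def test_infeasible_full_start_falls_back_to_forward(self):
        rng = np.random.default_rng(9)
        t = regression_frame(rng, 12, 15, beta=[1.0] + [0.0] * 14, sigma=0.1)
        fit, trace = stepwise_aic(t, [f"x{j}" for j in range(15)])
        assert len(fit.variables) < 12
        assert any(a == "add" for a, *_ in trace.steps)
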