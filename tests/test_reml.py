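import numpy as np
import pandas as pd
import pytest

from vcunet import METDataset, benjamini_hochberg, blup_diff_variance, lrt_correlation, reml_fit
from vcunet.model import FixedTerm, ModelSpec, RandomTerm
from vcunet.reml import (
    AliasingError,
    FitOptions,
    VarianceComponents,
    build_problem,
    prepare_frame,
)

from conftest import (
    balanced_met_frame,
    balanced_met_spec,
    make_records,
    one_way_frame,
    one_way_spec,
    two_way_frame,
    two_way_spec,
)

_LOG2PI = np.log(2 * np.pi)


def dense_neg2_reml(y, X, Z_list, var_list, resid_var):
    """Independent restricted likelihood via dense V (no MME machinery)."""
    n, p = X.shape
    V = resid_var * np.eye(n)
    for Z, s in zip(Z_list, var_list):
        V += s * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    return (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XVX)[1]
        + float(y @ P @ y)
        + (n - p) * _LOG2PI
    )


def indicator(df, col):
    levels = sorted(df[col].unique())
    return (df[col].to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)


class TestLikelihoodAgainstDenseOracle:
    def test_mme_likelihood_equals_dense_formula(self):
        df = one_way_frame(g=5, n=4, seed=2)
        prob = build_problem(prepare_frame(METDataset(df)), one_way_spec())
        Z = indicator(df, "variety")
        y = df["value"].to_numpy()
        X = np.ones((len(df), 1))
        for sg, se in [(0.5, 0.3), (1.2, 0.9), (0.05, 2.0)]:
            vc = VarianceComponents({"sigma2_G": sg, "sigma2_GLY'": se})
            assert prob.neg2_restricted_loglik(vc) == pytest.approx(
                dense_neg2_reml(y, X, [Z], [sg], se), abs=1e-8
            )

    def test_optimum_matches_dense_grid_search(self):
        """REML optimum agrees with a grid over the dense restricted likelihood."""
        df = one_way_frame(g=5, n=4, seed=4)  # 20 observations
        y = df["value"].to_numpy()
        X = np.ones((len(df), 1))
        Z = indicator(df, "variety")
        fit = reml_fit(METDataset(df), one_way_spec())
        grid_g = np.linspace(0.05, 4.0, 80)
        grid_e = np.linspace(0.05, 2.0, 80)
        vals = np.array(
            [[dense_neg2_reml(y, X, [Z], [sg], se) for se in grid_e] for sg in grid_g]
        )
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        res_g = grid_g[1] - grid_g[0]
        res_e = grid_e[1] - grid_e[0]
        assert abs(fit.vc["sigma2_G"] - grid_g[i]) <= res_g
        assert abs(fit.vc["sigma2_GLY'"] - grid_e[j]) <= res_e
        assert -2 * fit.loglik <= vals[i, j] + 1e-8


class TestBalancedIdentities:
    def test_one_way_equals_anova_estimators(self):
        df = one_way_frame(g=8, n=5, seed=0)
        fit = reml_fit(METDataset(df), one_way_spec())
        y = df.pivot_table(index="variety", columns="location", values="value").to_numpy()
        g, n = y.shape
        msb = n * np.var(y.mean(axis=1), ddof=1)
        mse = np.mean(np.var(y, axis=1, ddof=1))
        assert fit.vc["sigma2_G"] == pytest.approx((msb - mse) / n, abs=1e-8)
        assert fit.vc["sigma2_GLY'"] == pytest.approx(mse, abs=1e-8)

    def test_two_way_equals_anova_estimators(self):
        df = two_way_frame(seed=1)
        fit = reml_fit(METDataset(df), two_way_spec())
        Y = df.pivot_table(index="variety", columns="year", values="value").to_numpy()
        a, b = Y.shape
        gm = Y.mean()
        msa = b * np.var(Y.mean(axis=1), ddof=1)
        msb = a * np.var(Y.mean(axis=0), ddof=1)
        mse = ((Y - Y.mean(1, keepdims=True) - Y.mean(0, keepdims=True) + gm) ** 2).sum() / (
            (a - 1) * (b - 1)
        )
        assert fit.vc["sigma2_G"] == pytest.approx((msa - mse) / b, abs=1e-8)
        assert fit.vc["sigma2_Y"] == pytest.approx((msb - mse) / a, abs=1e-8)
        assert fit.vc["sigma2_GLY'"] == pytest.approx(mse, abs=1e-8)

    def test_against_statsmodels_mixedlm(self):
        """Independent cross-check of the one-way fit against MixedLM REML."""
        import statsmodels.api as sm

        df = one_way_frame(g=10, n=6, seed=9)
        fit = reml_fit(METDataset(df), one_way_spec())
        m = sm.MixedLM(
            df["value"].to_numpy(), np.ones((len(df), 1)), groups=df["variety"]
        ).fit(reml=True)
        assert fit.vc["sigma2_G"] == pytest.approx(
            float(np.asarray(m.cov_re)[0, 0]), rel=1e-4
        )
        assert fit.vc["sigma2_GLY'"] == pytest.approx(float(m.scale), rel=1e-4)


class TestFitMechanics:
    def test_freezing_at_optimum_reproduces_solution(self):
        df = one_way_frame(seed=5)
        fit = reml_fit(METDataset(df), one_way_spec())
        frozen = reml_fit(METDataset(df), one_way_spec(), fix=dict(fit.vc))
        assert np.allclose(
            frozen.fixed_effects.to_numpy(), fit.fixed_effects.to_numpy(), atol=1e-10
        )
        assert np.allclose(frozen.blups.to_numpy(), fit.blups.to_numpy(), atol=1e-10)

    def test_reference_level_invariance(self):
        """The restricted likelihood depends on the fixed column space only."""
        df = one_way_frame(seed=6)
        df["maturity_group"] = np.where(df["variety"].isin(["V1", "V2"]), "MGa", "MGb")
        spec = ModelSpec(
            "oneway-m",
            [FixedTerm("mu"), FixedTerm("M", factors=("maturity_group",))],
            [RandomTerm("G", ("variety",))],
            RandomTerm("GLY'", ("variety", "location")),
        )
        fit1 = reml_fit(METDataset(df), spec)
        df2 = df.copy()
        df2["maturity_group"] = df2["maturity_group"].map({"MGa": "zz", "MGb": "aa"})
        fit2 = reml_fit(METDataset(df2), spec)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-7)
        assert fit1.vc["sigma2_G"] == pytest.approx(fit2.vc["sigma2_G"], abs=1e-7)

    def test_aliased_fixed_design_raises_naming_columns(self):
        df = one_way_frame(seed=7)
        df["maturity_group"] = "onlyone"
        spec = ModelSpec(
            "aliased",
            [
                FixedTerm("mu"),
                FixedTerm("M", factors=("maturity_group",), coding="full"),
            ],
            [RandomTerm("G", ("variety",))],
            RandomTerm("GLY'", ("variety", "location")),
        )
        with pytest.raises(AliasingError, match="aliased"):
            reml_fit(METDataset(df), spec)

    def test_missing_response_rows_dropped(self):
        df = prepare_frame(METDataset(one_way_frame(seed=8)))
        df.loc[0, "value"] = np.nan
        fit = reml_fit(df, one_way_spec())
        assert fit.n_obs == len(df) - 1

    def test_response_decomposition_reproduces_observations(self):
        df = one_way_frame(seed=10)
        fit = reml_fit(METDataset(df), one_way_spec())
        prob, sol = fit.problem, fit.solution
        resid = prob.y - prob.W @ sol.sol
        assert np.allclose(prob.W @ sol.sol + resid, prob.y, atol=1e-12)
        assert np.std(resid) < np.std(prob.y)  # the model explains something

    def test_absorbed_and_plain_paths_agree(self):
        from vcunet import default_network_config, simulate_network
        from vcunet.model import build_model_spec

        cfg = default_network_config(
            "AT", "grain_yield", seed=13, n_years=10, n_new_varieties_per_year=12
        )
        ds, _ = simulate_network(cfg)
        prob = build_problem(prepare_frame(ds), build_model_spec("univariate", "AT"))
        assert prob._absorb is not None
        vc = VarianceComponents(
            {p.name: (0.05 if p.kind == "var" else 0.0) for p in prob.params}
        )
        ab = prob.neg2_restricted_loglik(vc)
        prob._absorb = None
        assert ab == pytest.approx(prob.neg2_restricted_loglik(vc), abs=1e-6)


class TestBlupDifferenceVariance:
    def frozen_fit(self, sg, se, g=6, n=4):
        df = one_way_frame(g=g, n=n, sigma_g=np.sqrt(sg), sigma_e=np.sqrt(se), seed=3)
        return reml_fit(
            METDataset(df), one_way_spec(),
            fix={"sigma2_G": sg, "sigma2_GLY'": se},
        )

    def test_balanced_closed_form_shrinkage(self):
        sg, se, n = 0.8, 0.5, 4
        fit = self.frozen_fit(sg, se, n=n)
        h = sg / (sg + se / n)
        assert blup_diff_variance(fit, "G") == pytest.approx(2 * sg * (1 - h), rel=1e-9)

    def test_vanishing_genetic_variance_limit(self):
        fit = self.frozen_fit(1e-9, 0.5)
        assert blup_diff_variance(fit, "G") < 1e-8

    def test_pair_formula_consistency(self):
        fit = self.frozen_fit(0.8, 0.5, g=2)
        labels = fit.problem.term_labels("G")
        P = fit.solution.inverse_block(labels)
        assert blup_diff_variance(fit, "G") == pytest.approx(
            P[0, 0] + P[1, 1] - 2 * P[0, 1], rel=1e-12
        )

    def test_requires_two_varieties(self):
        df = make_records(
            [("AT", 2003, f"L{j}", "", "M", "V1", "grain_yield", 4.0 + 0.1 * j)
             for j in range(4)]
        )
        fit = reml_fit(
            METDataset(df), one_way_spec(), fix={"sigma2_G": 0.1, "sigma2_GLY'": 0.1}
        )
        with pytest.raises(ValueError, match="two"):
            blup_diff_variance(fit, "G")


class TestLRTAndBH:
    def test_equal_likelihoods_give_p_one(self):
        df = one_way_frame(seed=11)
        fit = reml_fit(METDataset(df), one_way_spec())
        assert lrt_correlation(fit, fit) == pytest.approx(1.0)

    def test_chi2_quantile(self):
        from scipy.stats import chi2

        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_negative_statistic_clamped(self):
        df = one_way_frame(seed=12)
        fit = reml_fit(METDataset(df), one_way_spec())
        better = reml_fit(METDataset(df), one_way_spec(), fix=dict(fit.vc))
        # "constrained" fit with identical likelihood; tiny numeric noise only
        assert lrt_correlation(better, fit) >= 0.99

    def test_non_nested_pair_rejected(self):
        df = one_way_frame(seed=13)
        fit1 = reml_fit(METDataset(df), one_way_spec())
        df2 = two_way_frame(seed=13)
        fit2 = reml_fit(METDataset(df2), two_way_spec())
        with pytest.raises(ValueError, match="nested"):
            lrt_correlation(fit1, fit2)

    def test_bh_step_up_by_hand(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )
        # order-invariance
        assert np.allclose(
            benjamini_hochberg([0.04, 0.01, 0.02]), [0.04, 0.03, 0.03]
        )
        # monotone and bounded by 1
        out = benjamini_hochberg([0.9, 0.95, 0.99])
        assert np.all(out <= 1.0)


class TestCullisBalancedMET:
    def test_full_closed_form_with_gei_terms(self):
        df = balanced_met_frame(g=12, n_l=8, n_y=2)
        prob = build_problem(df, balanced_met_spec())
        vc = VarianceComponents(
            {"sigma2_G": 0.04, "sigma2_GL": 0.0144, "sigma2_GY": 0.018,
             "sigma2_L": 0.2, "sigma2_Y": 0.15, "sigma2_LY": 0.3,
             "sigma2_GLY'": 0.0925}
        )
        sol = prob.factorize(vc)

        class F:
            problem, solution = prob, sol

        vbar = blup_diff_variance(F, "G")
        h2 = 1 - vbar / (2 * 0.04)
        closed = 0.04 / (0.04 + 0.0144 / 8 + 0.018 / 2 + 0.0925 / 16)
        assert h2 == pytest.approx(closed, abs=1e-6)
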