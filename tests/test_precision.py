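import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vcunet import (
    METDataset,
    PrecisionConfig,
    cullis_h2,
    inv_logit,
    lsd,
    lsd_backtransform_logit,
    lsd_percent,
    scenario_grid,
    sed_squared,
    trait_q95,
)

from conftest import make_records


class TestCullisH2:
    def test_perfect_information(self):
        assert cullis_h2(0.04, 0.0) == 1.0

    def test_no_information(self):
        assert cullis_h2(0.04, 2 * 0.04) == 0.0

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert cullis_h2(0.01, 0.5) == 0.0

    def test_nonpositive_genetic_variance_rejected(self):
        with pytest.raises(ValueError):
            cullis_h2(0.0, 0.1)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=1e-6, max_value=10.0),
        st.floats(min_value=0.0, max_value=10.0),
    )
    def test_always_in_unit_interval(self, sg, vbar):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert 0.0 <= cullis_h2(sg, vbar) <= 1.0


class TestSEDSquared:
    VC = {"sigma2_GL": 0.02, "sigma2_GY": 0.03, "sigma2_GLY'": 0.08}

    def test_direct_arithmetic(self):
        cfg = PrecisionConfig(n_L=8, n_Y=2, q95=5.0)
        assert sed_squared(self.VC, cfg) == pytest.approx(0.045, abs=1e-12)

    def test_zero_components_give_zero(self):
        cfg = PrecisionConfig(n_L=8, n_Y=2, q95=5.0)
        vc = {"sigma2_GL": 0.0, "sigma2_GY": 0.0, "sigma2_GLY'": 0.0}
        assert sed_squared(vc, cfg) == 0.0

    def test_missing_component_named(self):
        cfg = PrecisionConfig(q95=5.0)
        with pytest.raises(KeyError, match="sigma2_GY"):
            sed_squared({"sigma2_GL": 0.1, "sigma2_GLY'": 0.1}, cfg)

    def test_plot_level_and_two_stage_forms_agree(self):
        """Separable plot error folded into the three-way term is identical."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            gl, gy, gly, eps = rng.uniform(0.001, 0.5, 4)
            n_l, n_y, n_r = rng.integers(1, 30), rng.integers(1, 8), rng.integers(1, 5)
            cfg = PrecisionConfig(n_L=int(n_l), n_Y=int(n_y), n_R=int(n_r), q95=5.0)
            vc4 = {"sigma2_GL": gl, "sigma2_GY": gy}
            v4 = sed_squared(vc4, cfg, sigma2_GLY=gly, sigma2_eps=eps)
            vc5 = {"sigma2_GL": gl, "sigma2_GY": gy, "sigma2_GLY'": gly + eps / n_r}
            v5 = sed_squared(vc5, cfg)
            assert v4 == pytest.approx(v5, abs=1e-12)

    def test_group_suffix_selection(self):
        cfg = PrecisionConfig(n_L=8, n_Y=2, q95=5.0)
        vc = {"sigma2_GL:AT": 0.02, "sigma2_GY:AT": 0.03, "sigma2_GLY':AT": 0.08}
        assert sed_squared(vc, cfg, group="AT") == pytest.approx(0.045)


class TestLSD:
    def test_default_multiplier_two(self):
        cfg = PrecisionConfig(q95=5.0)
        assert lsd(0.045, cfg) == pytest.approx(2 * np.sqrt(0.045), abs=1e-12)
        assert lsd(0.0, cfg) == 0.0

    def test_exact_t_quantile_vs_constant(self):
        cfg = PrecisionConfig(q95=5.0, use_t_quantile=True, error_df=30)
        assert cfg.multiplier == pytest.approx(2.042, abs=1e-3)
        assert cfg.multiplier / 2.0 == pytest.approx(1.021, abs=1e-3)

    def test_logit_backtransform_at_half(self):
        cfg = PrecisionConfig(q95=0.5)
        # derivative of the inverse logit at mu=0 is exactly 1/4
        assert lsd_backtransform_logit(0.04, 0.0, cfg) == pytest.approx(
            2 * 0.2 * 0.25, abs=1e-12
        )
        assert lsd_backtransform_logit(0.0, 0.3, cfg) == 0.0

    def test_logit_backtransform_matches_numeric_derivative(self):
        cfg = PrecisionConfig(q95=0.5)
        mu = -0.405465
        h = 1e-7
        deriv = (inv_logit(mu + h) - inv_logit(mu - h)) / (2 * h)
        got = lsd_backtransform_logit(0.01, mu, cfg)
        assert got == pytest.approx(2 * np.sqrt(0.01) * deriv, abs=1e-8)

    def test_lsd_percent(self):
        assert lsd_percent(0.4243, 5.0) == pytest.approx(8.486, abs=1e-3)
        assert lsd_percent(0.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            lsd_percent(0.4, 0.0)


class TestTraitQ95:
    def make_ds(self, values):
        rows = [
            ("AT", 2003, f"L{i}", "", "M", f"V{i % 7}", "grain_yield", v)
            for i, v in enumerate(values)
        ]
        return METDataset(make_records(rows))

    def test_linear_interpolation_convention(self):
        ds = self.make_ds(np.arange(1.0, 101.0))
        assert trait_q95(ds, "grain_yield", "AT") == pytest.approx(95.05)

    def test_constant_data(self):
        ds = self.make_ds(np.full(25, 3.3))
        assert trait_q95(ds, "grain_yield") == pytest.approx(3.3)

    def test_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(4, 1, 137)
        ds = self.make_ds(vals)
        s = np.sort(vals)
        h = 0.95 * (len(s) - 1)
        lo = int(np.floor(h))
        oracle = s[lo] + (h - lo) * (s[lo + 1] - s[lo])
        assert trait_q95(ds, "grain_yield") == pytest.approx(oracle, abs=1e-12)

    def test_too_few_observations(self):
        ds = self.make_ds(np.arange(1.0, 11.0))
        with pytest.raises(ValueError, match="few"):
            trait_q95(ds, "grain_yield")


class TestScenarioGrid:
    VC = {"sigma2_GL": 0.0144, "sigma2_GY": 0.018, "sigma2_GLY'": 0.0925}

    def test_monotone_non_increasing_full_grid(self):
        grid = scenario_grid(self.VC, q95=5.5)
        assert len(grid) == 50 * 10
        wide = grid.pivot(index="n_L", columns="n_Y", values="lsd_percent").to_numpy()
        assert np.all(np.diff(wide, axis=0) < 1e-12)  # more locations never worse
        assert np.all(np.diff(wide, axis=1) < 1e-12)  # more years never worse

    def test_all_zero_components_flat_zero_surface(self):
        vc = {"sigma2_GL": 0.0, "sigma2_GY": 0.0, "sigma2_GLY'": 0.0}
        grid = scenario_grid(vc, q95=5.0, n_L_range=range(1, 6), n_Y_range=range(1, 4))
        assert np.allclose(grid["lsd_percent"], 0.0)

    def test_matches_elementwise_recomputation(self):
        grid = scenario_grid(
            self.VC, q95=5.5, n_L_range=range(2, 12, 3), n_Y_range=range(1, 4)
        )
        for _, row in grid.iterrows():
            cfg = PrecisionConfig(n_L=int(row.n_L), n_Y=int(row.n_Y), q95=5.5)
            s2 = sed_squared(self.VC, cfg)
            assert row.lsd_percent == pytest.approx(
                lsd_percent(lsd(s2, cfg), 5.5), abs=1e-12
            )

    def test_unit_invariance(self):
        """Rescaling the trait rescales components by c^2 and q95 by c."""
        c = 3.7
        vc_scaled = {k: v * c * c for k, v in self.VC.items()}
        g1 = scenario_grid(self.VC, q95=5.5, n_L_range=range(1, 5), n_Y_range=range(1, 3))
        g2 = scenario_grid(vc_scaled, q95=5.5 * c, n_L_range=range(1, 5), n_Y_range=range(1, 3))
        assert np.allclose(g1["lsd_percent"], g2["lsd_percent"])
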