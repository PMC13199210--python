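import dataclasses

import numpy as np
import pytest
from scipy import stats

from vcunet import (
    DualSimConfig,
    NetworkSimConfig,
    default_dual_config,
    default_network_config,
    median_offdiagonal_overlap,
    overlap_matrix,
    simulate_dual_network,
    simulate_network,
)
from vcunet.simulate import ConfigError


def small_cfg(**kw):
    base = dict(
        n_years=6, locations_per_year=3, n_new_varieties_per_year=3,
        n_checks=1, mu=4.0, beta=0.0, gamma=0.0, variances={}, seed=0,
    )
    base.update(kw)
    return NetworkSimConfig(**base)


class TestSingleNetwork:
    def test_deterministic_limit_all_records_equal_mu(self):
        ds, _ = simulate_network(small_cfg())
        assert np.allclose(ds.records["value"], 4.0)

    def test_same_seed_bitwise_identical(self):
        cfg = small_cfg(variances={"G": 0.05, "LY": 0.1, "GLY'": 0.08}, seed=42)
        ds1, t1 = simulate_network(cfg)
        ds2, t2 = simulate_network(cfg)
        assert ds1.records.equals(ds2.records)
        assert t1.effects == t2.effects

    def test_named_streams_isolated_across_terms(self):
        """Adding one term's variance must not perturb another's draws."""
        a, _ = simulate_network(small_cfg(variances={"G": 0.05}, seed=7))
        b, _ = simulate_network(small_cfg(variances={"G": 0.05, "L": 0.2}, seed=7))
        # G contribution identical: per-variety mean differences shift only by L
        ga = a.records.groupby("variety")["value"].mean()
        gb = b.records.groupby("variety")["value"].mean()
        assert np.allclose((gb - ga) - (gb - ga).mean(), 0.0, atol=1e-12)

    def test_genotypic_variance_within_chisq_band(self):
        """Sample variance of 500 genotypic draws stays in its 95% band."""
        cfg = small_cfg(
            n_years=1, n_new_varieties_per_year=499, n_checks=1,
            variances={"G": 1.0}, seed=3,
        )
        ds, truth = simulate_network(cfg)
        g = np.array(list(truth.effects["G"].values()))
        s2 = np.var(g, ddof=1)
        n = len(g)
        lo = stats.chi2.ppf(0.025, n - 1) / (n - 1)
        hi = stats.chi2.ppf(0.975, n - 1) / (n - 1)
        assert lo <= s2 <= hi
        assert 0.88 <= s2 <= 1.13

    def test_trend_and_cycle_structure(self):
        cfg = small_cfg(beta=0.1, variances={}, seed=0)
        ds, _ = simulate_network(cfg)
        # a cohort entering in year k carries beta * k exactly
        df = ds.records
        entry = df.groupby("variety")["year"].min() - 2003
        for v, e in entry.items():
            assert np.allclose(df[df.variety == v]["value"], 4.0 + 0.1 * e)
        # every non-check tested exactly test_cycle_len years (unless truncated)
        spans = df.groupby("variety")["year"].nunique()
        non_checks = [v for v in spans.index if "CHK" not in v]
        assert all(spans[v] <= cfg.test_cycle_len for v in non_checks)

    def test_diagonal_occurrence_structure(self):
        cfg = default_network_config("AT", "grain_yield", seed=1)
        ds, _ = simulate_network(cfg)
        om = overlap_matrix(ds).to_numpy()
        years = om.shape[0]
        adj = np.mean([om[k, k + 1] for k in range(years - 1)])
        far = np.mean([om[k, k + 5] for k in range(years - 5)])
        assert adj > far  # high adjacent-year, low distant-year overlap
        # checks keep distant years connected
        assert om[0, years - 1] >= cfg.n_checks

    def test_impossible_connectivity_rejected(self):
        with pytest.raises(ConfigError, match="disconnected"):
            NetworkSimConfig(
                n_years=6, locations_per_year=3, n_new_varieties_per_year=2,
                n_checks=0, variances={},
            )

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigError):
            small_cfg(variances={"G": -0.1})

    def test_protein_content_stored_as_fraction(self):
        cfg = default_network_config("AT", "protein_content", seed=2)
        ds, _ = simulate_network(cfg)
        v = ds.records["value"]
        assert ((v > 0) & (v < 1)).all()
        assert 0.2 < v.median() < 0.6


class TestDualNetwork:
    def make(self, rho_G, shared, seed=0, n_new=30, **kw):
        c1 = small_cfg(
            country="AT", n_new_varieties_per_year=n_new,
            variances={"G": 0.04, "GLY'": 0.01}, variety_prefix="A",
        )
        c2 = small_cfg(
            country="FR", n_new_varieties_per_year=n_new,
            variances={"G": 0.04, "GLY'": 0.01}, variety_prefix="F",
        )
        return DualSimConfig(
            config1=c1, config2=c2, rho_G=rho_G, rho_Y=0.0, rho_GY=0.0,
            shared_varieties=shared, seed=seed, **kw,
        )

    def shared_g_pairs(self, truth, shared_names):
        return np.array([truth.effects["G"][v] for v in shared_names])

    def test_perfect_correlation_equal_variances(self):
        dual = self.make(rho_G=1.0, shared=20, seed=5)
        ds, truth = simulate_dual_network(dual)
        G = np.array(list(truth.effects["G"].values()))
        assert np.allclose(G[:, 0], G[:, 1], atol=1e-10)

    def test_zero_correlation_fisher_band(self):
        dual = self.make(rho_G=0.0, shared=20, seed=6, n_new=67)  # ~400 varieties
        ds, truth = simulate_dual_network(dual)
        G = np.array(list(truth.effects["G"].values()))
        r = np.corrcoef(G[:, 0], G[:, 1])[0, 1]
        assert -0.2 < r < 0.2

    def test_intermediate_correlation_fisher_interval(self):
        dual = self.make(rho_G=0.8, shared=20, seed=7, n_new=34)  # ~200 varieties
        ds, truth = simulate_dual_network(dual)
        G = np.array(list(truth.effects["G"].values()))
        n = len(G)
        r = np.corrcoef(G[:, 0], G[:, 1])[0, 1]
        z, z0 = np.arctanh(r), np.arctanh(0.8)
        assert abs(z - z0) < 1.96 / np.sqrt(n - 3)

    def test_shared_varieties_present_in_both_countries(self):
        dual = self.make(rho_G=0.5, shared=10, seed=8)
        ds, _ = simulate_dual_network(dual)
        df = ds.records
        both = set(df[df.country == "AT"].variety) & set(df[df.country == "FR"].variety)
        assert len(both) == 10

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ConfigError, match="PSD"):
            self.make(rho_G=1.5, shared=5)

    def test_excess_shared_varieties_rejected(self):
        with pytest.raises(ConfigError, match="shared_varieties"):
            dual = self.make(rho_G=0.5, shared=10_000)
            simulate_dual_network(dual)


def test_default_presets_are_study_sized():
    at = default_network_config("AT", "grain_yield")
    fr = default_network_config("FR", "grain_yield")
    assert at.n_years == fr.n_years == 16
    assert at.locations_per_year == 8 and fr.locations_per_year == 10
    assert fr.subtrial_by_maturity and not at.subtrial_by_maturity
    ds, _ = simulate_network(dataclasses.replace(at, seed=11))
    # roughly the study's variety count and a small median between-year overlap
    assert 70 <= len(ds.varieties) <= 90
    assert median_offdiagonal_overlap(overlap_matrix(ds)) <= 12
    dual = default_dual_config("grain_yield")
    assert dual.rho_G > 0.7
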