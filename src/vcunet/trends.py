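"""Genetic and environmental trend estimation and variance summaries.

The genetic trend is the fixed regression coefficient beta on a variety's
first year of appearance (FYOA, a surrogate for its first year of testing);
the environmental (agronomic/climatic) trend gamma is the regression on the
trial year.  Both are identifiable simultaneously because varieties are
tested in several calendar years, so r_i and t_k differ within varieties.
Relative trends (% per year) are expressed against the model-predicted
trait mean at the reference year.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import METDataset, inv_logit
from .model import ModelSpec, build_model_spec
from scipy.stats import t as t_dist

from .reml import FitResult, prepare_frame, reml_fit, satterthwaite_df, wald_p


@dataclasses.dataclass
class TrendEstimate:
    absolute: float  # trait units per year, on the reporting scale
    se: float
    p_value: float
    relative: float  # % per year
    reference_mean: float  # trait units at the reference year
    significant: bool
    scale: str = "raw"


def _reference_mean_linear(fit: FitResult) -> float:
    """Model-predicted mean at t = r = 0, averaged over maturity groups.

    With drop-first coding the omitted group contributes 0, so the average
    runs over all groups including the reference.
    """
    fe = fit.fixed_effects
    mu = float(fe["mu"]) if "mu" in fe.index else 0.0
    m_cols = [c for c in fe.index if c.startswith("M[")]
    n_groups = len(m_cols) + 1  # + reference level
    m_avg = float(sum(fe[c] for c in m_cols)) / n_groups if n_groups > 1 else 0.0
    return mu + m_avg


def _trend(fit: FitResult, coef: str, on_logit: bool, alpha: float) -> TrendEstimate:
    if coef not in fit.fixed_effects.index:
        raise ValueError(
            f"fit has no '{coef}' coefficient; the genetic trend requires "
            "variety turnover (otherwise beta is confounded with gamma)"
        )
    b = float(fit.fixed_effects[coef])
    se = float(fit.fixed_se[coef])
    # t reference with Satterthwaite df: the trend's replication is the
    # number of years, and the plug-in normal reference over-rejects when
    # the year variance is estimated near its boundary
    df = satterthwaite_df(fit, coef)
    if np.isfinite(df):
        p = float(2.0 * t_dist.sf(abs(b) / se, df)) if se > 0 else float("nan")
    else:
        p = wald_p(b, se)
    ref_lin = _reference_mean_linear(fit)
    if on_logit:
        mu_p = inv_logit(ref_lin)
        deriv = mu_p * (1.0 - mu_p)
        absolute, se_abs, ref = b * deriv, se * deriv, mu_p
        scale = "logit-backtransformed"
    else:
        absolute, se_abs, ref = b, se, ref_lin
        scale = "raw"
    if ref <= 0:
        raise ValueError("reference mean must be positive for a relative trend")
    return TrendEstimate(
        absolute=absolute,
        se=se_abs,
        p_value=p,
        relative=100.0 * absolute / ref,
        reference_mean=ref,
        significant=bool(p < alpha),
        scale=scale,
    )


def genetic_trend(fit: FitResult, on_logit: bool = False, alpha: float = 0.05) -> TrendEstimate:
    """Genetic gain per year from the FYOA regression coefficient.

    Wald test on the fixed coefficient; for traits analysed on the logit
    scale the estimate is back-transformed by the delta method before the
    relative trend is formed.
    """
    return _trend(fit, "beta", on_logit, alpha)


def environmental_trend(
    fit: FitResult, on_logit: bool = False, alpha: float = 0.05
) -> TrendEstimate:
    """Non-genetic (agronomic/climatic) trend per trial year."""
    return _trend(fit, "gamma", on_logit, alpha)


GENOTYPIC_TERMS = ("G", "GL", "GY", "GLY'")


def variance_partition(vc, group: str | None = None) -> dict[str, float]:
    """Each genotypic component as a proportion of their sum."""
    suffix = "" if group is None else f":{group}"
    comps = {}
    for t in GENOTYPIC_TERMS:
        key = f"sigma2_{t}{suffix}"
        if key not in vc:
            raise KeyError(f"missing component {key}")
        comps[t] = float(vc[key])
    total = sum(comps.values())
    if total <= 0:
        raise ValueError("all genotypic components are zero")
    return {t: v / total for t, v in comps.items()}


def cv_percent(sigma2: float, mu: float, on_logit: bool = False) -> float:
    """Coefficient of variation, 100 * sd / intercept.

    For traits analysed on the logit scale the ratio is formed on that
    scale against the intercept magnitude (the convention implied by the
    reported protein-content CVs); see also
    :func:`cv_percent_backtransformed` for the delta-method raw-scale CV.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    denom = abs(mu) if on_logit else mu
    if denom <= 0:
        raise ValueError("intercept must be nonzero/positive for a CV")
    return 100.0 * float(np.sqrt(sigma2)) / denom


def cv_percent_backtransformed(sigma2_logit: float, mu_logit: float) -> float:
    """Raw-scale CV for a logit-analysed trait via the delta method."""
    mu_p = inv_logit(mu_logit)
    sd_raw = np.sqrt(sigma2_logit) * mu_p * (1.0 - mu_p)
    return 100.0 * float(sd_raw) / mu_p


def variety_means_fixed(
    dataset: METDataset,
    country_layout: str = "AT",
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Per-variety adjusted means from the MET model with a fixed variety effect.

    The genetic-trend covariate is dropped (it is a linear function of the
    variety dummies); means are evaluated at the average trial year and
    back-transformed for protein content.  Varieties with very weak
    connectivity surface through large standard errors rather than being
    dropped.
    """
    spec = spec or build_model_spec("fixed_variety", country_layout)
    df = prepare_frame(dataset)
    fit = reml_fit(df, spec)
    fe, prob, sol = fit.fixed_effects, fit.problem, fit.solution
    t_bar = float(df["_t"].mean())
    on_logit = bool((df["trait"] == "protein_content").all()) and len(df) > 0

    cov = sol.inverse_block(prob.x_names)
    name_idx = {n: i for i, n in enumerate(prob.x_names)}
    mg_of = df.drop_duplicates("variety").set_index("variety")["maturity_group"]
    rows = []
    for v in sorted(df["variety"].unique()):
        c = np.zeros(len(prob.x_names))
        c[name_idx["mu"]] = 1.0
        if "gamma" in name_idx:
            c[name_idx["gamma"]] = t_bar
        mkey = f"M[{mg_of[v]}]"
        if mkey in name_idx:
            c[name_idx[mkey]] = 1.0
        gkey = f"G[{v}]"
        if gkey in name_idx:  # reference variety has no column
            c[name_idx[gkey]] = 1.0
        est = float(c @ fe.to_numpy())
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        if on_logit:
            mu_p = inv_logit(est)
            est, se = mu_p, se * mu_p * (1.0 - mu_p)
        rows.append((v, dataset.fyoa[v], est, se))
    return pd.DataFrame(rows, columns=["variety", "fyoa", "adjusted_mean", "se"])
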