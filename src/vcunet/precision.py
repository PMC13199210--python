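"""Heritability and trial-network precision (SED / LSD calculus).

Precision of a variety-testing network is summarized by the least
significant difference between two variety means after a full test cycle,

    sed^2 = 2 (s2_GL/n_L + s2_GY/n_Y + s2_GLY'/(n_L n_Y)),
    LSD   = t_{alpha/2} * sqrt(sed^2)  ~=  2 * sqrt(sed^2),

where s2_GLY' is the three-way interaction confounded with the stage-one
plot error.  When a separable plot-error variance is available the
plot-level form with s2_GLY/(n_L n_Y) + s2_eps/(n_L n_Y n_R) is algebraically
identical after folding s2_eps/n_R into s2_GLY'.  LSD is reported as a
percentage of the trait's empirical 0.95 quantile so that it reads as the
margin a candidate must beat a top variety by to be declared different.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .data import METDataset, inv_logit


@dataclasses.dataclass
class PrecisionConfig:
    """Test-cycle dimensions and LSD conventions.

    ``lsd_multiplier`` defaults to the constant 2 (the usual approximation
    to t_{alpha/2}); pass ``use_t_quantile=True`` with ``error_df`` for the
    exact quantile.
    """

    n_L: int = 8
    n_Y: int = 2
    n_R: int = 2
    alpha: float = 0.05
    q95: float = 5.0
    use_t_quantile: bool = False
    error_df: int | None = None

    def __post_init__(self):
        if self.n_L < 1 or self.n_Y < 1:
            raise ValueError("n_L and n_Y must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.q95 <= 0:
            raise ValueError("q95 must be positive")

    @property
    def multiplier(self) -> float:
        if self.use_t_quantile:
            if self.error_df is None:
                raise ValueError("error_df required for the exact t quantile")
            return float(t_dist.ppf(1.0 - self.alpha / 2.0, self.error_df))
        return 2.0


@dataclasses.dataclass
class LSDResult:
    sed2: float
    lsd: float
    lsd_percent: float
    scale: str = "raw"  # or "logit-backtransformed"


def cullis_h2(sigma2_G: float, vbar_delta: float) -> float:
    """Generalized heritability 1 - vbar/(2 s2_G), clamped to [0, 1].

    ``vbar_delta`` is the average variance of a difference between two
    varieties' BLUPs; the measure accounts for unequal BLUP accuracies in
    unbalanced data and reduces to the classic entry-mean heritability in
    balanced settings.
    """
    if sigma2_G <= 0:
        raise ValueError("sigma2_G must be positive")
    if vbar_delta < 0:
        raise ValueError("vbar_delta must be non-negative")
    h2 = 1.0 - vbar_delta / (2.0 * sigma2_G)
    if h2 < 0.0 or h2 > 1.0:
        warnings.warn(f"Cullis H2 = {h2:.4f} outside [0, 1]; clamped", stacklevel=2)
    return float(np.clip(h2, 0.0, 1.0))


def sed_squared(
    vc,
    cfg: PrecisionConfig,
    *,
    sigma2_GLY: float | None = None,
    sigma2_eps: float | None = None,
    group: str | None = None,
) -> float:
    """Variance of a difference between two variety means over a test cycle.

    ``vc`` is a mapping with ``sigma2_GL``, ``sigma2_GY`` and either
    ``sigma2_GLY'`` or a separable pair (``sigma2_GLY``, ``sigma2_eps``)
    passed explicitly, in which case the plot error is divided by
    ``n_L * n_Y * n_R``.  ``group`` selects per-group components
    (``sigma2_GL:<group>`` ...) from multi-group fits.
    """
    suffix = "" if group is None else f":{group}"
    def get(name):
        key = f"sigma2_{name}{suffix}"
        if key not in vc:
            raise KeyError(f"variance component '{key}' missing")
        return float(vc[key])

    s_gl, s_gy = get("GL"), get("GY")
    if sigma2_GLY is not None or sigma2_eps is not None:
        if sigma2_GLY is None or sigma2_eps is None:
            raise ValueError("need both sigma2_GLY and sigma2_eps")
        tail = sigma2_GLY / (cfg.n_L * cfg.n_Y) + sigma2_eps / (
            cfg.n_L * cfg.n_Y * cfg.n_R
        )
    else:
        tail = get("GLY'") / (cfg.n_L * cfg.n_Y)
    return 2.0 * (s_gl / cfg.n_L + s_gy / cfg.n_Y + tail)


def lsd(sed2: float, cfg: PrecisionConfig) -> float:
    """Least significant difference in trait units."""
    if sed2 < 0:
        raise ValueError("sed2 must be non-negative")
    return cfg.multiplier * float(np.sqrt(sed2))


def lsd_backtransform_logit(sed2: float, mu_logit: float, cfg: PrecisionConfig) -> float:
    """LSD on the fraction scale for a trait analysed on the logit scale.

    Applies the delta method: the derivative of the inverse logit at the
    back-transformed intercept, mu_p (1 - mu_p), converts the logit-scale
    LSD to the proportion scale.
    """
    mu_p = inv_logit(mu_logit)
    return lsd(sed2, cfg) * mu_p * (1.0 - mu_p)


def lsd_percent(lsd_value: float, q95: float) -> float:
    """LSD as a percentage of the trait's 0.95 quantile."""
    if q95 <= 0:
        raise ValueError("q95 must be positive")
    return 100.0 * lsd_value / q95


def lsd_result(
    vc, cfg: PrecisionConfig, *, mu_logit: float | None = None, group: str | None = None
) -> LSDResult:
    """SED^2, LSD, LSD% in one go; logit back-transform when mu_logit given."""
    s2 = sed_squared(vc, cfg, group=group)
    if mu_logit is not None:
        l = lsd_backtransform_logit(s2, mu_logit, cfg)
        scale = "logit-backtransformed"
    else:
        l = lsd(s2, cfg)
        scale = "raw"
    return LSDResult(sed2=s2, lsd=l, lsd_percent=lsd_percent(l, cfg.q95), scale=scale)


def trait_q95(dataset: METDataset, trait: str, country: str | None = None) -> float:
    """Empirical 0.95 quantile of the variety-by-trial means (raw scale).

    Linear-interpolation quantile convention; protein content is already a
    fraction in the records, so no back-transform is needed here.
    """
    df = dataset.records
    vals = df.loc[
        (df["trait"] == trait)
        & ((df["country"] == country) if country is not None else True),
        "value",
    ].to_numpy()
    if len(vals) < 20:
        raise ValueError(f"too few observations ({len(vals)}) for a stable quantile")
    return float(np.quantile(vals, 0.95))


def scenario_grid(
    vc,
    q95: float,
    n_L_range=range(1, 51),
    n_Y_range=range(1, 11),
    *,
    mu_logit: float | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """LSD% over a grid of alternative network configurations.

    Long-format table (n_L, n_Y, sed2, lsd, lsd_percent); LSD% is
    non-increasing along each axis whenever the corresponding component is
    positive.
    """
    rows = []
    for n_l in n_L_range:
        for n_y in n_Y_range:
            cfg = PrecisionConfig(n_L=int(n_l), n_Y=int(n_y), q95=q95)
            r = lsd_result(vc, cfg, mu_logit=mu_logit, group=group)
            rows.append((int(n_l), int(n_y), r.sed2, r.lsd, r.lsd_percent))
    return pd.DataFrame(rows, columns=["n_L", "n_Y", "sed2", "lsd", "lsd_percent"])
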