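"""Precision gains from merging two national trial networks.

When the genotypic (G), year (Y) and genotype-by-year (GY) effects of two
networks are correlated, a joint mixed model lets a variety tested in one
network borrow information from the other.  The gain is quantified on a
constructed, fully balanced two-country design (default 10 locations, 2
years, 2 replicates per country): variance components and correlations are
frozen at values estimated from the combined-country model, the mixed-model
equations are assembled once, and pairwise SEDs of random genotypic effects
are read off the generalized inverse of the coefficient matrix — once with
the estimated correlations active and once with them zeroed (the
status-quo of separate national analyses).

Eight comparison scenarios distinguish where the two varieties of a pair
were tested and in which network the comparison is wanted:

  i, ii    both varieties in both networks; focal network 1 / 2
  iii, iv  both varieties only in network 1; focal network 1 / 2
  v, vi    both varieties only in network 2; focal network 1 / 2
  vii, viii one variety in each network; focal network 1 / 2

With all cross-network correlations zero, (i) equals (iii) and (ii) equals
(vi) exactly, because no information flows between networks in a balanced
design.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .model import FixedTerm, ModelSpec, RandomTerm
from .reml import VarianceComponents, build_problem

SCENARIOS = {
    "i": ("both", "both", 0),
    "ii": ("both", "both", 1),
    "iii": ("only1", "only1", 0),
    "iv": ("only1", "only1", 1),
    "v": ("only2", "only2", 0),
    "vi": ("only2", "only2", 1),
    "vii": ("only1", "only2", 0),
    "viii": ("only1", "only2", 1),
}


@dataclasses.dataclass
class MergeScenario:
    id: str
    membership: tuple[str, str]  # membership class of each variety of the pair
    focal: str  # country label

    @classmethod
    def standard(cls, sid: str, countries) -> "MergeScenario":
        m1, m2, focal_idx = SCENARIOS[sid]
        return cls(id=sid, membership=(m1, m2), focal=countries[focal_idx])


@dataclasses.dataclass
class MergeResult:
    table: pd.DataFrame  # one row per scenario

    def improvement(self, sid: str) -> float:
        row = self.table.set_index("scenario").loc[sid]
        return float(row["improvement_pp"])


def build_balanced_merged_design(
    varieties_net1,
    varieties_net2,
    countries=("AT", "FR"),
    n_L: int = 10,
    n_Y: int = 2,
    n_R: int = 2,
    start_year: int = 2003,
    trait: str = "grain_yield",
) -> pd.DataFrame:
    """Fully balanced two-country design rows for the merge computation.

    Every variety of a network's list occurs in all of that network's
    locations, years and replicates.  The replicate index is carried so a
    separable plot error can be represented when available; computations
    based on two-stage components collapse replicates to means first.
    """
    v1, v2 = list(varieties_net1), list(varieties_net2)
    if not v1 and not v2:
        raise ValueError("both membership lists are empty")
    orphan = [v for v in set(v1) | set(v2) if v not in v1 and v not in v2]
    if orphan:
        raise ValueError(f"varieties in neither network: {orphan}")
    rows = []
    for country, vlist in zip(countries, (v1, v2)):
        for v in vlist:
            for j in range(n_L):
                for k in range(n_Y):
                    for r in range(n_R):
                        rows.append(
                            (
                                country, start_year + k, f"{country}_L{j + 1:02d}",
                                "", "MG", v, trait, 0.0, r + 1,
                            )
                        )
    df = pd.DataFrame(
        rows,
        columns=[
            "country", "year", "location", "subtrial", "maturity_group",
            "variety", "trait", "value", "rep",
        ],
    )
    return df


def _merged_spec(with_plot_error: bool) -> ModelSpec:
    """Joint two-country model on the constructed design.

    A single maturity group and no subtrials make M, ML/MY, MLY and S(LY)
    level-wise redundant with the intercept and LY, so the term list
    reduces to the environment terms, the correlated G/Y/GY blocks, and the
    country-specific residual.  The shared genetic-trend covariate is
    dropped because r_i = 0 for every variety in the constructed design.
    """
    random = [
        RandomTerm("L", ("country", "location"), "group_diag", group="country"),
        RandomTerm("Y", ("year_f",), "us2", group="country"),
        RandomTerm("LY", ("country", "location", "year_f"), "group_diag", group="country"),
        RandomTerm("G", ("variety",), "us2", group="country"),
        RandomTerm("GY", ("variety", "year_f"), "us2", group="country"),
    ]
    if with_plot_error:
        random.append(
            RandomTerm("GLY'", ("country", "variety", "location", "year_f"),
                       "group_diag", group="country")
        )
        residual = RandomTerm("eps", ("country", "variety", "location", "year_f", "rep_f"),
                              "group_diag", group="country")
    else:
        residual = RandomTerm("GLY'", ("country", "variety", "location", "year_f"),
                              "group_diag", group="country")
    fixed = [
        FixedTerm("mu", factors=("country",), coding="full"),
        FixedTerm("gamma", factors=("country",), covariate="_t", coding="full"),
    ]
    return ModelSpec("merged-balanced", fixed, random, residual)


def _required_vc(problem, vc, zero_correlations: bool) -> VarianceComponents:
    out = VarianceComponents()
    for name in problem.param_names:
        if name not in vc:
            raise KeyError(f"variance component '{name}' missing for the merge")
        out[name] = float(vc[name])
        if name.startswith("rho_"):
            # a correlation estimated exactly at 1 would make the genetic
            # covariance singular; back off to the representable boundary
            out[name] = float(np.clip(out[name], -0.999999, 0.999999))
            if zero_correlations and name in ("rho_G", "rho_Y", "rho_GY"):
                out[name] = 0.0
    return out


def pairwise_sed_fixed_vc(
    design: pd.DataFrame,
    vc,
    *,
    zero_correlations: bool = False,
    with_plot_error: bool = False,
):
    """Pairwise SED matrix of genotypic effects per focal network.

    Returns ``(countries, varieties, sed)`` where ``sed[p]`` is the
    len(varieties) x len(varieties) SED matrix for focal country ``p``,
    from the G block of the generalized inverse of the MME coefficient
    matrix with components frozen at ``vc``.  ``zero_correlations`` zeroes
    rho_G, rho_Y and rho_GY (separate-network counterfactual).
    """
    df = design.copy()
    if with_plot_error:
        df["rep_f"] = df["rep"].astype(str)
    else:
        df = (
            df.groupby(
                ["country", "year", "location", "subtrial", "maturity_group",
                 "variety", "trait"],
                as_index=False,
            )["value"].mean()
        )
    df["_t"] = (df["year"] - df["year"].min()).astype(float)
    df["_r"] = 0.0
    df["year_f"] = df["year"].astype(str)
    spec = _merged_spec(with_plot_error)
    prob = build_problem(df.reset_index(drop=True), spec)
    use = _required_vc(prob, vc, zero_correlations)
    sol = prob.factorize(use)
    if sol is None or not sol.ok:
        raise ValueError("singular coefficient matrix in the merged design")
    countries = sorted(df["country"].unique())
    varieties = sorted(df["variety"].unique())
    seds = {}
    for p in countries:
        labels = [f"G[{p}:{v}]" for v in varieties]
        P = sol.inverse_block(labels)
        d = np.diag(P)
        seds[p] = np.sqrt(np.maximum(d[:, None] + d[None, :] - 2.0 * P, 0.0))
    return countries, varieties, seds


def merge_comparison(
    vc,
    q95_by_country: dict[str, float],
    *,
    countries=("AT", "FR"),
    n_per_class: int = 10,
    n_L: int = 10,
    n_Y: int = 2,
    n_R: int = 2,
    scenarios=tuple(SCENARIOS),
) -> MergeResult:
    """Average pairwise LSD% per scenario, correlated vs zero-correlation.

    Builds the balanced merged design with ``n_per_class`` varieties in
    each membership class (both networks / only network 1 / only network
    2), computes average pairwise LSD% (multiplier 2, normalized by the
    focal network's 0.95 quantile) under the estimated correlations and
    under the zeroed counterfactual, and reports the improvement in
    percentage points.
    """
    both = [f"B{i + 1:02d}" for i in range(n_per_class)]
    only1 = [f"O1_{i + 1:02d}" for i in range(n_per_class)]
    only2 = [f"O2_{i + 1:02d}" for i in range(n_per_class)]
    classes = {"both": both, "only1": only1, "only2": only2}
    design = build_balanced_merged_design(
        both + only1, both + only2, countries=countries, n_L=n_L, n_Y=n_Y, n_R=n_R
    )
    _, varieties, sed_corr = pairwise_sed_fixed_vc(design, vc, zero_correlations=False)
    _, _, sed_zero = pairwise_sed_fixed_vc(design, vc, zero_correlations=True)
    vidx = {v: i for i, v in enumerate(varieties)}

    rows = []
    for sid in scenarios:
        sc = MergeScenario.standard(sid, countries)
        set1, set2 = classes[sc.membership[0]], classes[sc.membership[1]]
        if sc.membership[0] == sc.membership[1]:
            pairs = list(itertools.combinations(set1, 2))
        else:
            pairs = [(a, b) for a in set1 for b in set2]
        q95 = q95_by_country[sc.focal]

        def avg_lsd_pct(sed):
            vals = [
                100.0 * 2.0 * sed[sc.focal][vidx[a], vidx[b]] / q95 for a, b in pairs
            ]
            return float(np.mean(vals))

        l_corr = avg_lsd_pct(sed_corr)
        l_zero = avg_lsd_pct(sed_zero)
        rows.append((sid, sc.focal, len(pairs), l_corr, l_zero, l_zero - l_corr))
    table = pd.DataFrame(
        rows,
        columns=[
            "scenario", "focal", "n_pairs", "lsd_pct_correlated",
            "lsd_pct_zero_corr", "improvement_pp",
        ],
    )
    return MergeResult(table=table)
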