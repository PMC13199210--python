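"""Synthetic multi-environment trial (MET) generators.

Emulates the stochastic structure of national variety-testing (VCU)
networks: varieties enter in annual cohorts, stay for a short test cycle
(typically two years), and long-running check varieties provide
connectivity across years — producing the characteristic "diagonal"
variety-occurrence structure.  Trait values follow the additive mixed model
used for analysis,

    z = mu + gamma*t + L + Y + LY + [S(LY)] + M + G + beta*r
        + GL + GY + [ML + MY] + MLY + GLY'

with every random term drawn i.i.d. normal at its configured variance.
``GLY'`` — the three-way interaction confounded with the plot error of the
stage-one means — is drawn as a single normal term, because the analysis
model never separates the two.  A dual-network generator draws the G, Y and
GY effects jointly bivariate-normal across two countries with configurable
correlations, matching the structure assumed when two networks are merged.

Every generator consumes one named substream per model term, split from a
master seed, so the draws of one term do not shift when another term's
level count changes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data import METDataset, inv_logit

#: stable substream index per model term (do not reorder)
TERM_STREAMS = {
    "L": 0,
    "Y": 1,
    "LY": 2,
    "S(LY)": 3,
    "M": 4,
    "G": 5,
    "GL": 6,
    "GY": 7,
    "ML": 8,
    "MY": 9,
    "MLY": 10,
    "GLY'": 11,
    "assign": 12,
}


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class NetworkSimConfig:
    """Study conditions for a single national trial network.

    Defaults correspond to the variance magnitudes and layout of an
    Austrian-style grain-yield network (16 trial years, 8 locations per
    year, two-year test cycles, persistent checks); see
    :func:`default_network_config` for per-country/per-trait presets.
    """

    country: str = "AT"
    trait: str = "grain_yield"
    n_years: int = 16
    start_year: int = 2003
    locations_per_year: int | Sequence[int] = 8
    n_new_varieties_per_year: int = 5
    test_cycle_len: int = 2
    n_checks: int = 2
    maturity_groups: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"early": 0.5, "medium_early": 0.5}
    )
    subtrial_by_maturity: bool = False  # FR layout: maturity confounded with subtrial
    mu: float = 4.0
    beta: float = 0.079  # genetic trend, trait units / year
    gamma: float = 0.0  # environmental (agronomic) trend, trait units / year
    variances: dict[str, float] = dataclasses.field(default_factory=dict)
    balanced: bool = False  # all varieties in all years/locations (no cohorts)
    seed: int = 0
    variety_prefix: str = "V"

    def __post_init__(self):
        for k, v in self.variances.items():
            if k not in TERM_STREAMS:
                raise ConfigError(f"unknown variance term '{k}'")
            if v < 0:
                raise ConfigError(f"negative variance for {k}")
        if self.test_cycle_len < 1:
            raise ConfigError("test_cycle_len must be >= 1")
        if not self.balanced and self.n_checks < 1 and self.n_years > self.test_cycle_len:
            raise ConfigError(
                "no checks and disjoint cohorts: the network would be "
                "disconnected across years"
            )
        probs = np.array(list(self.maturity_groups.values()), float)
        if len(probs) == 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("maturity group probabilities must sum to 1")

    def locations_for_year(self, k: int) -> int:
        if isinstance(self.locations_per_year, int):
            return self.locations_per_year
        return int(self.locations_per_year[k])

    @property
    def max_locations(self) -> int:
        if isinstance(self.locations_per_year, int):
            return self.locations_per_year
        return int(max(self.locations_per_year))


@dataclasses.dataclass
class DualSimConfig:
    """Two national networks whose G, Y and GY effects are correlated."""

    config1: NetworkSimConfig
    config2: NetworkSimConfig
    rho_G: float = 0.85
    rho_Y: float = 0.6
    rho_GY: float = 0.7
    shared_varieties: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("rho_G", "rho_Y", "rho_GY"):
            if abs(getattr(self, name)) > 1:
                raise ConfigError(f"{name} outside [-1, 1]: covariance block not PSD")
        if self.config1.n_years != self.config2.n_years or (
            self.config1.start_year != self.config2.start_year
        ):
            raise ConfigError("both networks must share the same trial calendar")
        if self.config1.country == self.config2.country:
            raise ConfigError("the two networks need distinct country labels")


@dataclasses.dataclass
class TruthRecord:
    """All drawn effects, keyed by term and level, plus the config used."""

    config: dict
    effects: dict[str, dict]

    def to_json_dict(self) -> dict:
        return {"config": self.config, "effects": self.effects}


def _rng(seed: int, term: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), TERM_STREAMS[term], extra])


def _chol2(s1: float, s2: float, rho: float) -> np.ndarray:
    """Exact lower Cholesky of a 2x2 correlation-scaled covariance.

    Analytic form stays exact at the degenerate boundaries rho = +/-1
    and at zero standard deviations.
    """
    return np.array([[s1, 0.0], [rho * s2, s2 * np.sqrt(max(0.0, 1.0 - rho**2))]])


def _roster(cfg: NetworkSimConfig):
    """Variety -> (entry year index, list of active year indices)."""
    roster: dict[str, list[int]] = {}
    entry: dict[str, int] = {}
    if cfg.balanced:
        n_tot = cfg.n_checks + cfg.n_new_varieties_per_year
        for i in range(n_tot):
            name = f"{cfg.variety_prefix}{i + 1:04d}"
            roster[name] = list(range(cfg.n_years))
            entry[name] = 0
        return roster, entry
    for c in range(cfg.n_checks):
        name = f"{cfg.country}_CHK{c + 1:02d}"
        roster[name] = list(range(cfg.n_years))
        entry[name] = 0
    idx = 0
    for k in range(cfg.n_years):
        for _ in range(cfg.n_new_varieties_per_year):
            idx += 1
            name = f"{cfg.variety_prefix}{idx:04d}"
            last = min(k + cfg.test_cycle_len, cfg.n_years)
            roster[name] = list(range(k, last))
            entry[name] = k
    return roster, entry


def _draw(rng, sd, labels):
    vals = rng.normal(0.0, sd, size=len(labels)) if sd > 0 else np.zeros(len(labels))
    return dict(zip(labels, vals.tolist()))


def simulate_network(cfg: NetworkSimConfig) -> tuple[METDataset, TruthRecord]:
    """Draw one network's variety-by-trial means plus the generating truth.

    Varieties enter in annual cohorts and remain ``test_cycle_len`` years;
    checks are present in all years.  With all variances and trends zero,
    every record equals ``mu`` exactly.  For protein content the linear
    predictor lives on the logit scale and records are stored as fractions.
    """
    roster, entry = _roster(cfg)
    varieties = list(roster)
    years = [cfg.start_year + k for k in range(cfg.n_years)]
    locations = [f"{cfg.country}_L{j + 1:02d}" for j in range(cfg.max_locations)]
    groups = list(cfg.maturity_groups)

    rng_a = _rng(cfg.seed, "assign")
    probs = np.array(list(cfg.maturity_groups.values()), float)
    mg_of = {
        v: groups[i]
        for v, i in zip(varieties, rng_a.choice(len(groups), size=len(varieties), p=probs))
    }

    sd = {t: float(np.sqrt(cfg.variances.get(t, 0.0))) for t in TERM_STREAMS}
    eff: dict[str, dict] = {}
    eff["L"] = _draw(_rng(cfg.seed, "L"), sd["L"], locations)
    eff["Y"] = _draw(_rng(cfg.seed, "Y"), sd["Y"], [str(y) for y in years])
    eff["LY"] = _draw(
        _rng(cfg.seed, "LY"), sd["LY"], [f"{l}:{y}" for l in locations for y in years]
    )
    eff["M"] = _draw(_rng(cfg.seed, "M"), sd["M"], groups)
    eff["G"] = _draw(_rng(cfg.seed, "G"), sd["G"], varieties)
    eff["GL"] = _draw(
        _rng(cfg.seed, "GL"), sd["GL"], [f"{v}:{l}" for v in varieties for l in locations]
    )
    eff["GY"] = _draw(
        _rng(cfg.seed, "GY"), sd["GY"], [f"{v}:{y}" for v in varieties for y in years]
    )
    eff["ML"] = _draw(
        _rng(cfg.seed, "ML"), sd["ML"], [f"{m}:{l}" for m in groups for l in locations]
    )
    eff["MY"] = _draw(
        _rng(cfg.seed, "MY"), sd["MY"], [f"{m}:{y}" for m in groups for y in years]
    )
    eff["MLY"] = _draw(
        _rng(cfg.seed, "MLY"),
        sd["MLY"],
        [f"{m}:{l}:{y}" for m in groups for l in locations for y in years],
    )
    if cfg.subtrial_by_maturity:
        eff["S(LY)"] = _draw(
            _rng(cfg.seed, "S(LY)"),
            sd["S(LY)"],
            [f"{l}:{y}:{m}" for l in locations for y in years for m in groups],
        )

    rng_res = _rng(cfg.seed, "GLY'")
    rows = []
    res_eff: dict[str, float] = {}
    for k, year in enumerate(years):
        nl = cfg.locations_for_year(k)
        active = [v for v in varieties if k in roster[v]]
        for l in locations[:nl]:
            for v in active:
                m = mg_of[v]
                t_k = k
                r_i = entry[v]
                lp = (
                    cfg.mu
                    + cfg.gamma * t_k
                    + cfg.beta * r_i
                    + eff["L"][l]
                    + eff["Y"][str(year)]
                    + eff["LY"][f"{l}:{year}"]
                    + eff["M"][m]
                    + eff["G"][v]
                    + eff["GL"][f"{v}:{l}"]
                    + eff["GY"][f"{v}:{year}"]
                    + eff["ML"][f"{m}:{l}"]
                    + eff["MY"][f"{m}:{year}"]
                    + eff["MLY"][f"{m}:{l}:{year}"]
                )
                subtrial = f"S_{m}" if cfg.subtrial_by_maturity else ""
                if cfg.subtrial_by_maturity:
                    lp += eff["S(LY)"][f"{l}:{year}:{m}"]
                e = float(rng_res.normal(0.0, sd["GLY'"])) if sd["GLY'"] > 0 else 0.0
                res_eff[f"{v}:{l}:{year}"] = e
                lp += e
                value = inv_logit(lp) if cfg.trait == "protein_content" else lp
                rows.append((cfg.country, year, l, subtrial, m, v, cfg.trait, value))
    eff["GLY'"] = res_eff
    df = pd.DataFrame(rows, columns=[
        "country", "year", "location", "subtrial", "maturity_group", "variety",
        "trait", "value",
    ])
    ds = METDataset(df, reference_year=cfg.start_year)
    truth = TruthRecord(config=dataclasses.asdict(cfg), effects=eff)
    return ds, truth


def simulate_dual_network(dual: DualSimConfig) -> tuple[METDataset, TruthRecord]:
    """Two networks with jointly drawn G, Y and GY effects.

    The first ``shared_varieties`` non-check varieties of network 2 are
    relabelled to coincide with network 1's, so the merged dataset contains
    genuinely shared entries.  Shared and unshared varieties alike get one
    bivariate (g_1, g_2) draw; a country's records only ever express its own
    column of the pair.
    """
    c1, c2 = dual.config1, dual.config2
    ros1, ent1 = _roster(c1)
    ros2, ent2 = _roster(c2)
    non_checks1 = [v for v in ros1 if not v.startswith(f"{c1.country}_CHK")]
    non_checks2 = [v for v in ros2 if not v.startswith(f"{c2.country}_CHK")]
    s = dual.shared_varieties
    if s > min(len(non_checks1), len(non_checks2)):
        raise ConfigError("shared_varieties exceeds a network's variety count")
    relabel = dict(zip(non_checks2[:s], non_checks1[:s]))

    def bivariate(term, labels, s1, s2, rho):
        rng = _rng(dual.seed, term, extra=7)
        draws = rng.standard_normal((len(labels), 2)) @ _chol2(s1, s2, rho).T
        return {lab: (float(a), float(b)) for lab, (a, b) in zip(labels, draws)}

    years = [c1.start_year + k for k in range(c1.n_years)]
    all_varieties = sorted(set(ros1) | {relabel.get(v, v) for v in ros2})
    sdG = (np.sqrt(c1.variances.get("G", 0.0)), np.sqrt(c2.variances.get("G", 0.0)))
    sdY = (np.sqrt(c1.variances.get("Y", 0.0)), np.sqrt(c2.variances.get("Y", 0.0)))
    sdGY = (np.sqrt(c1.variances.get("GY", 0.0)), np.sqrt(c2.variances.get("GY", 0.0)))
    G2 = bivariate("G", all_varieties, *sdG, dual.rho_G)
    Y2 = bivariate("Y", [str(y) for y in years], *sdY, dual.rho_Y)
    GY2 = bivariate(
        "GY", [f"{v}:{y}" for v in all_varieties for y in years], *sdGY, dual.rho_GY
    )

    parts, truth_effects = [], {}
    for idx, (cfg, relab) in enumerate(((c1, {}), (c2, relabel))):
        sub = dataclasses.replace(
            cfg,
            variances={**cfg.variances, "G": 0.0, "Y": 0.0, "GY": 0.0},
            seed=int(np.random.default_rng([dual.seed % (2**31), 100 + idx]).integers(2**31)),
        )
        ds, tr = simulate_network(sub)
        df = ds.records.copy()
        df["variety"] = df["variety"].map(lambda v: relab.get(v, v))
        onlogit = cfg.trait == "protein_content"
        lp = (
            np.array([np.log(v / (1 - v)) for v in df["value"]])
            if onlogit
            else df["value"].to_numpy().copy()
        )
        lp += np.array([G2[v][idx] for v in df["variety"]])
        lp += np.array([Y2[str(y)][idx] for y in df["year"]])
        lp += np.array([GY2[f"{v}:{y}"][idx] for v, y in zip(df["variety"], df["year"])])
        df["value"] = inv_logit(lp) if onlogit else lp
        parts.append(df)
        truth_effects[cfg.country] = tr.effects
    truth_effects["G"] = {v: list(G2[v]) for v in all_varieties}
    truth_effects["Y"] = {y: list(Y2[y]) for y in Y2}
    truth_effects["GY"] = {k: list(GY2[k]) for k in GY2}

    ds = METDataset(pd.concat(parts, ignore_index=True), reference_year=c1.start_year)
    truth = TruthRecord(
        config={
            "config1": dataclasses.asdict(c1),
            "config2": dataclasses.asdict(c2),
            "rho_G": dual.rho_G,
            "rho_Y": dual.rho_Y,
            "rho_GY": dual.rho_GY,
            "shared_varieties": s,
            "seed": dual.seed,
        },
        effects=truth_effects,
    )
    return ds, truth


def simulate_bivariate_traits(
    cfg: NetworkSimConfig,
    trait2: str,
    mu2: float,
    variances2: dict[str, float],
    rho: dict[str, float],
    beta2: float = 0.0,
) -> tuple[METDataset, TruthRecord]:
    """Two traits measured in the same trials with correlated genotypic terms.

    The G, GL, GY and GLY' effects are drawn jointly bivariate-normal across
    traits with the correlations in ``rho`` (keys among ``G, GL, GY, GLY'``);
    environmental terms are independent per trait, mirroring the bivariate
    analysis model used for genotypic trait correlations.
    """
    roster, entry = _roster(cfg)
    varieties = list(roster)
    years = [cfg.start_year + k for k in range(cfg.n_years)]
    locations = [f"{cfg.country}_L{j + 1:02d}" for j in range(cfg.max_locations)]

    def bidraw(term, labels):
        s1 = float(np.sqrt(cfg.variances.get(term, 0.0)))
        s2 = float(np.sqrt(variances2.get(term, 0.0)))
        r = float(rho.get(term, 0.0))
        if abs(r) > 1:
            raise ConfigError(f"rho_{term} outside [-1, 1]")
        rng = _rng(cfg.seed, term, extra=13)
        draws = rng.standard_normal((len(labels), 2)) @ _chol2(s1, s2, r).T
        return {lab: (float(a), float(b)) for lab, (a, b) in zip(labels, draws)}

    G2 = bidraw("G", varieties)
    GL2 = bidraw("GL", [f"{v}:{l}" for v in varieties for l in locations])
    GY2 = bidraw("GY", [f"{v}:{y}" for v in varieties for y in years])

    parts = []
    truth_effects: dict[str, dict] = {}
    res_labels = None
    for idx, (trait, mu_t, var_t, beta_t) in enumerate(
        [(cfg.trait, cfg.mu, cfg.variances, cfg.beta), (trait2, mu2, variances2, beta2)]
    ):
        sub = dataclasses.replace(
            cfg,
            trait=trait,
            mu=mu_t,
            beta=beta_t,
            variances={**var_t, "G": 0.0, "GL": 0.0, "GY": 0.0, "GLY'": 0.0},
            seed=int(np.random.default_rng([cfg.seed % (2**31), 200 + idx]).integers(2**31)),
        )
        ds, tr = simulate_network(sub)
        df = ds.records.copy()
        if res_labels is None:
            res_labels = [
                f"{v}:{l}:{y}"
                for v, l, y in zip(df["variety"], df["location"], df["year"])
            ]
            GLY2 = bidraw("GLY'", res_labels)
        onlogit = trait == "protein_content"
        lp = (
            np.array([np.log(v / (1 - v)) for v in df["value"]])
            if onlogit
            else df["value"].to_numpy().copy()
        )
        lp += np.array([G2[v][idx] for v in df["variety"]])
        lp += np.array(
            [GL2[f"{v}:{l}"][idx] for v, l in zip(df["variety"], df["location"])]
        )
        lp += np.array([GY2[f"{v}:{y}"][idx] for v, y in zip(df["variety"], df["year"])])
        lp += np.array(
            [
                GLY2[f"{v}:{l}:{y}"][idx]
                for v, l, y in zip(df["variety"], df["location"], df["year"])
            ]
        )
        df["value"] = inv_logit(lp) if onlogit else lp
        parts.append(df)
        truth_effects[trait] = tr.effects
    truth_effects["G"] = {v: list(G2[v]) for v in varieties}

    ds = METDataset(pd.concat(parts, ignore_index=True), reference_year=cfg.start_year)
    truth = TruthRecord(
        config={"base": dataclasses.asdict(cfg), "trait2": trait2, "rho": dict(rho)},
        effects=truth_effects,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

_GRAIN_YIELD_VAR = {
    "L": 0.23, "Y": 0.16, "LY": 0.36, "S(LY)": 0.010, "M": 0.010,
    "G": 0.040, "GL": 0.0144, "GY": 0.018,
    "ML": 0.004, "MY": 0.004, "MLY": 0.006, "GLY'": 0.0925,
}
_PROTEIN_YIELD_VAR = {
    "L": 0.032, "Y": 0.022, "LY": 0.050, "S(LY)": 0.0014, "M": 0.0014,
    "G": 0.0056, "GL": 0.0018, "GY": 0.0026,
    "ML": 0.0006, "MY": 0.0006, "MLY": 0.0009, "GLY'": 0.0130,
}
# protein content lives on the logit scale; a genotypic SD of ~0.073 logit
# units is ~1.8 percentage points of content around a 40% mean
_PROTEIN_CONTENT_VAR = {
    "L": 0.0040, "Y": 0.0030, "LY": 0.0050, "S(LY)": 0.0008, "M": 0.0020,
    "G": 0.0053, "GL": 0.0005, "GY": 0.0004,
    "ML": 0.0002, "MY": 0.0002, "MLY": 0.0005, "GLY'": 0.0011,
}

_PRESETS = {
    ("AT", "grain_yield"): dict(mu=4.0, beta=0.079, var=_GRAIN_YIELD_VAR),
    ("FR", "grain_yield"): dict(mu=3.5, beta=0.030, var=_GRAIN_YIELD_VAR),
    ("AT", "protein_yield"): dict(mu=1.50, beta=0.0308, var=_PROTEIN_YIELD_VAR),
    ("FR", "protein_yield"): dict(mu=1.40, beta=0.0105, var=_PROTEIN_YIELD_VAR),
    ("AT", "protein_content"): dict(mu=-0.405465, beta=0.0001, var=_PROTEIN_CONTENT_VAR),
    ("FR", "protein_content"): dict(mu=-0.405465, beta=-0.0028, var=_PROTEIN_CONTENT_VAR),
}


def default_network_config(
    country: str = "AT", trait: str = "grain_yield", seed: int = 0, **overrides
) -> NetworkSimConfig:
    """Preset study conditions per country layout and trait.

    AT: 16 years, 8 locations/year, 2 maturity groups, no subtrials.
    FR: 16 years, 10 locations/year, 4 maturity groups nested in subtrials
    (maturity confounded with subtrial, so ML/MY are absent from its
    analysis model), fewer candidate varieties.
    """
    p = _PRESETS[(country, trait)]
    base = dict(
        country=country,
        trait=trait,
        n_years=16,
        start_year=2003,
        mu=p["mu"],
        beta=p["beta"],
        gamma=0.0,
        variances=dict(p["var"]),
        seed=seed,
    )
    if country == "AT":
        base.update(
            locations_per_year=8,
            n_new_varieties_per_year=5,
            # six persistent checks reproduce the reported median
            # between-year variety overlap of ~6
            n_checks=6,
            maturity_groups={"early": 0.5, "medium_early": 0.5},
            subtrial_by_maturity=False,
            variety_prefix="A",
        )
        base["variances"].pop("S(LY)", None)
    else:
        base.update(
            locations_per_year=10,
            n_new_varieties_per_year=1,
            n_checks=3,  # median between-year overlap ~3
            maturity_groups={
                "very_early": 0.25, "early": 0.25, "semi_early": 0.25,
                "semi_late": 0.25,
            },
            subtrial_by_maturity=True,
            variety_prefix="F",
        )
        base["variances"].pop("ML", None)
        base["variances"].pop("MY", None)
    base.update(overrides)
    return NetworkSimConfig(**base)


def default_dual_config(trait: str = "grain_yield", seed: int = 0, **overrides) -> DualSimConfig:
    """Merged-network study conditions: AT + FR with strong genotypic correlation."""
    c1 = default_network_config("AT", trait, seed=seed)
    c2 = default_network_config("FR", trait, seed=seed)
    base = dict(config1=c1, config2=c2, rho_G=0.85, rho_Y=0.6, rho_GY=0.7,
                shared_varieties=15, seed=seed)
    base.update(overrides)
    return DualSimConfig(**base)
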