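"""Model-term declarations for the trial-network mixed models.

Three model variants are used throughout:

* ``univariate`` — the single-trait, single-country MET model: fixed
  intercept, environmental trend ``gamma * t_k``, maturity-group means and
  genetic trend ``beta * r_i``; random location (L), year (Y), their
  interaction (LY), subtrial-within-trial S(LY) where maturity groups are
  nested in subtrials, genotype G (nested in maturity group), GL, GY,
  maturity-by-environment terms, and a residual GLY' that confounds the
  three-way interaction with the stage-one plot error.
* ``bivariate`` — two traits analysed jointly; G, GL, GY and GLY' carry an
  unstructured 2x2 covariance across traits (yielding the genotypic trait
  correlations), all environmental terms get separate variances per trait.
* ``combined`` — two countries analysed jointly; country-specific fixed
  effects and variances, a genetic trend shared across countries, and
  unstructured 2x2 covariance across countries for G, Y and GY (the
  between-network correlations that make data merging informative).

Rows whose value for any factor of a term is the empty string do not load
on that term (e.g. records without subtrials carry no S(LY) effect).
"""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass(frozen=True)
class FixedTerm:
    """One fixed-effect term: factor dummies, a covariate, or their product.

    ``coding`` is ``"full"`` (one column per level) or ``"drop_first"``;
    with ``within`` set, the first level is dropped separately inside each
    level of that column (country-specific maturity means).
    """

    name: str
    factors: tuple[str, ...] = ()
    covariate: str | None = None
    coding: str = "drop_first"
    within: str | None = None


@dataclasses.dataclass(frozen=True)
class RandomTerm:
    """One random term and its covariance structure.

    structure:
      * ``sci`` — scaled identity, one variance.
      * ``group_diag`` — separate variance per level of ``group`` (which
        must be among ``factors``).
      * ``us2`` — unstructured 2x2 across the two levels of ``group``
        (which must NOT be among ``factors``); every base level gets a
        latent effect in both groups, so effects in a group where the level
        was never observed are still predictable through the correlation.
    """

    name: str
    factors: tuple[str, ...]
    structure: str = "sci"
    group: str | None = None

    def __post_init__(self):
        if self.structure == "group_diag" and self.group not in self.factors:
            raise ValueError(f"{self.name}: group_diag needs group among factors")
        if self.structure == "us2" and (self.group is None or self.group in self.factors):
            raise ValueError(f"{self.name}: us2 needs a group column outside factors")


@dataclasses.dataclass
class ModelSpec:
    name: str
    fixed: list[FixedTerm]
    random: list[RandomTerm]
    residual: RandomTerm


def build_model_spec(variant: str, country_layout: str = "AT") -> ModelSpec:
    """Assemble the exact term list for a model variant.

    ``country_layout`` is ``"AT"`` (no subtrials; ML and MY present) or
    ``"FR"`` (maturity groups fully confounded with subtrials: S(LY)
    present, ML and MY omitted).  For ``variant="combined"`` the layout
    argument is ignored: each country keeps its own layout, with S(LY)
    loading only on records that carry a subtrial label.
    """
    if variant in ("univariate", "fixed_variety"):
        fixed = [
            FixedTerm("mu"),
            FixedTerm("gamma", covariate="_t"),
            FixedTerm("M", factors=("maturity_group",)),
        ]
        random = [
            RandomTerm("L", ("location",)),
            RandomTerm("Y", ("year_f",)),
            RandomTerm("LY", ("location", "year_f")),
            RandomTerm("G", ("variety",)),
            RandomTerm("GL", ("variety", "location")),
            RandomTerm("GY", ("variety", "year_f")),
            RandomTerm("MLY", ("maturity_group", "location", "year_f")),
        ]
        if country_layout == "AT":
            random.insert(6, RandomTerm("ML", ("maturity_group", "location")))
            random.insert(7, RandomTerm("MY", ("maturity_group", "year_f")))
        elif country_layout == "FR":
            random.insert(3, RandomTerm("S(LY)", ("location", "year_f", "subtrial")))
        else:
            raise ValueError(f"unknown country layout '{country_layout}'")
        if variant == "univariate":
            fixed.append(FixedTerm("beta", covariate="_r"))
        else:
            # Fixed-variety variant for adjusted variety means: G fixed; the
            # genetic-trend covariate and the maturity-group means are both
            # linear combinations of the variety dummies (every variety sits
            # in exactly one group), so they are dropped to keep X full rank.
            fixed = [f for f in fixed if f.name != "M"]
            fixed.append(
                FixedTerm("G", factors=("variety",), coding="drop_first")
            )
            random = [t for t in random if t.name not in ("G",)]
        return ModelSpec(
            name=f"{variant}-{country_layout}",
            fixed=fixed,
            random=random,
            residual=RandomTerm("GLY'", ("variety", "location", "year_f")),
        )

    if variant == "bivariate":
        fixed = [
            FixedTerm("mu", factors=("trait",), coding="full"),
            FixedTerm("gamma", factors=("trait",), covariate="_t", coding="full"),
            FixedTerm("M", factors=("trait", "maturity_group"), within="trait"),
            FixedTerm("beta", factors=("trait",), covariate="_r", coding="full"),
        ]
        random = [
            RandomTerm("L", ("trait", "location"), "group_diag", group="trait"),
            RandomTerm("Y", ("trait", "year_f"), "group_diag", group="trait"),
            RandomTerm("LY", ("trait", "location", "year_f"), "group_diag", group="trait"),
            RandomTerm("G", ("variety",), "us2", group="trait"),
            RandomTerm("GL", ("variety", "location"), "us2", group="trait"),
            RandomTerm("GY", ("variety", "year_f"), "us2", group="trait"),
            RandomTerm(
                "MLY", ("trait", "maturity_group", "location", "year_f"),
                "group_diag", group="trait",
            ),
        ]
        if country_layout == "FR":
            random.insert(
                3,
                RandomTerm(
                    "S(LY)", ("trait", "location", "year_f", "subtrial"),
                    "group_diag", group="trait",
                ),
            )
        return ModelSpec(
            name=f"bivariate-{country_layout}",
            fixed=fixed,
            random=random,
            residual=RandomTerm(
                "GLY'", ("variety", "location", "year_f", "subtrial"),
                "us2", group="trait",
            ),
        )

    if variant == "combined":
        fixed = [
            FixedTerm("mu", factors=("country",), coding="full"),
            FixedTerm("gamma", factors=("country",), covariate="_t", coding="full"),
            FixedTerm("M", factors=("country", "maturity_group"), within="country"),
            FixedTerm("beta", covariate="_r"),  # genetic trend shared across countries
        ]
        random = [
            RandomTerm("L", ("country", "location"), "group_diag", group="country"),
            RandomTerm("Y", ("year_f",), "us2", group="country"),
            RandomTerm("LY", ("country", "location", "year_f"), "group_diag", group="country"),
            RandomTerm(
                "S(LY)", ("country", "location", "year_f", "subtrial"),
                "group_diag", group="country",
            ),
            RandomTerm("G", ("variety",), "us2", group="country"),
            RandomTerm("GY", ("variety", "year_f"), "us2", group="country"),
            RandomTerm(
                "MLY", ("country", "maturity_group", "location", "year_f"),
                "group_diag", group="country",
            ),
        ]
        return ModelSpec(
            name="combined",
            fixed=fixed,
            random=random,
            residual=RandomTerm(
                "GLY'", ("country", "variety", "location", "year_f"),
                "group_diag", group="country",
            ),
        )

    raise ValueError(f"unknown model variant '{variant}'")
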