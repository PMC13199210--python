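"""Data model for multi-environment trial (MET) variety means.

The unit of observation is a *variety-by-trial adjusted mean*: the mean
trait value of one variety in one trial (a location-by-year combination,
possibly split into subtrials by maturity group), already adjusted for the
within-trial experimental design.  Traits are grain yield and protein yield
(t/ha) on the raw scale and protein content stored as a fraction of dry
weight in (0, 1); protein content is logit-transformed before any mixed
model is fitted.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

TRAITS = ("grain_yield", "protein_yield", "protein_content")

#: canonical column order of the records table
COLUMNS = [
    "country",
    "year",
    "location",
    "subtrial",
    "maturity_group",
    "variety",
    "trait",
    "value",
]

#: columns forming the unique key of a record
KEY_COLUMNS = ["country", "year", "location", "subtrial", "variety", "trait"]


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class IntegrityError(ValueError):
    """Duplicate record keys or violated invariants."""


def logit(p):
    """Log-odds of a fraction ``p`` in the open interval (0, 1).

    Used for protein content, which is bounded; analysis happens on the
    logit scale and results are back-transformed for reporting.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("logit requires values strictly inside (0, 1)")
    out = np.log(p / (1.0 - p))
    return out.item() if out.ndim == 0 else out


def inv_logit(x):
    """Inverse of :func:`logit`: maps the real line to (0, 1)."""
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(-x))
    return out.item() if out.ndim == 0 else out


@dataclasses.dataclass
class METDataset:
    """A collection of variety-by-trial means plus derived bookkeeping.

    Parameters
    ----------
    records
        Table with the canonical columns (:data:`COLUMNS`).
    reference_year
        Calendar year mapped to 0 for the trend covariates (default 2003).
    registration_year
        Optional map variety -> official registration year, used for
        sensitivity analyses of the genetic trend.
    """

    records: pd.DataFrame
    reference_year: int | None = None
    registration_year: dict[str, int] | None = None

    def __post_init__(self):
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = df[COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["value"] = df["value"].astype(float)
        if not np.all(np.isfinite(df["value"].to_numpy())):
            raise IntegrityError("non-finite trait values present")
        bad_trait = set(df["trait"]) - set(TRAITS)
        if bad_trait:
            raise SchemaError(f"unknown trait labels: {sorted(bad_trait)}")
        pc = df.loc[df["trait"] == "protein_content", "value"]
        if len(pc) and ((pc <= 0).any() or (pc >= 1).any()):
            raise IntegrityError(
                "protein_content must be a fraction in (0, 1) on the raw scale"
            )
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            keys = df.loc[dup, KEY_COLUMNS].head(5).to_dict("records")
            raise IntegrityError(f"duplicate record keys, e.g. {keys}")
        self.records = df.reset_index(drop=True)
        if self.reference_year is None:
            self.reference_year = int(df["year"].min()) if len(df) else 2003
        if len(df) and self.reference_year > int(df["year"].min()):
            raise IntegrityError(
                "reference_year must not exceed the earliest trial year"
            )
        self.fyoa = derive_fyoa(self)

    def __len__(self):
        return len(self.records)

    @property
    def varieties(self) -> list[str]:
        return sorted(self.records["variety"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.records["year"].unique())

    def subset(self, *, country=None, trait=None) -> "METDataset":
        """Rows restricted to one country and/or trait (labels unchanged)."""
        df = self.records
        if country is not None:
            df = df[df["country"] == country]
        if trait is not None:
            df = df[df["trait"] == trait]
        return METDataset(
            df.copy(),
            reference_year=self.reference_year,
            registration_year=self.registration_year,
        )

    def summary(self) -> dict:
        """Headline counts: years, locations, trials, varieties."""
        df = self.records
        out = {}
        for country, sub in df.groupby("country"):
            loc_year = sub[["location", "year"]].drop_duplicates()
            out[country] = {
                "n_years": int(sub["year"].nunique()),
                "n_locations": int(sub["location"].nunique()),
                "n_loc_year": int(len(loc_year)),
                "n_loc_year_subtrial": int(
                    len(sub[["location", "year", "subtrial"]].drop_duplicates())
                ),
                "n_varieties": int(sub["variety"].nunique()),
                "maturity_groups": sorted(sub["maturity_group"].unique()),
                "median_locations_per_year": float(
                    sub.groupby("year")["location"].nunique().median()
                ),
            }
        return out


def derive_fyoa(dataset: METDataset) -> dict[str, int]:
    """First year of appearance (FYOA) of each variety in the dataset.

    FYOA serves as a surrogate for the first year of testing when
    registration dates are unavailable; it is the regressor of the genetic
    trend.
    """
    if len(dataset.records) == 0:
        return {}
    g = dataset.records.groupby("variety")["year"].min()
    return {v: int(y) for v, y in g.items()}


def read_trial_means(
    path,
    schema: Mapping[str, str] | None = None,
    reference_year: int | None = None,
    protein_content_in_percent: bool = True,
) -> METDataset:
    """Read a CSV of variety-by-trial means into a :class:`METDataset`.

    ``schema`` maps canonical column names to the file's actual headers.
    Protein-content values given in percent are divided by 100 at read time
    so the in-memory scale is always a fraction.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path)
    rename = {}
    for canon in COLUMNS:
        src = schema.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
        elif canon == "subtrial":
            df[canon] = ""
        else:
            raise SchemaError(f"input file lacks a column for '{canon}' (expected header '{src}')")
    df = df.rename(columns=rename)
    df["subtrial"] = df["subtrial"].fillna("")
    if protein_content_in_percent:
        mask = df["trait"] == "protein_content"
        df.loc[mask, "value"] = df.loc[mask, "value"] / 100.0
    return METDataset(df, reference_year=reference_year)


def write_trial_means(dataset: METDataset, path) -> None:
    dataset.records.to_csv(path, index=False)


def exclude_varieties(dataset: METDataset, names) -> tuple[METDataset, int]:
    """Drop all records of the named varieties; FYOA is recomputed.

    Returns the filtered dataset and the number of removed records.  Names
    not present trigger a warning, not an error (exclusion lists may be
    shared across countries).
    """
    names = list(names)
    if not names:
        raise ValueError("exclusion list must be non-empty")
    present = set(dataset.records["variety"])
    absent = [n for n in names if n not in present]
    if absent:
        warnings.warn(f"varieties not present, ignored: {absent}", stacklevel=2)
    mask = dataset.records["variety"].isin(names)
    removed = int(mask.sum())
    out = METDataset(
        dataset.records[~mask].copy(),
        reference_year=dataset.reference_year,
        registration_year=dataset.registration_year,
    )
    return out, removed


def overlap_matrix(dataset: METDataset) -> pd.DataFrame:
    """Year-by-year variety overlap counts.

    Diagonal entries count the unique varieties tested in a year;
    off-diagonal (k, k') entries count varieties common to both years.  The
    characteristic "diagonal" occurrence structure of VCU trialling (short
    test cycles plus persistent checks) shows up as a bright band near the
    diagonal.
    """
    years = dataset.years
    if not years:
        raise ValueError("dataset has no years")
    sets = {
        y: set(dataset.records.loc[dataset.records["year"] == y, "variety"])
        for y in years
    }
    n = len(years)
    mat = np.zeros((n, n), dtype=int)
    for a, ya in enumerate(years):
        for b, yb in enumerate(years):
            mat[a, b] = len(sets[ya] & sets[yb])
    return pd.DataFrame(mat, index=years, columns=years)


def median_offdiagonal_overlap(overlap: pd.DataFrame) -> float:
    """Median of the off-diagonal overlap counts (pairs of distinct years)."""
    m = overlap.to_numpy()
    iu = np.triu_indices_from(m, k=1)
    if len(iu[0]) == 0:
        raise ValueError("need at least two years")
    return float(np.median(m[iu]))
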