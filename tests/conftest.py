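import numpy as np
import pandas as pd
import pytest

from vcunet import METDataset
from vcunet.model import FixedTerm, ModelSpec, RandomTerm

COLS = [
    "country", "year", "location", "subtrial", "maturity_group", "variety",
    "trait", "value",
]


def make_records(rows):
    return pd.DataFrame(rows, columns=COLS)


@pytest.fixture
def toy_dataset():
    """Two varieties x two trials, one trait."""
    rows = [
        ("AT", 2003, "L1", "", "MG1", "V1", "grain_yield", 4.1),
        ("AT", 2003, "L2", "", "MG1", "V1", "grain_yield", 3.9),
        ("AT", 2004, "L1", "", "MG1", "V2", "grain_yield", 4.3),
        ("AT", 2004, "L2", "", "MG1", "V2", "grain_yield", 4.5),
    ]
    return METDataset(make_records(rows))


def one_way_frame(g=8, n=5, sigma_g=1.0, sigma_e=0.7, seed=0, mu=5.0):
    """Balanced one-way layout: g varieties, n trials each."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(g):
        gi = rng.normal(0, sigma_g)
        for j in range(n):
            rows.append(
                ("AT", 2003, f"L{j + 1}", "", "MG1", f"V{i + 1}", "grain_yield",
                 mu + gi + rng.normal(0, sigma_e))
            )
    return make_records(rows)


def one_way_spec():
    return ModelSpec(
        "oneway",
        [FixedTerm("mu")],
        [RandomTerm("G", ("variety",))],
        RandomTerm("GLY'", ("variety", "location")),
    )


def two_way_frame(a=6, b=7, sigma_a=1.2, sigma_b=0.9, sigma_e=0.5, seed=1, mu=3.0):
    """Balanced two-way crossed layout (varieties x years), one obs per cell."""
    rng = np.random.default_rng(seed)
    A = rng.normal(0, sigma_a, a)
    B = rng.normal(0, sigma_b, b)
    rows = []
    for i in range(a):
        for j in range(b):
            rows.append(
                ("AT", 2003 + j, "L1", "", "MG1", f"V{i + 1}", "grain_yield",
                 mu + A[i] + B[j] + rng.normal(0, sigma_e))
            )
    return make_records(rows)


def two_way_spec():
    return ModelSpec(
        "twoway",
        [FixedTerm("mu")],
        [RandomTerm("G", ("variety",)), RandomTerm("Y", ("year_f",))],
        RandomTerm("GLY'", ("variety", "year_f")),
    )


def balanced_met_frame(g=12, n_l=8, n_y=2, value=0.0):
    """Fully balanced MET design frame (values constant; for frozen-vc use)."""
    rows = []
    for i in range(g):
        for j in range(n_l):
            for k in range(n_y):
                rows.append(
                    ("AT", 2003 + k, f"L{j + 1}", "", "MG1", f"V{i + 1:02d}",
                     "grain_yield", value)
                )
    df = make_records(rows)
    df["_t"] = 0.0
    df["_r"] = 0.0
    df["year_f"] = df["year"].astype(str)
    return df


def balanced_met_spec():
    return ModelSpec(
        "met-balanced",
        [FixedTerm("mu")],
        [
            RandomTerm("G", ("variety",)),
            RandomTerm("GL", ("variety", "location")),
            RandomTerm("GY", ("variety", "year_f")),
            RandomTerm("L", ("location",)),
            RandomTerm("Y", ("year_f",)),
            RandomTerm("LY", ("location", "year_f")),
        ],
        RandomTerm("GLY'", ("variety", "location", "year_f")),
    )
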