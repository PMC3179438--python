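"""Shared fixtures: worked-example tables, toy hierarchies, random tables."""

import numpy as np
import pandas as pd
import pytest

from deidkit import (
    Edge,
    GeneralizationHierarchy,
    Level,
    MicrodataTable,
    QuasiIdentifier,
    Schema,
    table1_fixture,
    walkthrough_fixture,
)
from deidkit.combinations import Combination, CombinationSet
from deidkit.synthdata import GeneratorSpec, build_dad_hierarchies, decade_of


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def walkthrough():
    return walkthrough_fixture()


@pytest.fixture(scope="session")
def walkthrough_combo():
    return CombinationSet(
        [Combination(id="w", columns=("Sex", "YearOfBirth", "Diagnosis"))]
    )


@pytest.fixture(scope="session")
def year_hierarchy():
    """Year of birth -> ten-year decades -> single top level."""
    years = {str(r[4]) for r in _table1_years()}
    decade_map = {y: decade_of(int(y)) for y in years}
    all_map = {d: "any" for d in set(decade_map.values())}
    return GeneralizationHierarchy(
        "birth_year",
        [Level("year", 1), Level("decade", 2), Level("all", 3)],
        [
            Edge("year", "decade", decade_map, totally_ordered=True),
            Edge("decade", "all", all_map, totally_ordered=True),
        ],
    )


def _table1_years():
    from deidkit.synthdata import _TABLE1_ROWS

    return _TABLE1_ROWS


@pytest.fixture(scope="session")
def dad_hierarchies():
    diag, interv, mrdx, cci = build_dad_hierarchies(
        GeneratorSpec(), np.random.default_rng(11)
    )
    return diag, interv, mrdx, cci


@pytest.fixture(scope="session")
def dad_schema(dad_hierarchies):
    diag, interv, _mrdx, _cci = dad_hierarchies
    return Schema(
        [
            QuasiIdentifier("PROV_ALL"),
            QuasiIdentifier("AGE_GROUP"),
            QuasiIdentifier("GENDER_CODE"),
            QuasiIdentifier("MRDx", hierarchy_ref=("diagnosis", "MRDx")),
            QuasiIdentifier("CCI_CODE", hierarchy_ref=("intervention", "CCI_CODE")),
        ],
        [],
        {"diagnosis": diag, "intervention": interv},
    )


@pytest.fixture
def table6():
    """Four records, 2-anonymous on each of two overlapping combinations."""
    df = pd.DataFrame(
        {
            "PROV_ALL": ["ON"] * 4,
            "AGE_GROUP": ["50-59"] * 4,
            "GENDER_CODE": ["M"] * 4,
            "MRDx": ["B022", "B022", "C793", "C793"],
            "CMG_CODE": ["013", "033", "013", "033"],
        },
        index=pd.RangeIndex(1, 5),
    )
    return MicrodataTable(df)


def random_table(seed: int, n: int = 60, n_cols: int = 3, n_values: int = 6):
    """Small random categorical table for brute-force oracle comparisons."""
    rng = np.random.default_rng(seed)
    data = {
        f"q{c}": rng.choice([f"v{j}" for j in range(n_values)], size=n)
        for c in range(n_cols)
    }
    return MicrodataTable(pd.DataFrame(data, index=pd.RangeIndex(1, n + 1)))
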