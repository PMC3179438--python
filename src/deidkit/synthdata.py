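"""Generators and embedded fixtures for discharge-abstract-style microdata.

Everything here is synthetic or reconstructed so the whole toolkit is
testable without any external data access:

* :func:`table1_fixture` -- the 27-record laboratory example used to
  illustrate variable roles and equivalence classes.
* :func:`walkthrough_fixture` -- the same 27 records with a diagnosis
  column constructed to satisfy the documented constraints of the
  suppression-algorithm walkthrough (supports, class memberships and pass
  structure); the assignment is re-verified on every build so the fixture
  cannot drift silently.
* :func:`generate_dad_like` -- skewed categorical microdata shaped like a
  national discharge abstract database: 10 provinces, 20 five-year age
  groups top-coded at 90+, 5 gender codes (two common), a four-level
  diagnosis hierarchy (code -> case-mix group / block -> chapter) and a
  two-level intervention hierarchy with ~46% of records having no
  intervention.  Zipf-like value frequencies produce the small-class tail
  that cell suppression exists to repair.
* :func:`generate_population` -- an identified individual-level population
  with (province, age group, sex) strata plus its exact aggregate
  :class:`~deidkit.risk.PopulationTable`, for the matching-attack simulator.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Edge,
    GeneralizationHierarchy,
    Level,
    MicrodataTable,
    QuasiIdentifier,
    Schema,
    equivalence_classes,
    support,
)
from .risk import PopulationTable

# ---------------------------------------------------------------------------
# The 27-record worked example
# ---------------------------------------------------------------------------

# (id, name, phone, sex, year of birth, lab test, lab result, pay delay)
_TABLE1_ROWS = [
    (1, "John Smith", "(412) 688-5468", "Male", 1959, "Albumin, Serum", "4.8", 37),
    (2, "Alan Smith", "(413) 822-5074", "Male", 1969, "Creatine kinase", "86", 36),
    (3, "Alice Brown", "(416) 886-5314", "Female", 1955, "Alkaline Phosphatase", "66", 52),
    (4, "Hercules Green", "(613) 763-5254", "Male", 1959, "Bilirubin", "Negative", 36),
    (5, "Alicia Freds", "(613) 586-6222", "Female", 1942, "BUN/Creatinine Ratio", "17", 82),
    (6, "Gill Stringer", "(954) 699-5423", "Female", 1975, "Calcium, Serum", "9.2", 34),
    (7, "Marie Kirkpatrick", "(416) 786-6212", "Female", 1966, "Free Thyroxine Index", "2.7", 23),
    (8, "Leslie Hall", "(905) 668-6581", "Female", 1987, "Globulin, Total", "3.5", 9),
    (9, "Douglas Henry", "(416) 423-5965", "Male", 1959, "B-type natriuretic peptide", "134.1", 38),
    (10, "Fred Thompson", "(416) 421-7719", "Male", 1967, "Creatine kinase", "80", 21),
    (11, "Joe Doe", "(705) 727-7808", "Male", 1968, "Alanine aminotransferase", "24", 33),
    (12, "Lillian Barley", "(416) 695-4669", "Female", 1955, "Cancer antigen 125", "86", 28),
    (13, "Deitmar Plank", "(416) 603-5526", "Male", 1967, "Creatine kinase", "327", 37),
    (14, "Anderson Hoyt", "(905) 388-2851", "Male", 1967, "Creatine kinase", "82", 16),
    (15, "Alexandra Knight", "(416) 539-4200", "Female", 1966, "Creatinine", "0.78", 44),
    (16, "Helene Arnold", "(519) 631-0587", "Female", 1955, "Triglycerides", "147", 59),
    (17, "Almond Zipf", "(519) 515-8500", "Male", 1967, "Creatine kinase", "73", 20),
    (18, "Britney Goldman", "(613) 737-7870", "Female", 1956, "Monocytes", "12", 34),
    (19, "Lisa Marie", "(902) 473-2383", "Female", 1956, "HDL Cholesterol", "68", 141),
    (20, "William Cooper", "(905) 763-6852", "Male", 1978, "Neutrophils", "83", 21),
    (21, "Kathy Last", "(705) 424-1266", "Female", 1966, "Prothrombin Time", "16.9", 23),
    (22, "Deitmar Plank", "(519) 831-2330", "Male", 1967, "Creatine kinase", "68", 16),
    (23, "Anderson Hoyt", "(705) 652-6215", "Male", 1971, "White Blood Cell Count", "13.0", 151),
    (24, "Alexandra Knight", "(416) 813-5873", "Female", 1954, "Hemoglobin", "14.8", 34),
    (25, "Helene Arnold", "(705) 663-1801", "Female", 1977, "Lipase, Serum", "37", 27),
    (26, "Anderson Heft", "(416) 813-6498", "Male", 1944, "Cholesterol, Total", "147", 18),
    (27, "Almond Zipf", "(617) 667-9540", "Male", 1965, "Hematocrit", "45.3", 53),
]

#: Diagnosis assignment for the walkthrough.  Built to satisfy, all at
#: once: four support-1 diagnoses; cardiac condition, arthropathy/spine
#: disorder and gastrointestinal bleeding each a single class of three;
#: acute respiratory problem on ids {8, 16, 19, 24} with {16, 19, 24} one
#: class; external injury support 4 with ids 10 and 14 forming a size-2
#: class; metabolic disorder support 6 with ids 23 and 25 in singleton
#: classes.  The totals are forced by the 27-record sum; supports of
#: arthropathy and gastrointestinal bleeding (3 and 3) are the unique
#: feasible remainders.
_WALKTHROUGH_DIAGNOSIS = {
    5: "COPD",
    6: "sepsis",
    20: "neurological problem",
    26: "pneumonia",
    2: "cardiac condition",
    11: "cardiac condition",
    13: "cardiac condition",
    17: "arthropathy or spine disorder",
    22: "arthropathy or spine disorder",
    27: "arthropathy or spine disorder",
    3: "gastrointestinal bleeding",
    12: "gastrointestinal bleeding",
    18: "gastrointestinal bleeding",
    8: "acute respiratory problem",
    16: "acute respiratory problem",
    19: "acute respiratory problem",
    24: "acute respiratory problem",
    1: "external injury",
    4: "external injury",
    10: "external injury",
    14: "external injury",
    7: "metabolic disorder",
    9: "metabolic disorder",
    15: "metabolic disorder",
    21: "metabolic disorder",
    23: "metabolic disorder",
    25: "metabolic disorder",
}


def decade_of(year: int) -> str:
    lo = (year // 10) * 10
    return f"{lo}-{lo + 9}"


def table1_fixture(include_identifiers: bool = False) -> MicrodataTable:
    """The 27-record lab-test example (sex + year of birth quasi-identifiers).

    Directly identifying name/phone columns are excluded unless requested.
    """
    records = {}
    for rid, name, phone, sex, yob, test, result, delay in _TABLE1_ROWS:
        row = {
            "Sex": sex,
            "YearOfBirth": str(yob),
            "LabTest": test,
            "LabResult": result,
            "PayDelay": str(delay),
        }
        if include_identifiers:
            row = {"Name": name, "TelephoneNumber": phone, **row}
        records[rid] = row
    return MicrodataTable(pd.DataFrame.from_dict(records, orient="index"))


def walkthrough_fixture() -> MicrodataTable:
    """Sex, ten-year birth decade and diagnosis for the algorithm walkthrough.

    The constructed diagnosis assignment is verified against all its
    documented constraints on every call; any drift raises ``AssertionError``.
    """
    rows = {}
    for rid, _name, _phone, sex, yob, *_rest in _TABLE1_ROWS:
        rows[rid] = {
            "Sex": sex,
            "YearOfBirth": decade_of(yob),
            "Diagnosis": _WALKTHROUGH_DIAGNOSIS[rid],
        }
    table = MicrodataTable(pd.DataFrame.from_dict(rows, orient="index"))
    _verify_walkthrough(table)
    return table


def _verify_walkthrough(table: MicrodataTable) -> None:
    sup = support(table, "Diagnosis")
    singles = [v for v, c in sup.items() if c == 1]
    assert sorted(singles) == [
        "COPD",
        "neurological problem",
        "pneumonia",
        "sepsis",
    ], "exactly these four singleton diagnoses expected"
    assert sup["cardiac condition"] == 3
    assert sup["arthropathy or spine disorder"] == 3
    assert sup["gastrointestinal bleeding"] == 3
    assert sup["acute respiratory problem"] == 4
    assert sup["external injury"] == 4
    assert sup["metabolic disorder"] == 6
    assert sum(sup.values()) == 27

    idx = equivalence_classes(table, ["Sex", "YearOfBirth", "Diagnosis"])

    def holders(diag):
        return {
            key: ids for key, ids in idx.classes.items() if key[2] == diag
        }

    # each support-3 diagnosis is one class of three (never in a small class)
    for diag in (
        "cardiac condition",
        "arthropathy or spine disorder",
        "gastrointestinal bleeding",
    ):
        sizes = sorted(len(ids) for ids in holders(diag).values())
        assert sizes == [3], f"{diag} must form a single class of 3"

    acute = holders("acute respiratory problem")
    assert frozenset({16, 19, 24}) in acute.values()
    assert frozenset({8}) in acute.values()

    ext = holders("external injury")
    assert frozenset({10, 14}) in ext.values(), "ids 10/14 share a size-2 class"

    met = holders("metabolic disorder")
    assert frozenset({23}) in met.values()
    assert frozenset({25}) in met.values()


# ---------------------------------------------------------------------------
# DAD-like generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorSpec:
    """Shape parameters for DAD-like microdata.

    Demographic category counts follow the national discharge abstract
    specification (10 provinces with the territories grouped, 20 five-year
    age groups top-coded at 90+, 5 gender codes of which two are common,
    25 length-of-stay weeks top-coded at 6 months).  Diagnosis and
    intervention code counts default to a ~1/18 toy scale of the national
    code inventories (8967 diagnosis codes, 545 case-mix groups, 523
    blocks, 19 chapters; 8780 interventions truncating to 569 short codes)
    so equivalence-class structure, not raw size, is preserved.  Roughly
    46% of records carry no intervention.  Value frequencies are Zipf-like
    with exponent ``skew``.
    """

    n: int = 1000
    seed: int = 0
    n_provinces: int = 10
    n_age_groups: int = 20
    n_genders: int = 5
    n_los_weeks: int = 25
    include_los: bool = False
    n_mrdx: int = 500
    n_cmg: int = 30
    n_block: int = 29
    n_chapter: int = 19
    n_cci: int = 480
    n_short_cci: int = 31
    empty_intervention_rate: float = 0.46
    skew: float = 1.0
    #: frequency split of the two common gender codes vs the three rare ones
    gender_probs: tuple = (0.49, 0.49, 0.012, 0.004, 0.004)

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("n_mrdx", "n_cmg", "n_block", "n_chapter",
                     "n_cci", "n_short_cci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_cmg > self.n_mrdx or self.n_block > self.n_mrdx:
            raise ValueError("hierarchy fan-out must be many-to-one")
        if self.n_chapter > self.n_block or self.n_short_cci > self.n_cci:
            raise ValueError("hierarchy fan-out must be many-to-one")
        if abs(sum(self.gender_probs) - 1.0) > 1e-9:
            raise ValueError("gender probabilities must sum to 1")


def _zipf_probs(n_categories: int, skew: float) -> np.ndarray:
    ranks = np.arange(1, n_categories + 1, dtype=float)
    w = ranks**-skew
    return w / w.sum()


def _age_group_labels(n: int) -> list[str]:
    labels = [f"{5 * i}-{5 * i + 4}" for i in range(n - 1)]
    labels.append(f"{5 * (n - 1)}+")
    return labels


def build_dad_hierarchies(spec: GeneratorSpec, rng: np.random.Generator):
    """Diagnosis and intervention hierarchies with consistent value maps.

    Each diagnosis code maps to exactly one case-mix group (branch edge,
    not totally ordered) and one block (chain edge); blocks map onto
    chapters contiguously; intervention codes truncate to short codes.
    """
    mrdx = [f"D{i:04d}" for i in range(spec.n_mrdx)]
    cmg = [f"G{i:03d}" for i in range(spec.n_cmg)]
    block = [f"B{i:03d}" for i in range(spec.n_block)]
    chapter = [f"C{i:02d}" for i in range(spec.n_chapter)]
    # blocks partition contiguously into chapters; codes into blocks
    block_of = {
        code: block[int(i * spec.n_block / spec.n_mrdx)]
        for i, code in enumerate(mrdx)
    }
    chapter_of = {
        b: chapter[int(i * spec.n_chapter / spec.n_block)]
        for i, b in enumerate(block)
    }
    # case-mix grouping also uses non-diagnosis information, so the map is
    # not alignable with the block chain: assign pseudo-randomly
    cmg_of = {code: cmg[int(g)] for code, g in
              zip(mrdx, rng.integers(0, spec.n_cmg, size=spec.n_mrdx))}
    diag = GeneralizationHierarchy(
        "diagnosis",
        [
            Level("MRDx", 1),
            Level("CMG_CODE", 2),
            Level("DIAG_BLOCK", 3),
            Level("DIAG_CHAPTER", 4),
        ],
        [
            Edge("MRDx", "CMG_CODE", cmg_of, totally_ordered=False),
            Edge("MRDx", "DIAG_BLOCK", block_of, totally_ordered=True),
            Edge("DIAG_BLOCK", "DIAG_CHAPTER", chapter_of, totally_ordered=True),
        ],
    )

    cci = ["NONE"] + [f"I{i:04d}" for i in range(spec.n_cci - 1)]
    short = ["NONE"] + [f"S{i:03d}" for i in range(spec.n_short_cci - 1)]
    short_of = {"NONE": "NONE"}
    for i, code in enumerate(cci[1:]):
        short_of[code] = short[1 + int(i * (spec.n_short_cci - 1) / (spec.n_cci - 1))]
    interv = GeneralizationHierarchy(
        "intervention",
        [Level("CCI_CODE", 1), Level("SHORT_CCI", 2)],
        [Edge("CCI_CODE", "SHORT_CCI", short_of, totally_ordered=True)],
    )
    return diag, interv, mrdx, cci


def generate_dad_like(
    spec: GeneratorSpec,
) -> tuple[MicrodataTable, Schema, dict[str, GeneralizationHierarchy]]:
    """Reproducible DAD-like microdata with schema and hierarchies."""
    rng = np.random.default_rng(spec.seed)
    diag_h, interv_h, mrdx_codes, cci_codes = build_dad_hierarchies(spec, rng)

    n = spec.n
    provinces = [f"P{i:02d}" for i in range(spec.n_provinces)]
    ages = _age_group_labels(spec.n_age_groups)
    genders = ["M", "F", "G3", "G4", "G5"][: spec.n_genders]

    data = {
        "PROV_ALL": rng.choice(
            provinces, size=n, p=_zipf_probs(len(provinces), spec.skew)
        ),
        "AGE_GROUP": rng.choice(
            ages, size=n, p=_zipf_probs(len(ages), spec.skew * 0.5)
        ),
        "GENDER_CODE": rng.choice(
            genders, size=n, p=np.asarray(spec.gender_probs)[: len(genders)]
        ),
        "MRDx": rng.choice(
            mrdx_codes, size=n, p=_zipf_probs(len(mrdx_codes), spec.skew)
        ),
    }
    if spec.include_los:
        weeks = [f"W{i:02d}" for i in range(spec.n_los_weeks - 1)] + ["176+"]
        data["TOTAL_LOS_WEEKS"] = rng.choice(
            weeks, size=n, p=_zipf_probs(len(weeks), spec.skew * 1.5)
        )
    # interventions: a point mass on "no intervention" plus a Zipf tail
    p_codes = _zipf_probs(len(cci_codes) - 1, spec.skew)
    cci_col = np.where(
        rng.random(n) < spec.empty_intervention_rate,
        "NONE",
        rng.choice(cci_codes[1:], size=n, p=p_codes),
    )
    data["CCI_CODE"] = cci_col

    df = pd.DataFrame(data, index=pd.RangeIndex(1, n + 1))
    table = MicrodataTable(df)

    qis = [
        QuasiIdentifier("PROV_ALL", frozenset(provinces)),
        QuasiIdentifier("AGE_GROUP", frozenset(ages)),
        QuasiIdentifier("GENDER_CODE", frozenset(genders)),
    ]
    if spec.include_los:
        qis.append(QuasiIdentifier("TOTAL_LOS_WEEKS", frozenset(weeks)))
    qis += [
        QuasiIdentifier(
            "MRDx", frozenset(mrdx_codes), hierarchy_ref=("diagnosis", "MRDx")
        ),
        QuasiIdentifier(
            "CCI_CODE",
            frozenset(cci_codes),
            hierarchy_ref=("intervention", "CCI_CODE"),
        ),
    ]
    hierarchies = {"diagnosis": diag_h, "intervention": interv_h}
    schema = Schema(qis, [], hierarchies)
    return table, schema, hierarchies


def draw_disjoint_samples(
    table: MicrodataTable, fraction: float, count: int, seed: int
) -> list[MicrodataTable]:
    """``count`` pairwise-disjoint simple random samples of ``fraction`` each.

    Mirrors drawing multiple public files from one population so no two
    released files share a patient.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if count * fraction > 1 + 1e-12:
        raise ValueError("count x fraction exceeds the table")
    rng = np.random.default_rng(seed)
    ids = np.asarray(table.record_ids, dtype=object)
    perm = rng.permutation(len(ids))
    size = int(fraction * len(ids))
    out = []
    for i in range(count):
        chosen = ids[perm[i * size : (i + 1) * size]]
        out.append(MicrodataTable(table.df.loc[list(chosen)].copy()))
    return out


# ---------------------------------------------------------------------------
# Identified population for matching simulations
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """Parameters for the identified synthetic population."""

    n: int = 10_000
    seed: int = 0
    n_provinces: int = 4
    n_age_groups: int = 10
    sexes: tuple = ("M", "F")
    skew: float = 1.0
    full_crossing: bool = True  # guarantee every stratum is non-empty

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")


def generate_population(
    spec: PopulationSpec,
) -> tuple[pd.DataFrame, PopulationTable]:
    """Identified individuals plus the exactly-matching aggregate table.

    The individual frame has columns ``person_id``, ``province``,
    ``age_group``, ``sex`` and a combined ``stratum`` label; the aggregate
    is its group-by count, so the two views are consistent by construction.
    """
    rng = np.random.default_rng(spec.seed)
    provinces = [f"P{i:02d}" for i in range(spec.n_provinces)]
    ages = _age_group_labels(spec.n_age_groups)
    sexes = list(spec.sexes)

    strata = [(p, a, s) for p in provinces for a in ages for s in sexes]
    if spec.full_crossing and spec.n < len(strata):
        raise ValueError("n too small to populate every stratum")
    probs = _zipf_probs(len(strata), spec.skew)
    counts = rng.multinomial(spec.n - (len(strata) if spec.full_crossing else 0),
                             probs)
    if spec.full_crossing:
        counts = counts + 1

    rows = []
    pid = 0
    for (p, a, s), c in zip(strata, counts):
        for _ in range(int(c)):
            rows.append((pid, p, a, s))
            pid += 1
    people = pd.DataFrame(
        rows, columns=["person_id", "province", "age_group", "sex"]
    )
    people["stratum"] = list(
        zip(people["province"], people["age_group"], people["sex"])
    )
    agg = (
        people.groupby(["province", "age_group", "sex"])
        .size()
        .reset_index(name="count")
    )
    return people, PopulationTable(agg)
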