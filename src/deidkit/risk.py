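"""Closed-form re-identification risk estimators and a matching-attack simulator.

Three attacks on a public-use microdata file (PUMF) that is a random sample
from a population are modelled.  Notation: for an equivalence class j on
the registry-matchable quasi-identifiers (province x age group x sex),
C_j is its size in the provincial population, f_j its size in the PUMF,
and F_j the population class size on the full released quasi-identifiers.

* **Attack 1** -- match one randomly chosen record against a population
  registry.  The probability of a correct match for a record in class j is
  1/C_j; the headline measure is the proportion of a province's population
  in classes with 1/C_j above the tolerance tau.
* **Attack 2** -- match *all* PUMF records against an overlapping registry.
  The expected number of correct matches is bounded by sum_j f_j / C_j,
  which under proportional sampling (f_j = alpha * C_j) collapses to
  Q * alpha for Q classes.
* **Attack 3** -- target a specific acquaintance.  The probability the
  matched record is the target is 1/F_j, so the release must guarantee
  F_j >= ceil(1/tau) for every class.

Only *correct* re-identifications are scored; the Monte Carlo simulator
reports incorrect-match counts as diagnostics but never in the risk
figures.  The simulator draws the PUMF and registry as independent simple
random samples of identified individuals and validates the closed forms
empirically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .suppression import k_from_threshold

#: Gender categories assumed to appear in population registries; the other
#: discharge-abstract gender codes are not tracked by registries and do not
#: participate in attack-1/2 strata.
REGISTRY_GENDERS = ("M", "F")


@dataclass
class PopulationTable:
    """Census-style stratum counts: (province, age_group, sex) -> count.

    Counts are assumed pre-weighted (survey weighting happens upstream).
    """

    strata: pd.DataFrame  # columns: province, age_group, sex, count

    def __post_init__(self):
        required = {"province", "age_group", "sex", "count"}
        missing = required - set(self.strata.columns)
        if missing:
            raise ValueError(f"population table missing columns {sorted(missing)}")
        if (self.strata["count"] <= 0).any():
            raise ValueError("stratum counts must be positive")
        key_cols = ["province", "age_group", "sex"]
        if self.strata.duplicated(key_cols).any():
            raise ValueError("duplicate strata")

    @classmethod
    def from_csv(cls, path) -> "PopulationTable":
        return cls(pd.read_csv(path, dtype={"count": int}))

    def province_totals(self) -> dict[str, int]:
        return self.strata.groupby("province")["count"].sum().to_dict()

    def class_sizes(
        self, registry_genders: tuple[str, ...] | None = REGISTRY_GENDERS
    ) -> dict[tuple, int]:
        """C_j per stratum, optionally restricted to registry-matchable sexes."""
        sub = self.strata
        if registry_genders is not None:
            sub = sub[sub["sex"].isin(registry_genders)]
        return {
            (row.province, row.age_group, row.sex): int(row.count)
            for row in sub.itertuples(index=False)
        }


@dataclass
class RiskReport:
    """Aggregated outputs of the three closed-form attacks."""

    tau: float
    attack1_by_province: dict[str, float] = field(default_factory=dict)
    attack2_expected_matches: float = 0.0
    attack3_max_risk: float = 0.0
    attack3_pass: bool = False

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "attack1_by_province": self.attack1_by_province,
            "attack2_expected_matches": self.attack2_expected_matches,
            "attack3_max_risk": self.attack3_max_risk,
            "attack3_pass": self.attack3_pass,
        }


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------


def attack1_proportion(pop: PopulationTable, tau: float) -> dict[str, float]:
    """Per province: fraction of people in classes with risk 1/C_j > tau."""
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    if len(pop.strata) == 0:
        raise ValueError("empty population")
    totals = pop.province_totals()
    out: dict[str, float] = {}
    for province, group in pop.strata.groupby("province"):
        exposed = int(group.loc[1.0 / group["count"] > tau, "count"].sum())
        out[str(province)] = exposed / totals[province]
    return out


def attack2_expected_matches(
    pumf_sizes: dict[tuple, int], pop_sizes: dict[tuple, int]
) -> float:
    """Expected number of correct matches: sum_j f_j / C_j."""
    total = 0.0
    for key, f_j in pumf_sizes.items():
        if f_j == 0:
            continue
        if key not in pop_sizes:
            raise KeyError(f"PUMF stratum {key!r} absent from population")
        total += f_j / pop_sizes[key]
    return total


def attack2_expected_matches_sampling(Q: int, alpha: float) -> float:
    """Proportional-sampling form: Q * alpha correct matches expected."""
    if Q < 0:
        raise ValueError("Q must be >= 0")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    return Q * alpha


def attack3_risk(
    pop_sizes: dict[tuple, int], tau: float | None = None
) -> tuple[float, dict[tuple, float], bool | None]:
    """Per-stratum risk 1/F_j, the maximum, and the tau pass flag."""
    if not pop_sizes:
        raise ValueError("no strata")
    for key, f in pop_sizes.items():
        if f < 1:
            raise ValueError(f"stratum {key!r} has non-positive size")
    per = {key: 1.0 / f for key, f in pop_sizes.items()}
    max_risk = max(per.values())
    passed = None
    if tau is not None:
        # max risk <= tau  <=>  min F_j >= ceil(1/tau)
        passed = min(pop_sizes.values()) >= k_from_threshold(tau)
    return max_risk, per, passed


# ---------------------------------------------------------------------------
# Monte Carlo matching-attack simulator
# ---------------------------------------------------------------------------


@dataclass
class MatchingSimReport:
    """Empirical vs. closed-form matching results over replicates.

    Per-stratum attack-1 standard errors are computed under the null
    (binomial with success probability 1/C_j), so strata that happen to
    record zero hits are still comparable.  ``attack1_within`` checks the
    hit total pooled over strata -- one z-test instead of dozens of
    simultaneous per-stratum tests.
    """

    reps: int
    attack1_hits_by_stratum: dict[tuple, int]
    attack1_tries_by_stratum: dict[tuple, int]
    attack1_predicted: dict[tuple, float]  # 1 / C_j
    attack2_mean_correct: float
    attack2_se: float
    attack2_predicted: float  # E[sum_j f_j / C_j] over PUMF draws
    incorrect_mean: float  # diagnostics only

    @property
    def attack1_rate_by_stratum(self) -> dict[tuple, float]:
        return {
            s: self.attack1_hits_by_stratum[s] / t
            for s, t in self.attack1_tries_by_stratum.items()
            if t > 0
        }

    def attack1_within(self, n_se: float = 3.0) -> bool:
        """Pooled attack-1 hit count within n_se of its closed-form mean."""
        total = expected = var = 0.0
        for s, tries in self.attack1_tries_by_stratum.items():
            if tries == 0:
                continue
            p0 = self.attack1_predicted[s]
            total += self.attack1_hits_by_stratum[s]
            expected += tries * p0
            var += tries * p0 * (1 - p0)
        return bool(abs(total - expected) <= n_se * max(np.sqrt(var), 1e-12))

    def attack1_fraction_within(self, n_se: float = 3.0) -> float:
        """Share of strata whose empirical rate is within n_se null SEs."""
        ok = tested = 0
        for s, tries in self.attack1_tries_by_stratum.items():
            if tries == 0:
                continue
            tested += 1
            p0 = self.attack1_predicted[s]
            se = np.sqrt(p0 * (1 - p0) / tries)
            rate = self.attack1_hits_by_stratum[s] / tries
            if abs(rate - p0) <= n_se * max(se, 1e-12):
                ok += 1
        return ok / tested if tested else 1.0

    def attack2_within(self, n_se: float = 3.0) -> bool:
        se = max(self.attack2_se, 1e-12)
        return bool(
            abs(self.attack2_mean_correct - self.attack2_predicted) <= n_se * se
        )


def simulate_matching_attack(
    population: pd.DataFrame,
    pumf_fraction: float,
    registry_fraction: float,
    reps: int,
    seed: int,
) -> MatchingSimReport:
    """Replicate the registry matching attacks on an identified population.

    ``population`` has one row per individual with columns ``person_id``
    and ``stratum`` (any hashable stratum label).  Each replicate draws the
    PUMF and registry as independent simple random samples.  Attack 1
    matches one random record per stratum present in both files; attack 2
    matches every PUMF record to a random same-stratum registry record.
    A match is correct when it recovers the true person identity.  Strata
    with no overlap contribute zero matches.
    """
    if not 0 < pumf_fraction <= 1 or not 0 < registry_fraction <= 1:
        raise ValueError("fractions must be in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    persons = population["person_id"].to_numpy()
    strata = population["stratum"].to_numpy()
    n = len(persons)
    c_j = pd.Series(strata).value_counts().to_dict()

    n_pumf = int(round(pumf_fraction * n))
    n_reg = int(round(registry_fraction * n))

    a1_hits: dict[tuple, int] = {key: 0 for key in c_j}
    a1_tries: dict[tuple, int] = {key: 0 for key in c_j}
    a2_correct = np.zeros(reps)
    a2_incorrect = np.zeros(reps)
    a2_expected_fc = np.zeros(reps)  # realized sum f_j / C_j per replicate

    for r in range(reps):
        pumf_idx = rng.choice(n, size=n_pumf, replace=False)
        reg_idx = rng.choice(n, size=n_reg, replace=False)
        pumf = pd.DataFrame({"pid": persons[pumf_idx], "s": strata[pumf_idx]})
        reg_groups: dict = {}
        for pid, s in zip(persons[reg_idx], strata[reg_idx]):
            reg_groups.setdefault(s, []).append(pid)

        # attack 2: exact-match every PUMF record
        for s, group in pumf.groupby("s"):
            a2_expected_fc[r] += len(group) / c_j[s]
            if s not in reg_groups:
                continue
            pool = np.asarray(reg_groups[s])
            picks = pool[rng.integers(0, len(pool), size=len(group))]
            correct = int((picks == group["pid"].to_numpy()).sum())
            a2_correct[r] += correct
            a2_incorrect[r] += len(group) - correct

        # attack 1: one random record per stratum present in both files
        for s, group in pumf.groupby("s"):
            if s not in reg_groups:
                continue
            a1_tries[s] += 1
            target = group["pid"].to_numpy()[rng.integers(0, len(group))]
            pool = reg_groups[s]
            pick = pool[rng.integers(0, len(pool))]
            if pick == target:
                a1_hits[s] += 1

    a1_pred = {s: 1.0 / c for s, c in c_j.items()}

    return MatchingSimReport(
        reps=reps,
        attack1_hits_by_stratum=a1_hits,
        attack1_tries_by_stratum=a1_tries,
        attack1_predicted=a1_pred,
        attack2_mean_correct=float(a2_correct.mean()),
        attack2_se=float(a2_correct.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
        attack2_predicted=float(a2_expected_fc.mean()),
        incorrect_mean=float(a2_incorrect.mean()),
    )


def pumf_class_sizes(
    table_df: pd.DataFrame, columns: list[str]
) -> dict[tuple, int]:
    """f_j per value-tuple of ``columns`` in a released file."""
    return {
        tuple(key) if isinstance(key, tuple) else (key,): int(size)
        for key, size in table_df.groupby(columns).size().items()
    }


def build_risk_report(
    pop: PopulationTable,
    pumf_sizes: dict[tuple, int],
    full_qi_pop_sizes: dict[tuple, int],
    tau: float,
) -> RiskReport:
    """Run all three closed-form attacks and collect the results."""
    a1 = attack1_proportion(pop, tau)
    c_sizes = pop.class_sizes()
    a2 = attack2_expected_matches(pumf_sizes, c_sizes)
    max_risk, _per, passed = attack3_risk(full_qi_pop_sizes, tau)
    return RiskReport(
        tau=tau,
        attack1_by_province=a1,
        attack2_expected_matches=a2,
        attack3_max_risk=max_risk,
        attack3_pass=bool(passed),
    )
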