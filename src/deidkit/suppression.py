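"""Two-phase heuristic local cell suppression over quasi-identifier combinations.

Given a minimum equivalence-class size k = ceil(1/tau), the algorithm
repairs every *mole* -- an equivalence class smaller than k on some
attackable combination -- by blanking individual cells rather than whole
records or columns:

* **Phase 1** (value-wise): any category whose support (number of records
  holding it) is below k is blanked everywhere it occurs; such values can
  never sit in a class of size >= k.
* **Phase 2** (cell-wise): combinations are processed in descending order
  of mole count.  Within a combination, categories are visited in ascending
  weighted support wsup(l) = sup(l) * w and each is blanked only inside the
  equivalence classes of size < k that contain it.  Supports and the class
  index are recomputed after every visit.

Two stopping rules are provided.  ``strict`` (default) repeats passes until
no mole contains a non-sentinel cell -- the auditable fixed point (a class
keyed entirely by sentinels still counts as a class, so "no moles at all"
is unachievable in general).  ``walkthrough`` performs exactly one
ascending pass per combination, the behaviour of the published worked
example, and is what the fixture tests replay.

The ``complete`` baseline is the same algorithm with a single combination
holding every quasi-identifier; it suppresses strictly more than the
combinations run on overlapping-hierarchy data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .core import (
    SENTINEL,
    MicrodataTable,
    Schema,
    equivalence_classes,
    recode,
    support,
)
from .combinations import (
    AdversaryKnowledge,
    Combination,
    CombinationSet,
    enumerate_combinations,
    plan_release_levels,
    propagate_suppressions,
)


def k_from_threshold(tau: float) -> int:
    """Minimum class size k = ceil(1/tau) for a re-identification threshold.

    Uses exact rational arithmetic on the decimal literal so that e.g.
    tau = 0.04 yields 25, not 26 from binary-float round-off.
    """
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    return math.ceil(1 / Fraction(str(tau)))


@dataclass(frozen=True)
class AuditEntry:
    """One suppressed cell and the reason it was blanked."""

    record_id: object
    column: str
    value: str
    phase: str  # "phase1" | "phase2" | "propagation"
    combination_id: str
    ec_size: int  # class size (phase 2) or value support (phase 1) at the time
    pass_number: int


@dataclass
class SuppressionAudit:
    """Ordered, replayable log of every suppression decision."""

    entries: list[AuditEntry] = field(default_factory=list)

    def extend(self, other: "SuppressionAudit") -> None:
        self.entries.extend(other.entries)

    def apply(self, table: MicrodataTable) -> MicrodataTable:
        """Replay the audit on ``table``; reproduces the algorithm output."""
        return table.with_suppressed([(e.record_id, e.column) for e in self.entries])

    def cells(self) -> set[tuple]:
        return {(e.record_id, e.column) for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "record_id": e.record_id,
                    "column": e.column,
                    "value": e.value,
                    "phase": e.phase,
                    "combination_id": e.combination_id,
                    "ec_size": e.ec_size,
                    "pass": e.pass_number,
                }
                for e in self.entries
            ],
            columns=[
                "record_id",
                "column",
                "value",
                "phase",
                "combination_id",
                "ec_size",
                "pass",
            ],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SuppressionConfig:
    """Run parameters: exactly one of k / tau; weights default to 1."""

    k: int | None = None
    tau: float | None = None
    mode: str = "strict"  # "strict" | "walkthrough"
    weights: dict[str, float] = field(default_factory=dict)
    sentinel_text: str = ""

    def resolve_k(self) -> int:
        if (self.k is None) == (self.tau is None):
            raise ValueError("provide exactly one of k or tau")
        k = self.k if self.k is not None else k_from_threshold(self.tau)
        if k < 1:
            raise ValueError("k must be >= 1")
        return k


# ---------------------------------------------------------------------------
# Phase 1
# ---------------------------------------------------------------------------


def phase1_suppress(
    table: MicrodataTable, combos: CombinationSet, k: int
) -> tuple[MicrodataTable, SuppressionAudit]:
    """Blank every category with support < k, in every cell that holds it.

    Operates column-wise over all quasi-identifiers that appear in any
    combination.  Suppressing one value never changes another value's
    support (supports count non-sentinel cells per value), so a single
    sweep per column reaches the fixed point.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    columns: list[str] = []
    for combo in combos:
        for col in combo.columns:
            if col not in columns:
                columns.append(col)
    audit = SuppressionAudit()
    df = table.df.copy()
    for col in columns:
        counts = df[col].value_counts()
        rare = [v for v, c in counts.items() if v != SENTINEL and c < k]
        for value in rare:
            mask = df[col] == value
            for rid in df.index[mask]:
                audit.entries.append(
                    AuditEntry(
                        record_id=rid,
                        column=col,
                        value=value,
                        phase="phase1",
                        combination_id="*",
                        ec_size=int(counts[value]),
                        pass_number=0,
                    )
                )
            df.loc[mask, col] = SENTINEL
    return MicrodataTable(df), audit


# ---------------------------------------------------------------------------
# Phase 2
# ---------------------------------------------------------------------------


def suppress_value_in_moles(
    table: MicrodataTable,
    combination: Combination | list[str],
    value: tuple[str, str],
    k: int,
    *,
    combination_id: str = "?",
    pass_number: int = 0,
) -> tuple[MicrodataTable, list[AuditEntry]]:
    """Blank ``value = (column, category)`` inside every class of size < k.

    Classes of size >= k that hold the value are untouched: the value
    itself may be frequent overall yet expose only a few records.
    """
    columns = list(combination.columns) if isinstance(combination, Combination) else list(combination)
    col, category = value
    if col not in columns:
        raise KeyError(f"column {col!r} not in combination {columns}")
    idx = equivalence_classes(table, columns)
    pos = columns.index(col)
    entries: list[AuditEntry] = []
    cells: list[tuple] = []
    for key, ids in idx.classes.items():
        if key[pos] == category and len(ids) < k:
            for rid in sorted(ids, key=str):
                cells.append((rid, col))
                entries.append(
                    AuditEntry(
                        record_id=rid,
                        column=col,
                        value=category,
                        phase="phase2",
                        combination_id=combination_id,
                        ec_size=len(ids),
                        pass_number=pass_number,
                    )
                )
    return table.with_suppressed(cells), entries


def _mole_count(table: MicrodataTable, columns: list[str], k: int) -> int:
    idx = equivalence_classes(table, columns)
    return sum(1 for ids in idx.classes.values() if len(ids) < k)


def _candidate_order_key(
    columns: list[str], weights: dict[str, float]
) -> "callable":
    def key(item):
        (col, category), sup = item
        w = weights.get(col, 1.0)
        return (sup * w, columns.index(col), category)

    return key


def _moles_with_open_cells(table, columns, k):
    """Moles that still contain at least one non-sentinel cell."""
    idx = equivalence_classes(table, columns)
    return {
        key: ids
        for key, ids in idx.classes.items()
        if len(ids) < k and any(v != SENTINEL for v in key)
    }


def phase2_suppress(
    table: MicrodataTable,
    combos: CombinationSet,
    k: int,
    weights: dict[str, float] | None = None,
    mode: str = "strict",
) -> tuple[MicrodataTable, SuppressionAudit]:
    """Mole-driven cell suppression across combinations.

    Combinations are ordered by descending initial mole count (ties by
    declaration order).  Raises if phase 1 was skipped (some value in scope
    still has 0 < support < k).
    """
    if mode not in ("strict", "walkthrough"):
        raise ValueError(f"unknown mode {mode!r}")
    weights = weights or {}
    in_scope: list[str] = []
    for combo in combos:
        for col in combo.columns:
            if col not in in_scope:
                in_scope.append(col)
    for col in in_scope:
        for value, cnt in support(table, col).items():
            if cnt < k:
                raise ValueError(
                    f"phase 1 precondition violated: {col!r}={value!r} "
                    f"has support {cnt} < k={k}"
                )

    ordered = sorted(
        enumerate(combos),
        key=lambda item: (-_mole_count(table, list(item[1].columns), k), item[0]),
    )
    audit = SuppressionAudit()
    current = table
    if mode == "walkthrough":
        for _, combo in ordered:
            current = _walkthrough_pass(
                current, combo, list(combo.columns), k, weights, audit
            )
        return current, audit
    # strict: suppressing cells for one combination can open new moles on a
    # previously settled combination (the columns overlap), so sweep the
    # ordered combinations until a full sweep changes nothing
    while True:
        before = len(audit.entries)
        for _, combo in ordered:
            current = _strict_passes(
                current, combo, list(combo.columns), k, weights, audit
            )
        if len(audit.entries) == before:
            return current, audit


def _walkthrough_pass(table, combo, columns, k, weights, audit):
    """One ascending-weighted-support visit of every value in the combination."""
    visited: set[tuple[str, str]] = set()
    pass_number = 0
    key = _candidate_order_key(columns, weights)
    while True:
        candidates = {
            (col, value): sup
            for col in columns
            for value, sup in support(table, col).items()
            if (col, value) not in visited
        }
        if not candidates:
            return table
        (col, value), _sup = min(candidates.items(), key=key)
        visited.add((col, value))
        pass_number += 1
        table, entries = suppress_value_in_moles(
            table,
            combo,
            (col, value),
            k,
            combination_id=combo.id,
            pass_number=pass_number,
        )
        audit.entries.extend(entries)


def _strict_passes(table, combo, columns, k, weights, audit):
    """Repeat value visits until every mole is fully suppressed.

    Each productive visit blanks at least one cell of a finite total, so
    termination is guaranteed.
    """
    pass_number = 0
    key = _candidate_order_key(columns, weights)
    while True:
        moles = _moles_with_open_cells(table, columns, k)
        if not moles:
            return table
        open_values: set[tuple[str, str]] = set()
        for mole_key in moles:
            for col, v in zip(columns, mole_key):
                if v != SENTINEL:
                    open_values.add((col, v))
        candidates = {
            (col, v): support(table, col).get(v, 0) for col, v in open_values
        }
        (col, value), _sup = min(candidates.items(), key=key)
        pass_number += 1
        table, entries = suppress_value_in_moles(
            table,
            combo,
            (col, value),
            k,
            combination_id=combo.id,
            pass_number=pass_number,
        )
        audit.entries.extend(entries)


# ---------------------------------------------------------------------------
# Full pipelines
# ---------------------------------------------------------------------------


def materialize_levels(
    table: MicrodataTable, schema: Schema, knowledge: AdversaryKnowledge
) -> tuple[MicrodataTable, dict[str, dict[str, str]]]:
    """Add one column per released hierarchy level for each hierarchical QI.

    Every level no coarser than the release level M is derived from the
    QI's raw column by table-driven recoding; the raw column is replaced by
    its level columns (named after the levels).  Returns the widened table
    and, per QI, the level -> column-name map used for propagation.
    """
    plan = plan_release_levels(schema, knowledge)
    level_cols: dict[str, dict[str, str]] = {}
    current = table
    for qi_name, spec in knowledge.hierarchical.items():
        qi = schema.qi(qi_name)
        if qi.hierarchy_ref is None:
            raise ValueError(f"{qi_name!r} has no hierarchy")
        hname, raw_level = qi.hierarchy_ref
        hierarchy = schema.hierarchies[hname]
        _s_level, m_level = plan[qi_name]
        m_rank = hierarchy.rank(m_level)
        wanted = sorted(
            (
                lv
                for lv in hierarchy.levels.values()
                if lv.rank >= m_rank
                and (
                    lv.name == raw_level
                    or lv.name in hierarchy.reachable_coarser(raw_level)
                )
            ),
            key=lambda lv: (lv.rank, lv.name),
        )
        cols: dict[str, str] = {}
        for lv in wanted:
            current = recode(
                current, qi_name, hierarchy, raw_level, lv.name, new_column=lv.name
            )
            cols[lv.name] = lv.name
        if qi_name not in cols.values():
            current = MicrodataTable(current.df.drop(columns=[qi_name]))
        level_cols[qi_name] = cols
    return current, level_cols


def run_combinations_algorithm(
    table: MicrodataTable,
    schema: Schema,
    knowledge: AdversaryKnowledge,
    config: SuppressionConfig,
) -> tuple[MicrodataTable, SuppressionAudit]:
    """Recode -> enumerate combinations -> phase 1 -> phase 2 -> propagate."""
    k = config.resolve_k()
    weights = dict(config.weights) or {
        q.name: q.weight for q in schema.quasi_identifiers
    }
    current, level_cols = materialize_levels(table, schema, knowledge)
    combos = enumerate_combinations(schema, knowledge)
    current, audit = phase1_suppress(current, combos, k)
    current, audit2 = phase2_suppress(current, combos, k, weights, config.mode)
    audit.extend(audit2)
    current = _propagate_all(current, schema, knowledge, combos, level_cols, audit)
    return current, audit


def run_complete_algorithm(
    table: MicrodataTable,
    schema: Schema,
    knowledge: AdversaryKnowledge | None,
    config: SuppressionConfig,
) -> tuple[MicrodataTable, SuppressionAudit]:
    """Baseline: identical pipeline with one all-quasi-identifier combination.

    With ``knowledge`` the released levels are materialized first and the
    single combination spans the demographics plus every evaluated level
    column; without it the schema's quasi-identifier columns are used as-is.
    """
    k = config.resolve_k()
    weights = dict(config.weights) or {
        q.name: q.weight for q in schema.quasi_identifiers
    }
    if knowledge is None or not knowledge.hierarchical:
        columns = tuple(schema.qi_names)
        combos = CombinationSet([Combination(id="all", columns=columns)])
        current = table
        level_cols: dict[str, dict[str, str]] = {}
    else:
        current, level_cols = materialize_levels(table, schema, knowledge)
        evaluated = enumerate_combinations(schema, knowledge)
        columns_list: list[str] = []
        for combo in evaluated:
            for col in combo.columns:
                if col not in columns_list:
                    columns_list.append(col)
        combos = CombinationSet(
            [Combination(id="all", columns=tuple(columns_list))]
        )
    current, audit = phase1_suppress(current, combos, k)
    current, audit2 = phase2_suppress(current, combos, k, weights, config.mode)
    audit.extend(audit2)
    if knowledge is not None and knowledge.hierarchical:
        current = _propagate_all(
            current, schema, knowledge, combos, level_cols, audit
        )
    return current, audit


def _propagate_all(table, schema, knowledge, combos, level_cols, audit):
    """Propagate per-record suppressions from every evaluated level column."""
    evaluated_cols = set()
    for combo in combos:
        evaluated_cols.update(combo.columns)
    for qi_name, spec in knowledge.hierarchical.items():
        hierarchy = schema.hierarchies[spec.hierarchy]
        cols = level_cols.get(qi_name, {})
        for level, col in cols.items():
            if col not in evaluated_cols or col not in table.columns:
                continue
            before = table
            table, cells = propagate_suppressions(table, hierarchy, level, cols)
            for rid, target_col in cells:
                audit.entries.append(
                    AuditEntry(
                        record_id=rid,
                        column=target_col,
                        value=str(before.df.at[rid, target_col]),
                        phase="propagation",
                        combination_id=f"{qi_name}:{level}",
                        ec_size=0,
                        pass_number=0,
                    )
                )
    return table
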