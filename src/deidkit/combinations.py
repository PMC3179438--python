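"""Enumeration of attackable quasi-identifier combinations.

An adversary is assumed to know each hierarchical quasi-identifier at some
level of detail Q (e.g. the case-mix group but not the full ICD-10 code).
The released file carries one column per hierarchy level, so every level at
or above Q must be protected: the probability of re-identification is
evaluated once per combination of (demographics x one level per
hierarchical quasi-identifier).

Along totally-ordered hierarchy chains the coarser evaluation can be
skipped: suppressions at the finer level are simply propagated upward,
which is what :func:`propagate_suppressions` implements (together with the
mandatory downward propagation -- a record whose case-mix group is blanked
must not reveal the diagnosis code it derives from).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    SENTINEL,
    GeneralizationHierarchy,
    HierarchyError,
    MicrodataTable,
    Schema,
)


@dataclass(frozen=True)
class KnowledgeSpec:
    """Adversary/analyst levels for one hierarchical quasi-identifier.

    ``knowledge_level`` (Q) is the most detailed level the adversary is
    assumed to know; ``release_level`` (M) the most detailed level the
    analysts require in the released file.
    """

    hierarchy: str
    knowledge_level: str
    release_level: str | None = None


@dataclass
class AdversaryKnowledge:
    """Per-QI background-knowledge assumptions driving the enumeration."""

    hierarchical: dict[str, KnowledgeSpec] = field(default_factory=dict)
    skip_totally_ordered: bool = True


@dataclass(frozen=True)
class Combination:
    """One attackable set of (column-name) quasi-identifiers."""

    id: str
    columns: tuple[str, ...]
    #: (qi name, level name) for the hierarchical members, for provenance.
    levels: tuple[tuple[str, str], ...] = ()


@dataclass
class CombinationSet:
    combinations: list[Combination]

    def __len__(self) -> int:
        return len(self.combinations)

    def __iter__(self):
        return iter(self.combinations)

    def column_sets(self) -> list[tuple[str, ...]]:
        return [c.columns for c in self.combinations]


def level_column(qi_name: str, level: str) -> str:
    """Column name used for a hierarchical QI released at ``level``.

    The level at which the QI's raw column already lives keeps its own
    name; coarser levels get ``level`` as the column name (hierarchy level
    names are unique per schema in practice, e.g. CMG_CODE, DIAG_BLOCK).
    """
    return level


def evaluated_levels(
    hierarchy: GeneralizationHierarchy,
    knowledge_level: str,
    skip_totally_ordered: bool,
) -> list[str]:
    """Levels at which re-identification must be evaluated.

    All levels no more detailed than the knowledge level are candidates
    (rank >= rank(Q)); with skipping enabled, a level reachable from
    another evaluated level via a totally-ordered path is handled by
    propagation instead of its own evaluation.
    """
    q_rank = hierarchy.rank(knowledge_level)
    candidates = sorted(
        (lv for lv in hierarchy.levels.values() if lv.rank >= q_rank),
        key=lambda lv: (lv.rank, lv.name),
    )
    names = [lv.name for lv in candidates]
    if knowledge_level not in names:
        raise HierarchyError(
            f"knowledge level {knowledge_level!r} missing from hierarchy"
        )
    if not skip_totally_ordered:
        return names
    kept: list[str] = []
    for name in names:
        covered = any(
            name in hierarchy.reachable_coarser(other, totally_ordered_only=True)
            for other in names
            if other != name
        )
        if not covered:
            kept.append(name)
    return kept


def enumerate_combinations(
    schema: Schema, knowledge: AdversaryKnowledge
) -> CombinationSet:
    """Cross product of evaluated levels, each joined with all demographics.

    Demographic (non-hierarchical) quasi-identifiers appear in every
    combination; hierarchical ones contribute one evaluated level each.
    Output order is lexicographic in (QI declaration order, level rank) so
    audit logs are reproducible.
    """
    demographic = [
        q.name for q in schema.quasi_identifiers if q.name not in knowledge.hierarchical
    ]
    per_qi: list[tuple[str, list[str]]] = []
    for qi_name, spec in knowledge.hierarchical.items():
        hierarchy = schema.hierarchies[spec.hierarchy]
        levels = evaluated_levels(
            hierarchy, spec.knowledge_level, knowledge.skip_totally_ordered
        )
        per_qi.append((qi_name, levels))

    combos: list[Combination] = []

    def build(idx: int, chosen: list[tuple[str, str]]):
        if idx == len(per_qi):
            columns = tuple(demographic) + tuple(
                level_column(q, lv) for q, lv in chosen
            )
            combos.append(
                Combination(
                    id=f"c{len(combos) + 1}",
                    columns=columns,
                    levels=tuple(chosen),
                )
            )
            return
        qi_name, levels = per_qi[idx]
        for lv in levels:
            build(idx + 1, chosen + [(qi_name, lv)])

    build(0, [])
    seen = set()
    for c in combos:
        key = frozenset(c.columns)
        if key in seen:
            raise ValueError(f"duplicate combination {c.columns}")
        seen.add(key)
    return CombinationSet(combos)


def plan_release_levels(
    schema: Schema, knowledge: AdversaryKnowledge
) -> dict[str, tuple[str, str]]:
    """Suppression level S and release level per hierarchical QI.

    If the analysts accept a generalization at or above the adversary's
    knowledge (M >= Q, i.e. M is coarser or equal), suppress and release at
    M.  If they need more detail than the adversary knows (M < Q), suppress
    at Q and release at M, with the finer values blanked wherever they
    generalize to a suppressed value (downward propagation).
    """
    plan: dict[str, tuple[str, str]] = {}
    for qi_name, spec in knowledge.hierarchical.items():
        hierarchy = schema.hierarchies[spec.hierarchy]
        q_level = spec.knowledge_level
        m_level = spec.release_level or q_level
        q_rank = hierarchy.rank(q_level)
        m_rank = hierarchy.rank(m_level)
        if m_rank >= q_rank:  # M coarser or equal: release exactly at M
            plan[qi_name] = (m_level, m_level)
        else:  # analysts need more detail than the adversary knows
            plan[qi_name] = (q_level, m_level)
    return plan


def propagate_suppressions(
    table: MicrodataTable,
    hierarchy: GeneralizationHierarchy,
    source_level: str,
    level_columns: dict[str, str] | None = None,
) -> tuple[MicrodataTable, list[tuple]]:
    """Propagate per-record suppressions from ``source_level`` to other levels.

    Downward: a record whose source-level cell is blanked has every
    finer-level cell of the same hierarchy blanked, so the suppressed value
    cannot be re-derived.  Upward: along totally-ordered edges only, the
    coarser chain cells are blanked as well (they are deterministic images
    of the suppressed finer value and were not evaluated separately).
    Returns the new table and the list of (record_id, column) cells blanked.
    """
    level_columns = level_columns or {
        lv: level_column("", lv) for lv in hierarchy.levels
    }
    if source_level not in hierarchy.levels:
        raise HierarchyError(f"unknown level {source_level!r}")
    src_col = level_columns[source_level]
    targets = [
        level_columns[lv]
        for lv in hierarchy.finer_levels(source_level)
        if level_columns.get(lv) in table.columns
    ] + [
        level_columns[lv]
        for lv in hierarchy.reachable_coarser(source_level, totally_ordered_only=True)
        if level_columns.get(lv) in table.columns
    ]
    if src_col not in table.columns:
        raise KeyError(f"source column {src_col!r} not in table")
    cells = []
    mask = table.df[src_col] == SENTINEL
    for rid in table.df.index[mask]:
        for col in targets:
            if table.df.at[rid, col] != SENTINEL:
                cells.append((rid, col))
    return table.with_suppressed(cells), cells
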