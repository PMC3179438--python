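"""Core data model for categorical microdata de-identification.

The central objects are:

* :class:`MicrodataTable` -- a rectangular categorical dataset (one row per
  discharge record) in which any quasi-identifier cell may hold the reserved
  suppression sentinel :data:`SENTINEL`.
* :class:`QuasiIdentifier` / :class:`Schema` -- the declaration of which
  columns an adversary can plausibly know, their permitted category domains,
  their suppression weights, and which generalization hierarchy (if any)
  each belongs to.
* :class:`GeneralizationHierarchy` -- named precision levels connected by
  many-to-one value maps.  The level graph is a DAG, not necessarily a total
  order: a diagnosis code can generalize both to a case-mix group and,
  along a separate totally-ordered chain, to its ICD block and chapter.
* :class:`EquivalenceClassIndex` -- the partition of records induced by
  their exact value-tuple on a combination of columns.

All recoding is table-driven: interval codings such as 5-year age bins or
length-of-stay weeks are expressed as explicit value maps, so every
transformation is auditable.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

#: Reserved cell value marking a suppressed quasi-identifier cell.  It is
#: rejected as an ordinary category on load unless suppression is explicitly
#: permitted, so it can never collide with real data.
SENTINEL = "<suppressed>"


class DomainError(ValueError):
    """A cell value falls outside the declared domain of its column."""


class HierarchyError(ValueError):
    """A hierarchy is malformed or a requested level path does not exist."""


# ---------------------------------------------------------------------------
# Microdata
# ---------------------------------------------------------------------------


class MicrodataTable:
    """A categorical microdata table with unique record ids.

    Wraps a :class:`pandas.DataFrame` of strings whose index holds the
    record ids.  Cells may contain :data:`SENTINEL`.  Instances are treated
    as immutable by the rest of the package: operations return copies.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate record ids: {dupes[:5]}")
        self._df = df.astype("object")

    # -- basic accessors ---------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def columns(self) -> list[str]:
        return list(self._df.columns)

    @property
    def record_ids(self) -> list:
        return list(self._df.index)

    def cell(self, record_id, column: str):
        return self._df.at[record_id, column]

    def copy(self) -> "MicrodataTable":
        return MicrodataTable(self._df.copy())

    def is_suppressed(self, record_id, column: str) -> bool:
        return self._df.at[record_id, column] == SENTINEL

    def suppressed_mask(self, columns: list[str] | None = None) -> pd.DataFrame:
        cols = columns if columns is not None else self.columns
        return self._df[cols] == SENTINEL

    def with_suppressed(self, cells: list[tuple]) -> "MicrodataTable":
        """Return a copy with the given ``(record_id, column)`` cells blanked."""
        df = self._df.copy()
        for rid, col in cells:
            df.at[rid, col] = SENTINEL
        return MicrodataTable(df)

    def equals(self, other: "MicrodataTable") -> bool:
        return self._df.equals(other._df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MicrodataTable(n={self.n}, columns={self.columns})"


# ---------------------------------------------------------------------------
# Quasi-identifiers and hierarchies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuasiIdentifier:
    """A background-knowledge column an adversary can use for linkage.

    ``weight`` in [0, 1] expresses analytic importance: a higher weight
    makes phase-2 suppression prefer other quasi-identifiers.  ``domain``
    of ``None`` means "infer from data on load".
    """

    name: str
    domain: frozenset | None = None
    weight: float = 1.0
    hierarchy_ref: tuple[str, str] | None = None  # (hierarchy name, level name)

    def __post_init__(self):
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight of {self.name!r} must be in [0, 1]")
        if self.domain is not None and len(self.domain) == 0:
            raise ValueError(f"domain of {self.name!r} must be non-empty")


@dataclass(frozen=True)
class Level:
    name: str
    rank: int  # 1 = most detailed


@dataclass(frozen=True)
class Edge:
    finer: str
    coarser: str
    mapping: dict
    totally_ordered: bool = False


class GeneralizationHierarchy:
    """A DAG of precision levels with many-to-one value maps on its edges.

    Level rank 1 is the most detailed.  Edges flagged ``totally_ordered``
    form simple chains (e.g. diagnosis block -> chapter); branch edges
    (e.g. diagnosis code -> case-mix group) are not totally ordered and
    never participate in upward suppression propagation.
    """

    def __init__(self, name: str, levels: list[Level], edges: list[Edge]):
        self.name = name
        self.levels = {lv.name: lv for lv in levels}
        if len(self.levels) != len(levels):
            raise HierarchyError(f"duplicate level names in hierarchy {name!r}")
        self.edges = list(edges)
        self._out: dict[str, list[Edge]] = {lv.name: [] for lv in levels}
        for e in edges:
            if e.finer not in self.levels or e.coarser not in self.levels:
                raise HierarchyError(
                    f"edge {e.finer}->{e.coarser} references unknown level"
                )
            self._out[e.finer].append(e)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(node: str) -> None:
            if seen.get(node) == 0:
                raise HierarchyError(f"hierarchy {self.name!r} has a cycle")
            if node in seen:
                return
            seen[node] = 0
            for e in self._out[node]:
                visit(e.coarser)
            seen[node] = 1

        for lv in self.levels:
            visit(lv)

    def rank(self, level: str) -> int:
        try:
            return self.levels[level].rank
        except KeyError:
            raise HierarchyError(
                f"unknown level {level!r} in hierarchy {self.name!r}"
            ) from None

    def path(self, source: str, target: str) -> list[Edge]:
        """Shortest edge path from ``source`` to the coarser ``target``."""
        self.rank(source), self.rank(target)
        if source == target:
            return []
        queue = deque([(source, [])])
        seen = {source}
        while queue:
            node, trail = queue.popleft()
            for e in self._out[node]:
                if e.coarser == target:
                    return trail + [e]
                if e.coarser not in seen:
                    seen.add(e.coarser)
                    queue.append((e.coarser, trail + [e]))
        raise HierarchyError(
            f"no generalization path {source!r} -> {target!r} "
            f"in hierarchy {self.name!r}"
        )

    def compose_map(self, source: str, target: str) -> dict | None:
        """Composed value map from ``source`` to ``target``; None if identity."""
        edges = self.path(source, target)
        if not edges:
            return None
        mapping = dict(edges[0].mapping)
        for e in edges[1:]:
            out = {}
            for v, img in mapping.items():
                if img not in e.mapping:
                    raise HierarchyError(
                        f"value {img!r} missing from map "
                        f"{e.finer}->{e.coarser} in hierarchy {self.name!r}"
                    )
                out[v] = e.mapping[img]
            mapping = out
        return mapping

    def reachable_coarser(self, level: str, totally_ordered_only: bool = False):
        """All levels reachable from ``level`` by generalization edges."""
        out, queue = [], deque([level])
        seen = {level}
        while queue:
            node = queue.popleft()
            for e in self._out[node]:
                if totally_ordered_only and not e.totally_ordered:
                    continue
                if e.coarser not in seen:
                    seen.add(e.coarser)
                    out.append(e.coarser)
                    queue.append(e.coarser)
        return out

    def finer_levels(self, level: str) -> list[str]:
        """All levels that can reach ``level`` (i.e. its specializations)."""
        return [
            lv
            for lv in self.levels
            if lv != level and level in self.reachable_coarser(lv)
        ]

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_dict(cls, spec: dict) -> "GeneralizationHierarchy":
        for key in ("name", "levels", "edges"):
            if key not in spec:
                raise HierarchyError(f"hierarchy definition missing {key!r}")
        levels = [Level(lv["name"], int(lv["rank"])) for lv in spec["levels"]]
        edges = [
            Edge(
                e["from"],
                e["to"],
                {str(k): str(v) for k, v in e["map"].items()},
                bool(e.get("totally_ordered", False)),
            )
            for e in spec["edges"]
        ]
        return cls(spec["name"], levels, edges)

    @classmethod
    def from_json(cls, path) -> "GeneralizationHierarchy":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "levels": [
                {"name": lv.name, "rank": lv.rank} for lv in self.levels.values()
            ],
            "edges": [
                {
                    "from": e.finer,
                    "to": e.coarser,
                    "totally_ordered": e.totally_ordered,
                    "map": dict(e.mapping),
                }
                for e in self.edges
            ],
        }


@dataclass
class Schema:
    """Column roles: quasi-identifiers vs. never-suppressed passenger columns."""

    quasi_identifiers: list[QuasiIdentifier]
    other_columns: list[str] = field(default_factory=list)
    hierarchies: dict[str, GeneralizationHierarchy] = field(default_factory=dict)

    def __post_init__(self):
        qi_names = [q.name for q in self.quasi_identifiers]
        if len(set(qi_names)) != len(qi_names):
            raise ValueError("duplicate quasi-identifier names")
        overlap = set(qi_names) & set(self.other_columns)
        if overlap:
            raise ValueError(f"columns in two roles: {sorted(overlap)}")
        for q in self.quasi_identifiers:
            if q.hierarchy_ref is not None:
                hname, lname = q.hierarchy_ref
                if hname not in self.hierarchies:
                    raise ValueError(
                        f"{q.name!r} references unknown hierarchy {hname!r}"
                    )
                self.hierarchies[hname].rank(lname)  # raises if unknown

    @property
    def qi_names(self) -> list[str]:
        return [q.name for q in self.quasi_identifiers]

    def qi(self, name: str) -> QuasiIdentifier:
        for q in self.quasi_identifiers:
            if q.name == name:
                return q
        raise KeyError(f"unknown quasi-identifier {name!r}")

    def weight(self, name: str) -> float:
        try:
            return self.qi(name).weight
        except KeyError:
            return 1.0

    @classmethod
    def from_dict(cls, spec: dict, hierarchies=None) -> "Schema":
        hierarchies = dict(hierarchies or {})
        for hspec in spec.get("hierarchies", []):
            h = GeneralizationHierarchy.from_dict(hspec)
            hierarchies[h.name] = h
        qis = []
        for q in spec["quasi_identifiers"]:
            domain = q.get("domain")
            if domain in (None, "infer"):
                dom = None
            else:
                dom = frozenset(str(v) for v in domain)
            href = q.get("hierarchy")
            if href is not None:
                href = (href["name"], href["level"])
            qis.append(
                QuasiIdentifier(
                    name=q["name"],
                    domain=dom,
                    weight=float(q.get("weight", 1.0)),
                    hierarchy_ref=href,
                )
            )
        return cls(qis, list(spec.get("other_columns", [])), hierarchies)

    @classmethod
    def from_yaml(cls, path, hierarchies=None) -> "Schema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh), hierarchies)


# ---------------------------------------------------------------------------
# Equivalence classes
# ---------------------------------------------------------------------------


@dataclass
class EquivalenceClassIndex:
    """Partition of records by value-tuple on a column combination.

    The suppression sentinel is deliberately a distinct grouping value: two
    records whose birth decade was suppressed share an equivalence class
    only if they also agree on every other column of the combination.
    """

    combination: list[str]
    classes: dict[tuple, frozenset]

    @property
    def sizes(self) -> dict[tuple, int]:
        return {key: len(ids) for key, ids in self.classes.items()}

    def class_of(self, value_tuple: tuple) -> frozenset:
        return self.classes.get(tuple(value_tuple), frozenset())

    def small_classes(self, k: int) -> dict[tuple, frozenset]:
        return {key: ids for key, ids in self.classes.items() if len(ids) < k}


def equivalence_classes(
    table: MicrodataTable, combination: list[str]
) -> EquivalenceClassIndex:
    """Group records by their exact value-tuple on ``combination``."""
    if not combination:
        raise ValueError("combination must name at least one column")
    missing = [c for c in combination if c not in table.columns]
    if missing:
        raise KeyError(f"unknown columns: {missing}")
    classes: dict[tuple, set] = {}
    sub = table.df[list(combination)]
    for rid, row in zip(sub.index, sub.itertuples(index=False, name=None)):
        classes.setdefault(row, set()).add(rid)
    return EquivalenceClassIndex(
        list(combination), {key: frozenset(ids) for key, ids in classes.items()}
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def support(table: MicrodataTable, column: str) -> dict:
    """Number of records holding each non-sentinel value of ``column``."""
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}")
    counts = table.df[column].value_counts()
    return {
        value: int(cnt) for value, cnt in counts.items() if value != SENTINEL
    }


def recode(
    table: MicrodataTable,
    column: str,
    hierarchy: GeneralizationHierarchy,
    source_level: str,
    target_level: str,
    new_column: str | None = None,
) -> MicrodataTable:
    """Replace every non-sentinel cell of ``column`` by its coarser image.

    The composed level map must cover every value present; sentinel cells
    stay sentinel.  With ``new_column`` the recoded values are stored in a
    new column and the original is kept (the released-file layout carries
    one column per hierarchy level).
    """
    mapping = hierarchy.compose_map(source_level, target_level)
    df = table.df.copy()
    if mapping is None:  # identity recode
        if new_column is not None:
            df[new_column] = df[column]
        return MicrodataTable(df)

    def apply_one(v):
        if v == SENTINEL:
            return SENTINEL
        if v not in mapping:
            raise DomainError(
                f"value {v!r} in column {column!r} missing from "
                f"{source_level}->{target_level} map"
            )
        return mapping[v]

    recoded = df[column].map(apply_one)
    df[new_column if new_column is not None else column] = recoded
    return MicrodataTable(df)


def read_microdata(
    path,
    schema: Schema | None = None,
    *,
    id_column: str | None = None,
    allow_sentinel: bool = False,
    allow_unknown: bool = False,
    sentinel_text: str = "",
) -> MicrodataTable:
    """Load a CSV (RFC-4180, header mandatory) into a :class:`MicrodataTable`.

    Quasi-identifier cells are validated against the schema domains; a value
    outside its domain raises :class:`DomainError` naming the record and
    column unless ``allow_unknown`` is set.  Cells equal to ``sentinel_text``
    become the suppression sentinel, permitted only with ``allow_sentinel``
    (round-tripping previously de-identified output).  Without an id column,
    sequential 1-based ids are assigned so audit logs stay stable.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.apply(lambda s: s.str.strip())
    if id_column is not None:
        if id_column not in df.columns:
            raise KeyError(f"id column {id_column!r} not in file")
        df = df.set_index(id_column)
        if df.index.has_duplicates:
            raise ValueError(f"duplicate record ids in {id_column!r}")
    else:
        df.index = pd.RangeIndex(1, len(df) + 1)

    if allow_sentinel:
        df = df.mask(df == sentinel_text, SENTINEL)
    elif (df == SENTINEL).any().any():
        raise DomainError(
            "input contains the reserved suppression sentinel; "
            "pass allow_sentinel=True to accept pre-suppressed data"
        )

    if schema is not None:
        missing = [c for c in schema.qi_names + schema.other_columns
                   if c not in df.columns]
        if missing:
            raise KeyError(f"missing columns: {missing}")
        if not allow_unknown:
            for q in schema.quasi_identifiers:
                if q.domain is None:
                    continue
                col = df[q.name]
                bad = ~(col.isin(q.domain) | (col == SENTINEL))
                if bad.any():
                    rid = df.index[bad][0]
                    raise DomainError(
                        f"value {col[bad].iloc[0]!r} at record {rid!r}, "
                        f"column {q.name!r} is outside the declared domain"
                    )
    return MicrodataTable(df)


def write_microdata(
    table: MicrodataTable,
    path,
    *,
    sentinel_text: str = "",
    id_column: str = "record_id",
) -> None:
    """Write CSV with sentinel cells rendered as ``sentinel_text``."""
    df = table.df.copy()
    df = df.mask(df == SENTINEL, sentinel_text)
    df.index.name = id_column
    df.to_csv(path)


def infer_domains(table: MicrodataTable, schema: Schema) -> Schema:
    """Fill in ``domain=None`` quasi-identifiers from observed values."""
    qis = []
    for q in schema.quasi_identifiers:
        if q.domain is None:
            observed = frozenset(
                v for v in table.df[q.name].unique() if v != SENTINEL
            )
            qis.append(replace(q, domain=observed))
        else:
            qis.append(q)
    return Schema(qis, schema.other_columns, schema.hierarchies)
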