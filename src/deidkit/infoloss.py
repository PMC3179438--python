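"""Information-loss metrics: suppression extent and non-uniform entropy.

Suppression extent is the intuitive metric analysts read first: the share
of records with at least one blanked quasi-identifier cell, and the share
of all quasi-identifier cells blanked, overall and per column.

Non-uniform entropy measures the information removed by recoding *and*
suppression in bits, weighting rare values more heavily than common ones.
Each cell contributes the conditional surprisal of its original value
given its released value, estimated from the original table's empirical
distribution:

* released unchanged          -> 0 bits;
* generalized to category g   -> -log2( n(v) / n(values mapping to g) );
* suppressed (sentinel)       -> -log2( n(v) / n ), the full column
  surprisal, since the sentinel reveals nothing about the value.

Summed over cells the metric is additive over records and columns,
never decreases under generalization (equality only for bijective maps),
and grows monotonically as the suppression set grows.  Because bits have
no intuitive scale, reports are usually expressed relative to a designated
baseline run (baseline = 100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import SENTINEL, MicrodataTable


@dataclass
class InfoLossReport:
    """Suppression-extent percentages and entropy for one de-identified file."""

    n_records: int
    qi_columns: list[str]
    pct_values_suppressed_by_qi: dict[str, float] = field(default_factory=dict)
    pct_records_with_suppression: float = 0.0
    pct_cells_suppressed: float = 0.0
    entropy_bits: float = 0.0
    entropy_pct_of_baseline: float | None = None

    def to_dict(self) -> dict:
        out = {
            "n_records": self.n_records,
            "per_qi_pct_suppressed": {
                col: round(v, 1)
                for col, v in self.pct_values_suppressed_by_qi.items()
            },
            "pct_records_with_suppression": round(
                self.pct_records_with_suppression, 1
            ),
            "total_pct_cells_suppressed": round(self.pct_cells_suppressed, 1),
            "entropy_bits": self.entropy_bits,
        }
        if self.entropy_pct_of_baseline is not None:
            out["entropy_pct_of_baseline"] = round(self.entropy_pct_of_baseline, 1)
        # raw (unrounded) values retained alongside the display rounding
        out["raw"] = {
            "per_qi_pct_suppressed": dict(self.pct_values_suppressed_by_qi),
            "pct_records_with_suppression": self.pct_records_with_suppression,
            "total_pct_cells_suppressed": self.pct_cells_suppressed,
        }
        return out


def suppression_extent(
    original: MicrodataTable, final: MicrodataTable, qis: list[str]
) -> InfoLossReport:
    """Percent of records / cells / per-column values suppressed."""
    if list(original.record_ids) != list(final.record_ids):
        raise ValueError("tables have different record ids")
    missing = [c for c in qis if c not in final.columns]
    if missing:
        raise ValueError(f"final table lacks columns {missing}")
    n = final.n
    mask = final.suppressed_mask(qis)
    per_qi = {
        col: (100.0 * mask[col].sum() / n if n else 0.0) for col in qis
    }
    rec_pct = 100.0 * mask.any(axis=1).sum() / n if n else 0.0
    cell_pct = 100.0 * mask.to_numpy().sum() / (n * len(qis)) if n else 0.0
    return InfoLossReport(
        n_records=n,
        qi_columns=list(qis),
        pct_values_suppressed_by_qi=per_qi,
        pct_records_with_suppression=float(rec_pct),
        pct_cells_suppressed=float(cell_pct),
    )


def nonuniform_entropy(
    original: MicrodataTable, final: MicrodataTable, qis: list[str]
) -> float:
    """Total conditional surprisal, in bits, of the released file.

    ``final`` must be derived from ``original`` by recoding and/or
    suppression on the listed columns (same record ids, many-to-one value
    maps); a released value that no original value maps to raises.
    """
    if list(original.record_ids) != list(final.record_ids):
        raise ValueError("tables have different record ids")
    total = 0.0
    n = original.n
    if n == 0:
        return 0.0
    for col in qis:
        orig = original.df[col]
        rel = final.df[col]
        value_counts = orig.value_counts()
        # Reconstruct the (many-to-one) value map from the released cells.
        # Global recoding releases every occurrence of a value the same
        # way, so two different non-sentinel images for one original value
        # mean the final table is not a recoding of the original.
        value_map: dict = {}
        for rid, (o, r) in zip(orig.index, zip(orig, rel)):
            if r == SENTINEL:
                continue
            if o in value_map and value_map[o] != r:
                raise ValueError(
                    f"column {col!r}: value {o!r} released inconsistently "
                    f"({value_map[o]!r} vs {r!r} at record {rid!r})"
                )
            value_map[o] = r
        # Size of each released category's preimage under the original
        # empirical distribution: the denominator of P(original | released).
        preimage: dict = {}
        for o, r in value_map.items():
            preimage[r] = preimage.get(r, 0) + int(value_counts[o])
        for o, r in zip(orig, rel):
            if r == SENTINEL:
                p = value_counts[o] / n
            else:
                p = value_counts[o] / preimage[r]
            total += -math.log2(p)
    return total


def entropy_relative(
    reports: list[InfoLossReport], baseline_index: int = 0
) -> list[InfoLossReport]:
    """Express each report's entropy as a percentage of the baseline's.

    The baseline itself reads 100%.  Mutates and returns the reports.
    """
    base = reports[baseline_index].entropy_bits
    if base <= 0:
        raise ValueError("baseline entropy must be positive")
    for rep in reports:
        rep.entropy_pct_of_baseline = 100.0 * rep.entropy_bits / base
    return reports


def full_report(
    original: MicrodataTable,
    final: MicrodataTable,
    qis: list[str],
) -> InfoLossReport:
    """Suppression extent plus entropy in a single report."""
    rep = suppression_extent(original, final, qis)
    rep.entropy_bits = nonuniform_entropy(original, final, qis)
    return rep
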