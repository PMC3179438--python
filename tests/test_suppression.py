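"""Two-phase local cell suppression: worked example, oracles, invariants."""

import itertools

import pandas as pd
import pytest

from deidkit import (
    SENTINEL,
    AdversaryKnowledge,
    KnowledgeSpec,
    MicrodataTable,
    QuasiIdentifier,
    Schema,
    SuppressionConfig,
    equivalence_classes,
    k_from_threshold,
    phase1_suppress,
    phase2_suppress,
    run_combinations_algorithm,
    run_complete_algorithm,
    suppress_value_in_moles,
    support,
)
from deidkit.combinations import Combination, CombinationSet
from deidkit.synthdata import GeneratorSpec, generate_dad_like

from conftest import random_table


class TestKFromThreshold:
    @pytest.mark.parametrize(
        "tau,expected",
        [(0.04, 25), (0.05, 20), (0.2, 5), (1.0, 1), (0.3, 4), (0.5, 2)],
    )
    def test_minimum_class_size(self, tau, expected):
        assert k_from_threshold(tau) == expected

    @pytest.mark.parametrize("tau", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, tau):
        with pytest.raises(ValueError):
            k_from_threshold(tau)


class TestPhase1:
    def test_rare_birth_decades_suppressed_at_k3(
        self, walkthrough, walkthrough_combo
    ):
        out, audit = phase1_suppress(walkthrough, walkthrough_combo, 3)
        year_cells = {
            e.record_id for e in audit.entries if e.column == "YearOfBirth"
        }
        assert year_cells == {5, 8, 26}

    def test_four_singleton_diagnoses_suppressed(
        self, walkthrough, walkthrough_combo
    ):
        out, audit = phase1_suppress(walkthrough, walkthrough_combo, 3)
        diags = {e.value for e in audit.entries if e.column == "Diagnosis"}
        assert diags == {"COPD", "sepsis", "neurological problem", "pneumonia"}
        assert sum(e.column == "Diagnosis" for e in audit.entries) == 4

    def test_k_one_never_suppresses(self, walkthrough, walkthrough_combo):
        out, audit = phase1_suppress(walkthrough, walkthrough_combo, 1)
        assert audit.entries == [] and out.equals(walkthrough)

    @pytest.mark.parametrize("seed,k", [(0, 3), (1, 5), (2, 8), (3, 2)])
    def test_matches_brute_force_oracle(self, seed, k):
        """Oracle: independently blank every value whose count is < k."""
        t = random_table(seed, n=80, n_values=12)
        combo = CombinationSet([Combination("c", ("q0", "q1", "q2"))])
        out, _ = phase1_suppress(t, combo, k)
        expect = t.df.copy()
        for col in expect.columns:
            counts = expect[col].value_counts()
            rare = counts[counts < k].index
            expect.loc[expect[col].isin(rare), col] = SENTINEL
        assert out.df.equals(expect)

    @pytest.mark.parametrize("seed", range(4))
    def test_suppression_monotone_in_k(self, seed):
        t = random_table(seed, n=70, n_values=10)
        combo = CombinationSet([Combination("c", ("q0", "q1", "q2"))])
        prev: set = set()
        for k in (2, 3, 5, 9):
            _, audit = phase1_suppress(t, combo, k)
            cells = audit.cells()
            assert prev <= cells
            prev = cells


class TestSuppressValueInMoles:
    @pytest.fixture
    def after_phase1(self, walkthrough, walkthrough_combo):
        out, _ = phase1_suppress(walkthrough, walkthrough_combo, 3)
        return out

    def test_value_with_only_small_classes_suppressed_everywhere(
        self, after_phase1, walkthrough_combo
    ):
        combo = walkthrough_combo.combinations[0]
        out, entries = suppress_value_in_moles(
            after_phase1, combo, ("YearOfBirth", "1970-1979"), 3
        )
        assert {e.record_id for e in entries} == {6, 20, 23, 25}

    def test_value_with_no_small_classes_untouched(
        self, after_phase1, walkthrough_combo
    ):
        combo = walkthrough_combo.combinations[0]
        out, entries = suppress_value_in_moles(
            after_phase1, combo, ("Diagnosis", "cardiac condition"), 3
        )
        assert entries == [] and out.equals(after_phase1)

    def test_large_class_keeps_value_small_class_loses_it(
        self, after_phase1, walkthrough_combo
    ):
        combo = walkthrough_combo.combinations[0]
        out, entries = suppress_value_in_moles(
            after_phase1, combo, ("Diagnosis", "acute respiratory problem"), 3
        )
        assert {e.record_id for e in entries} == {8}
        for rid in (16, 19, 24):
            assert out.cell(rid, "Diagnosis") == "acute respiratory problem"


@pytest.fixture(scope="module")
def replay(walkthrough, walkthrough_combo):
    t, _ = phase1_suppress(walkthrough, walkthrough_combo, 3)
    return phase2_suppress(t, walkthrough_combo, 3, mode="walkthrough")


class TestPhase2Walkthrough:
    def test_exactly_five_suppression_passes(self, replay):
        _, audit = replay
        passes = {e.pass_number for e in audit.entries}
        assert len(passes) == 5

    def test_pass_sequence_cell_for_cell(self, replay):
        _, audit = replay
        by_pass = [
            (g[0].column, g[0].value, sorted(e.record_id for e in g))
            for _, grp in itertools.groupby(
                audit.entries, key=lambda e: e.pass_number
            )
            if (g := list(grp))
        ]
        assert by_pass == [
            ("YearOfBirth", "1970-1979", [6, 20, 23, 25]),
            ("Diagnosis", "acute respiratory problem", [8]),
            ("Diagnosis", "external injury", [1, 4, 10, 14]),
            ("Diagnosis", "metabolic disorder", [9, 23, 25]),
            ("YearOfBirth", "1960-1969", [10, 14]),
        ]

    def test_metabolic_pass_suppresses_singleton_classes_of_23_and_25(
        self, replay
    ):
        _, audit = replay
        met = [e for e in audit.entries if e.value == "metabolic disorder"]
        assert {23, 25} <= {e.record_id for e in met}
        assert all(
            e.ec_size == 1 for e in met if e.record_id in (23, 25)
        )

    def test_size_two_class_of_10_and_14_loses_birth_decade(self, replay):
        _, audit = replay
        sixties = [e for e in audit.entries if e.value == "1960-1969"]
        assert {e.record_id for e in sixties} == {10, 14}
        assert all(e.ec_size == 2 for e in sixties)

    def test_fifties_decade_never_suppressed(self, replay):
        out, audit = replay
        assert all(e.value != "1950-1959" for e in audit.entries)

    def test_result_is_three_anonymous(self, replay):
        out, _ = replay
        idx = equivalence_classes(out, ["Sex", "YearOfBirth", "Diagnosis"])
        assert min(idx.sizes.values()) >= 3

    def test_strict_mode_agrees_on_this_fixture(
        self, walkthrough, walkthrough_combo, replay
    ):
        t, _ = phase1_suppress(walkthrough, walkthrough_combo, 3)
        strict_out, _ = phase2_suppress(t, walkthrough_combo, 3, mode="strict")
        assert strict_out.equals(replay[0])


class TestPhase2Contracts:
    def test_refuses_to_run_without_phase1(self, walkthrough, walkthrough_combo):
        with pytest.raises(ValueError, match="phase 1"):
            phase2_suppress(walkthrough, walkthrough_combo, 3)

    def test_already_anonymous_table_untouched(self, table6):
        combos = CombinationSet(
            [
                Combination("1", ("PROV_ALL", "AGE_GROUP", "GENDER_CODE", "MRDx")),
                Combination("2", ("PROV_ALL", "AGE_GROUP", "GENDER_CODE", "CMG_CODE")),
            ]
        )
        out, audit = phase2_suppress(table6, combos, 2)
        assert audit.entries == [] and out.equals(table6)

    @pytest.mark.parametrize("seed,k", [(0, 3), (1, 4), (2, 5)])
    def test_strict_postcondition(self, seed, k):
        """Every surviving value has support >= k and every small class is
        fully blanked (exhaustive scan)."""
        t = random_table(seed, n=90, n_values=8)
        combo = CombinationSet([Combination("c", ("q0", "q1", "q2"))])
        t1, _ = phase1_suppress(t, combo, k)
        out, _ = phase2_suppress(t1, combo, k, mode="strict")
        idx = equivalence_classes(out, ["q0", "q1", "q2"])
        for key, ids in idx.classes.items():
            if len(ids) < k:
                assert all(v == SENTINEL for v in key), (key, ids)

    @pytest.mark.parametrize("seed", range(3))
    def test_audit_replay_reproduces_output(self, seed):
        t = random_table(seed, n=90, n_values=8)
        combo = CombinationSet([Combination("c", ("q0", "q1", "q2"))])
        t1, a1 = phase1_suppress(t, combo, 4)
        out, a2 = phase2_suppress(t1, combo, 4, mode="strict")
        a1.extend(a2)
        assert a1.apply(t).equals(out)

    def test_higher_weight_spares_the_weighted_column(self, walkthrough,
                                                      walkthrough_combo):
        t, _ = phase1_suppress(walkthrough, walkthrough_combo, 3)

        def diagnosis_cells(weights):
            _, audit = phase2_suppress(
                t, walkthrough_combo, 3, weights=weights, mode="walkthrough"
            )
            return sum(e.column == "Diagnosis" for e in audit.entries)

        low = diagnosis_cells({"Diagnosis": 0.2})
        high = diagnosis_cells({"Diagnosis": 1.0})
        assert high <= low


class TestFullPipelines:
    @pytest.fixture
    def table6_schema(self, dad_schema, dad_hierarchies):
        diag = dad_hierarchies[0]
        return Schema(
            [
                QuasiIdentifier("PROV_ALL"),
                QuasiIdentifier("AGE_GROUP"),
                QuasiIdentifier("GENDER_CODE"),
                QuasiIdentifier("MRDx", hierarchy_ref=("diagnosis", "MRDx")),
            ],
            [],
            {"diagnosis": diag},
        )

    def test_combinations_beat_complete_on_overlapping_levels(self, table6):
        """The overlapping-combination example: zero cells suppressed when the
        two 4-QI combinations are handled separately, forced suppression when
        all five columns form one combination."""
        combos = CombinationSet(
            [
                Combination("1", ("PROV_ALL", "AGE_GROUP", "GENDER_CODE", "MRDx")),
                Combination("2", ("PROV_ALL", "AGE_GROUP", "GENDER_CODE", "CMG_CODE")),
            ]
        )
        t1, a1 = phase1_suppress(table6, combos, 2)
        out, a2 = phase2_suppress(t1, combos, 2, mode="strict")
        assert len(a1.entries) + len(a2.entries) == 0

        allc = CombinationSet(
            [Combination("all", tuple(table6.columns))]
        )
        t1, b1 = phase1_suppress(table6, allc, 2)
        out, b2 = phase2_suppress(t1, allc, 2, mode="strict")
        suppressed_cols = {e.column for e in b1.entries + b2.entries}
        # one whole diagnosis-bearing column must be sacrificed
        assert suppressed_cols == {"MRDx"} or suppressed_cols == {"CMG_CODE"}
        col = suppressed_cols.pop()
        assert all(out.cell(r, col) == SENTINEL for r in out.record_ids)

    def test_empty_table_runs_vacuously(self, table6_schema):
        empty = MicrodataTable(
            pd.DataFrame(
                columns=["PROV_ALL", "AGE_GROUP", "GENDER_CODE", "MRDx"]
            )
        )
        knowledge = AdversaryKnowledge(
            {"MRDx": KnowledgeSpec("diagnosis", "MRDx")},
            skip_totally_ordered=False,
        )
        out, audit = run_combinations_algorithm(
            empty, table6_schema, knowledge, SuppressionConfig(k=2)
        )
        assert out.n == 0 and audit.entries == []

    def test_single_qi_schema_combinations_equals_complete(self):
        t = random_table(5, n=40, n_cols=1, n_values=9)
        schema = Schema([QuasiIdentifier("q0")])
        cfg = SuppressionConfig(k=3)
        knowledge = AdversaryKnowledge()
        a, _ = run_complete_algorithm(t, schema, knowledge, cfg)
        combos = CombinationSet([Combination("c", ("q0",))])
        b1, audit1 = phase1_suppress(t, combos, 3)
        b, audit2 = phase2_suppress(b1, combos, 3, mode="strict")
        assert a.equals(b)

    def test_complete_strict_oracle_on_synthetic_table(self):
        """After the complete run at k=5, any class still smaller than k
        consists only of fully-suppressed quasi-identifier tuples."""
        table, schema, _ = generate_dad_like(GeneratorSpec(n=300, seed=9))
        knowledge = AdversaryKnowledge(
            {
                "MRDx": KnowledgeSpec("diagnosis", "CMG_CODE"),
                "CCI_CODE": KnowledgeSpec("intervention", "SHORT_CCI"),
            }
        )
        out, _ = run_complete_algorithm(
            table, schema, knowledge, SuppressionConfig(k=5)
        )
        qi_cols = [
            c
            for c in out.columns
            if c in ("PROV_ALL", "AGE_GROUP", "GENDER_CODE", "CMG_CODE", "SHORT_CCI")
        ]
        idx = equivalence_classes(out, qi_cols)
        for key, ids in idx.classes.items():
            if len(ids) < 5:
                assert all(v == SENTINEL for v in key)

    def test_pipeline_propagates_to_released_levels(self):
        table, schema, _ = generate_dad_like(GeneratorSpec(n=250, seed=4))
        knowledge = AdversaryKnowledge(
            {
                "MRDx": KnowledgeSpec("diagnosis", "CMG_CODE", release_level="MRDx"),
                "CCI_CODE": KnowledgeSpec(
                    "intervention", "SHORT_CCI", release_level="CCI_CODE"
                ),
            }
        )
        out, audit = run_combinations_algorithm(
            table, schema, knowledge, SuppressionConfig(k=5)
        )
        diag = schema.hierarchies["diagnosis"]
        cmg_map = diag.compose_map("MRDx", "CMG_CODE")
        for rid in out.record_ids:
            code = out.cell(rid, "MRDx")
            if code != SENTINEL:
                # a released code never generalizes to a suppressed group
                assert out.cell(rid, "CMG_CODE") == cmg_map[code]

    def test_config_requires_exactly_one_of_k_and_tau(self):
        with pytest.raises(ValueError):
            SuppressionConfig().resolve_k()
        with pytest.raises(ValueError):
            SuppressionConfig(k=5, tau=0.2).resolve_k()
        assert SuppressionConfig(tau=0.05).resolve_k() == 20
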