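"""Input assembly, check/grouping/characterization, dependency resolution."""

import math
import random

import numpy as np
import pytest

from dqmm.data_model import MISSING, load_dataset
from dqmm.executor import (
    ALL_GROUP,
    CycleError,
    EmptyFilterError,
    MMResult,
    UnsupportedCombinationError,
    apply_characterization,
    apply_check,
    apply_grouping,
    assemble_input,
    execute_all,
    execute_mm,
    resolve_execution_order,
)
from dqmm.mm_model import (
    CHARACTERIZATION_REGISTRY,
    Characterization,
    DatasetBinding,
    DomainPath,
    MeasurementMethod,
    MMFilterBinding,
)
from tests.conftest import FACILITY_PATH


def _mm(items, check=None, grouping=None, builtin="mean", tags=("t",),
        params=None):
    return MeasurementMethod(
        tags=tuple(tags),
        domain_paths=tuple(
            DomainPath(f"item{i}", typ, src) for i, (typ, src) in enumerate(items)
        ),
        check=check,
        grouping=grouping,
        characterization=Characterization(builtin=builtin,
                                          params=params or {}),
    )


def _rows(pairs):
    """Dataset with leaves a/b per row."""
    lines = []
    for a, b in pairs:
        import json

        lines.append(json.dumps({"children": [
            {"name": "a", "value": a}, {"name": "b", "value": b},
        ]}))
    return load_dataset("\n".join(lines) + "\n", format="nested-records")


class TestAssembly:
    def test_two_items_five_rows_aligned(self):
        ds = _rows([(i, f"s{i}") for i in range(5)])
        mm = _mm([("numeric", DatasetBinding("dataset-row/a")),
                  ("text", DatasetBinding("dataset-row/b"))])
        table = assemble_input(mm, ds)
        assert table.n_rows == 5
        assert table.columns["item0"] == [0, 1, 2, 3, 4]
        assert table.provenance == [0, 1, 2, 3, 4]

    def test_filter_binding_enumerates_mm_group_pairs(self):
        # 3 check MMs, one grouped into two groups -> 4 input rows
        prior = {
            "m1": MMResult("m1", ("check",), [(ALL_GROUP, 1.0)]),
            "m2": MMResult("m2", ("check",), [(ALL_GROUP, 0.8)]),
            "m3": MMResult("m3", ("check", "per_site"),
                           [("SiteA", 0.5), ("SiteB", 0.9)]),
            "m4": MMResult("m4", ("check", "grouped"),
                           [("X", 0.1), ("Y", 0.2)]),
        }
        mm = _mm([("numeric", MMFilterBinding(
            "has_tag('check') and lacks_tag('per_*')", "resultsValue"))])
        table = assemble_input(mm, None, prior)
        assert table.n_rows == 4
        assert sorted(v for v in table.columns["item0"]) == [0.1, 0.2, 0.8, 1.0]
        assert ("m3", "SiteA") not in table.provenance

    def test_empty_filter_is_error(self):
        mm = _mm([("numeric", MMFilterBinding("has_tag('nope')", "resultsValue"))])
        with pytest.raises(EmptyFilterError):
            assemble_input(mm, None, {})

    def test_mixed_binding_kinds_rejected(self):
        mm = _mm([
            ("numeric", DatasetBinding("dataset-row/a")),
            ("numeric", MMFilterBinding("has_tag('x')", "resultsValue")),
        ])
        with pytest.raises(UnsupportedCombinationError):
            assemble_input(mm, _rows([(1, "s")]), {})

    def test_multi_match_paths_flatten_with_provenance(self):
        text = ('{"children": [{"name": "panel", "children": [{"name": "v", '
                '"value": 1}]}, {"name": "panel", "children": [{"name": "v", '
                '"value": 2}]}]}\n'
                '{"children": [{"name": "panel", "children": [{"name": "v", '
                '"value": 3}]}]}\n')
        ds = load_dataset(text, format="nested-records")
        mm = _mm([("numeric", DatasetBinding("dataset-row/panel/v"))])
        table = assemble_input(mm, ds)
        assert table.columns["item0"] == [1, 2, 3]
        assert table.provenance == [0, 0, 1]


class TestCheckAndGrouping:
    def test_cardinality_rule_on_counts(self):
        counts = [1, 0, 2]
        import json

        lines = []
        for c in counts:
            children = [{"name": "x", "value": i} for i in range(c)]
            lines.append(json.dumps(
                {"children": [{"name": "facility", "children": children}]}
                if c else {"children": []}
            ))
        ds = load_dataset("\n".join(lines) + "\n", format="nested-records")
        mm = _mm(
            [("numeric", DatasetBinding(
                "dataset-row/facility.countChildnodes(only_child)",
                "only_child"))],
            check="item0 >= 1 and item0 <= 1",
        )
        table = apply_check(mm, assemble_input(mm, ds))
        assert table.check_results == [True, False, False]

    def test_value_set_check_propagates_missing(self):
        ds = _rows([("Weiblich", "s"), ("ND", "s")])
        mm = _mm([("text", DatasetBinding("dataset-row/a"))],
                 check="in_list(item0, ['Weiblich','Männlich','Divers'])")
        table = apply_check(mm, assemble_input(mm, ds))
        assert table.check_results == [True, MISSING]

    def test_grouping_by_item_and_combined_key(self):
        ds = _rows([(1, "A"), (2, "B"), (3, "A")])
        mm = _mm([("numeric", DatasetBinding("dataset-row/a")),
                  ("text", DatasetBinding("dataset-row/b"))],
                 grouping="item1")
        table = assemble_input(mm, ds)
        assert apply_grouping(mm, table) == ["A", "B", "A"]
        combined = _mm([("text", DatasetBinding("dataset-row/a")),
                        ("text", DatasetBinding("dataset-row/b"))],
                       grouping="format('%s_%s', item0, item1)")
        ds2 = _rows([("E. coli", "ampicillin")])
        labels = apply_grouping(combined, assemble_input(combined, ds2))
        assert labels == ["E. coli_ampicillin"]

    def test_no_grouping_is_single_all_group(self):
        ds = _rows([(1, "x"), (2, "y"), (3, "z")])
        mm = _mm([("numeric", DatasetBinding("dataset-row/a"))])
        assert apply_grouping(mm, assemble_input(mm, ds)) == ["ALL"] * 3

    def test_missing_grouping_value_pooled_under_missing_label(self):
        ds = _rows([(1, "A"), (2, "NA")])
        mm = _mm([("numeric", DatasetBinding("dataset-row/a")),
                  ("text", DatasetBinding("dataset-row/b"))],
                 grouping="item1")
        assert apply_grouping(mm, assemble_input(mm, ds)) == ["A", "MISSING"]


class TestCharacterizations:
    def test_count_present_skips_missing(self):
        assert CHARACTERIZATION_REGISTRY["count_present"]([1, MISSING, 3]) == 2

    def test_mean_density(self):
        got = CHARACTERIZATION_REGISTRY["mean_density"]([1, 3, 6])
        assert got == pytest.approx((2 + 3) / 2)

    def test_mean_of_boolean_check_vector(self):
        got = CHARACTERIZATION_REGISTRY["mean"]([True, False, True, True])
        assert got == pytest.approx(0.75)

    def test_relative_frequency_table(self):
        got = CHARACTERIZATION_REGISTRY["relative_frequency_table"](
            ["a", "a", "b"])
        assert got == {"a": pytest.approx(2 / 3), "b": pytest.approx(1 / 3)}

    def test_statistics_match_naive_oracles_on_random_vectors(self):
        rng = random.Random(42)
        for _ in range(200):
            n = rng.randint(1, 40)
            values = [rng.uniform(-100, 100) for _ in range(n)]
            reg = CHARACTERIZATION_REGISTRY
            assert reg["min"](values) == pytest.approx(min(values), abs=1e-9)
            assert reg["max"](values) == pytest.approx(max(values), abs=1e-9)
            assert reg["mean"](values) == pytest.approx(
                sum(values) / n, abs=1e-9)
            srt = sorted(values)
            naive_median = (
                srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
            )
            assert reg["median"](values) == pytest.approx(naive_median, abs=1e-9)
            if n >= 2:
                m = sum(values) / n
                naive_sd = math.sqrt(
                    sum((v - m) ** 2 for v in values) / (n - 1))
                assert reg["sd"](values) == pytest.approx(naive_sd, abs=1e-9)
            freq = reg["frequency_table"]([round(v) for v in values])
            for key, count in freq.items():
                assert count == sum(
                    1 for v in values if str(round(v)) == key)
            rel = reg["relative_frequency_table"]([round(v) for v in values])
            assert sum(rel.values()) == pytest.approx(1.0, abs=1e-9)

    def test_histogram_is_plot_data(self):
        got = CHARACTERIZATION_REGISTRY["histogram"]([1, 2, 3], bins=2)
        assert sum(got["counts"]) == 3
        assert len(got["bin_edges"]) == 3


class TestExecutionOrderAndBatch:
    def _checks_and_summary(self):
        ds = _rows([(5, "A"), (50, "B"), (500, "A")])
        c1 = _mm([("numeric", DatasetBinding("dataset-row/a"))],
                 check="item0 >= 0 and item0 <= 100", tags=("check", "c1"))
        c2 = _mm([("numeric", DatasetBinding("dataset-row/a"))],
                 check="item0 >= 0 and item0 <= 1000", tags=("check", "c2"))
        summary = _mm(
            [("numeric", MMFilterBinding("has_tag('check')", "resultsValue"))],
            builtin="mean", tags=("summary",),
        )
        return ds, c1, c2, summary

    def test_checks_execute_before_summary(self):
        ds, c1, c2, summary = self._checks_and_summary()
        order = resolve_execution_order([summary, c1, c2])
        ids = [mm.id for mm in order]
        assert ids.index(summary.id) > max(ids.index(c1.id), ids.index(c2.id))

    def test_input_order_preserved_without_filters(self):
        ds, c1, c2, _ = self._checks_and_summary()
        assert [m.id for m in resolve_execution_order([c2, c1])] == [c2.id, c1.id]

    def test_cycle_detected(self):
        a = _mm([("numeric", MMFilterBinding("has_tag('b')", "resultsValue"))],
                tags=("a",))
        b = _mm([("numeric", MMFilterBinding("has_tag('a')", "resultsValue"))],
                tags=("b",))
        with pytest.raises(CycleError):
            resolve_execution_order([a, b])

    def test_any_topological_order_yields_identical_results(self):
        ds, c1, c2, summary = self._checks_and_summary()
        res_a = execute_all([summary, c1, c2], ds)
        res_b = execute_all([c2, summary, c1], ds)
        for mid in res_a:
            assert res_a[mid].groups == res_b[mid].groups

    def test_multi_layer_summary_value(self):
        ds, c1, c2, summary = self._checks_and_summary()
        results = execute_all([summary, c1, c2], ds)
        # c1 passes 2/3, c2 passes 3/3; summary mean = (2/3 + 1) / 2
        assert results[summary.id].value() == pytest.approx((2 / 3 + 1.0) / 2)

    def test_fail_soft_execution(self):
        ds, c1, _, _ = self._checks_and_summary()
        broken = _mm([("numeric", DatasetBinding("dataset-row/a"))],
                     check="item0 < 'not a number'", tags=("broken",))
        results = execute_all([broken, c1], ds)
        assert results[broken.id].failed
        assert not results[c1.id].failed

    def test_grouped_mean_compliance_per_site(self):
        ds, *_ = self._checks_and_summary()
        mm = _mm([("numeric", DatasetBinding("dataset-row/a")),
                  ("text", DatasetBinding("dataset-row/b"))],
                 check="item0 >= 0 and item0 <= 100", grouping="item1",
                 tags=("check", "per_site"))
        result = execute_mm(mm, ds)
        assert result.group_labels() == ["A", "B"]  # lexicographic
        assert result.value("A") == pytest.approx(0.5)
        assert result.value("B") == pytest.approx(1.0)

    def test_check_mean_equals_one_minus_violation_fraction(self, study):
        ds, schema = study
        from dqmm.generator import generate_constraint_mms
        from dqmm.data_model import resolve_path

        mms = generate_constraint_mms(schema)
        results = execute_all(mms, ds)
        for mm in mms:
            r = results[mm.id]
            assert not r.failed
            counts = r.checked_counts
            judged = counts["true"] + counts["false"]
            if judged:
                assert r.value() == pytest.approx(counts["true"] / judged)
            assert 0.0 <= r.value() <= 1.0

    def test_group_count_decomposition(self):
        ds = _rows([(1, "A"), (2, "B"), (3, "A"), (None, "B")])
        plain = _mm([("numeric", DatasetBinding("dataset-row/a"))],
                    builtin="count_present")
        grouped = _mm([("numeric", DatasetBinding("dataset-row/a")),
                       ("text", DatasetBinding("dataset-row/b"))],
                      builtin="count_present", grouping="item1")
        total = execute_mm(plain, ds).value()
        by_group = execute_mm(grouped, ds)
        assert sum(v for _, v in by_group.groups) == total == 3

    def test_determinism_across_runs(self, study):
        ds, schema = study
        from dqmm.generator import generate_constraint_mms

        mms = generate_constraint_mms(schema)
        r1 = execute_all(mms, ds)
        r2 = execute_all(mms, ds)
        for mid in r1:
            assert r1[mid].groups == r2[mid].groups
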