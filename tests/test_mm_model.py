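"""The MM 5-tuple, domain-path grammar, expression dialect, tag filters."""

import pytest
from hypothesis import given, settings, strategies as st

from dqmm.data_model import MISSING
from dqmm.mm_model import (
    Characterization,
    DatasetBinding,
    DomainPath,
    DomainPathSyntaxError,
    ExpressionError,
    FilterSyntaxError,
    MeasurementMethod,
    MMFilterBinding,
    evaluate_expression,
    evaluate_filter,
    mm_from_document,
    mm_to_document,
    parse_domain_path,
    parse_filter,
    render_domain_path,
    validate_mm,
)


class TestDomainPathGrammar:
    def test_dataset_binding(self):
        dp = parse_domain_path(
            "# item1 (string) = "
            "dataset-row/composition/context/health_care_facility/name"
        )
        assert dp.item_name == "item1"
        assert dp.declared_type == "text"
        assert isinstance(dp.source, DatasetBinding)
        assert dp.source.path.endswith("health_care_facility/name")

    def test_filter_binding_with_results_value_selector(self):
        dp = parse_domain_path(
            "# item0 (numeric) = other_data_input: "
            "has_tag('check') and lacks_tag('per_*') .resultsValue"
        )
        assert isinstance(dp.source, MMFilterBinding)
        assert dp.source.selector == "resultsValue"
        assert "has_tag('check')" in dp.source.filter

    def test_count_childnodes_instruction_preserved(self):
        dp = parse_domain_path(
            "# item0 (numeric) = dataset-row/facility"
            ".countChildnodes(only_child)"
        )
        assert dp.source.instruction == "only_child"

    @pytest.mark.parametrize(
        "bad",
        [
            "# item0 = dataset-row/x",  # missing type
            "# item0 (bogus) = dataset-row/x",  # unknown type keyword
            "item0 (numeric) = dataset-row/x",  # missing leading '#'
            "# item0 (numeric) = other_data_input: has_tag('a')",  # no selector
            "# item0 (numeric) = no-prefix/x",  # bad path
        ],
    )
    def test_grammar_violations(self, bad):
        with pytest.raises((DomainPathSyntaxError, Exception)):
            parse_domain_path(bad)

    def test_render_parse_round_trip(self):
        lines = [
            "# item0 (numeric) = dataset-row/a/b.countChildnodes(only_child)",
            "# item1 (string) = dataset-row/c/items[at0098,'biopsy result final']/value",
            "# item0 (numeric) = other_data_input: has_tag('check') .resultsValue",
        ]
        for line in lines:
            dp = parse_domain_path(line)
            assert parse_domain_path(render_domain_path(dp)) == dp


class TestExpressionDialect:
    def test_range_rule(self):
        expr = "item0 >= 0.0 and item0 <= 1000.0"
        assert evaluate_expression(expr, {"item0": 500.0}) is True
        assert evaluate_expression(expr, {"item0": 1500.0}) is False

    def test_value_set_rule(self):
        expr = "in_list(item0, ['Weiblich','Männlich','Divers'])"
        assert evaluate_expression(expr, {"item0": "Weiblich"}) is True
        assert evaluate_expression(expr, {"item0": "w"}) is False

    def test_unit_conditional_range_rule(self):
        expr = (
            "(item0 >= 0.0 and item0 <= 1000.0) if item1 == 'kg' "
            "else ((item0 >= 0.0 and item0 <= 1000000.0) if item1 == 'g' "
            "else MISSING)"
        )
        assert evaluate_expression(expr, {"item0": 1500000.0, "item1": "g"}) is False
        assert evaluate_expression(expr, {"item0": 500.0, "item1": "kg"}) is True
        assert evaluate_expression(expr, {"item0": 1.0, "item1": "lb"}) is MISSING

    def test_missing_operand_propagates(self):
        for expr in ("item0 >= 1", "item0 + 1", "not item0",
                     "in_list(item0, ['a'])", "year(item0)"):
            assert evaluate_expression(expr, {"item0": MISSING}) is MISSING

    def test_unbound_variable_is_error(self):
        with pytest.raises(ExpressionError, match="unbound"):
            evaluate_expression("item3 > 0", {"item0": 1})

    def test_type_mismatch_is_error(self):
        with pytest.raises(ExpressionError):
            evaluate_expression("item0 < 3", {"item0": "a"})

    def test_date_extraction(self):
        b = {"item0": "2021-05-17"}
        assert evaluate_expression("year(item0)", b) == 2021
        assert evaluate_expression("month(item0)", b) == 5
        assert evaluate_expression("quarter(item0)", b) == 2
        assert evaluate_expression("day(item0)", b) == 17
        assert evaluate_expression("weekday(item0)", b) == 1  # a Monday

    def test_string_concat_and_format(self):
        b = {"item1": "E. coli", "item2": "ampicillin"}
        assert (
            evaluate_expression("format('%s_%s', item1, item2)", b)
            == "E. coli_ampicillin"
        )
        assert evaluate_expression("item1 + '_' + item2", b) == "E. coli_ampicillin"

    def test_regex_match(self):
        assert evaluate_expression(
            "matches(item0, '^P\\\\d{4}$')", {"item0": "P0042"}
        ) is True

    def test_sandbox_rejects_host_constructs(self):
        for bad in ("__import__('os')", "item0.attr", "[x for x in item0]",
                    "lambda: 1", "item0[0]"):
            with pytest.raises(ExpressionError):
                evaluate_expression(bad, {"item0": [1]})

    # randomized agreement with a direct reference interpreter
    @given(
        st.integers(min_value=-50, max_value=50),
        st.integers(min_value=-50, max_value=50),
        st.integers(min_value=-50, max_value=50),
        st.sampled_from(["+", "-", "*"]),
        st.sampled_from([">=", "<", "=="]),
    )
    @settings(max_examples=200, deadline=None)
    def test_arithmetic_comparison_agree_with_python(self, a, b, c, op, cmp):
        expr = f"(item0 {op} item1) {cmp} item2"
        got = evaluate_expression(expr, {"item0": a, "item1": b, "item2": c})
        lhs = {"+": a + b, "-": a - b, "*": a * b}[op]
        want = {
            ">=": lhs >= c, "<": lhs < c, "==": lhs == c,
        }[cmp]
        assert got == want


class TestTagFilters:
    def test_has_tag_exact_membership(self):
        assert evaluate_filter("has_tag('check')", ["check", "range"])
        assert not evaluate_filter("has_tag('check')", ["range"])

    def test_prefix_star_matches_any_prefixed_tag(self):
        assert evaluate_filter("has_tag('per_*')", ["mean", "per_site"])
        assert evaluate_filter("lacks_tag('per_*')", ["mean"])
        assert not evaluate_filter("lacks_tag('per_*')", ["per_patient"])

    def test_boolean_combinations(self):
        f = "has_tag('check') and lacks_tag('per_*')"
        assert evaluate_filter(f, ["check"])
        assert not evaluate_filter(f, ["check", "per_site"])
        assert evaluate_filter("not has_tag('a') or has_tag('b')", ["b"])

    def test_filter_rejects_non_tag_constructs(self):
        for bad in ("True", "item0 > 1", "has_tag(x)", "os_system('x')"):
            with pytest.raises(FilterSyntaxError):
                parse_filter(bad)

    @given(st.lists(st.sampled_from(
        ["check", "range", "per_site", "per_patient", "mean", "generated"]),
        unique=True))
    @settings(max_examples=100, deadline=None)
    def test_atoms_match_exhaustive_enumeration(self, tags):
        assert evaluate_filter("has_tag('check')", tags) == ("check" in tags)
        assert evaluate_filter("lacks_tag('per_*')", tags) == (
            not any(t.startswith("per_") for t in tags)
        )


def _range_mm():
    return MeasurementMethod(
        tags=("check", "range", "per_site_demo"),
        domain_paths=(
            DomainPath("item0", "numeric",
                       DatasetBinding("dataset-row/biopsy/date_offset")),
            DomainPath("item1", "text",
                       DatasetBinding("dataset-row/context/facility/name")),
        ),
        check="item0 >= 0.0 and item0 <= 120.0",
        grouping="item1",
        characterization=Characterization(builtin="mean"),
        description="mean compliance to a range constraint per clinical site",
    )


class TestValidateAndSerialize:
    def test_valid_range_check_mm_has_no_issues(self):
        assert validate_mm(_range_mm()) == []

    def test_undeclared_item_reported(self):
        mm = MeasurementMethod(
            tags=("check",),
            domain_paths=(
                DomainPath("item0", "numeric", DatasetBinding("dataset-row/x")),
            ),
            check="item3 > 0",
            grouping=None,
            characterization=Characterization(builtin="mean"),
        )
        assert "UNDECLARED_ITEM" in [i.code for i in validate_mm(mm)]

    def test_empty_tags_reported(self):
        mm = MeasurementMethod(
            tags=(),
            domain_paths=(
                DomainPath("item0", "numeric", DatasetBinding("dataset-row/x")),
            ),
            check=None,
            grouping=None,
            characterization=Characterization(builtin="mean"),
        )
        assert "EMPTY_TAGS" in [i.code for i in validate_mm(mm)]

    def test_bad_item_numbering_reported(self):
        mm = MeasurementMethod(
            tags=("t",),
            domain_paths=(
                DomainPath("item1", "numeric", DatasetBinding("dataset-row/x")),
            ),
            check=None,
            grouping=None,
            characterization=Characterization(builtin="mean"),
        )
        assert "BAD_ITEM_NUMBERING" in [i.code for i in validate_mm(mm)]

    def test_document_round_trip_preserves_identity(self):
        mm = _range_mm()
        doc = mm_to_document(mm)
        back = mm_from_document(doc)
        assert back == mm
        assert back.id == mm.id

    def test_content_id_changes_with_content(self):
        mm = _range_mm()
        other = MeasurementMethod(
            tags=mm.tags,
            domain_paths=mm.domain_paths,
            check="item0 >= 0.0 and item0 <= 60.0",
            grouping=mm.grouping,
            characterization=mm.characterization,
            description=mm.description,
        )
        assert other.id != mm.id
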