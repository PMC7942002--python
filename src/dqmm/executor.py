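"""Execution of single and multi-layered measurement methods.

The pipeline per MM: assemble the input table (one vector per domain-path
item, rows aligned per dataset row or per upstream (MM, group) pair), apply
the optional check rule per row, assign each row to a group, then summarize
each group with the characterization. Multi-layered MMs are ordered by
dependency resolution (an MM whose filter matches another MM's tags runs
after it); execution is fail-soft — one failing MM never aborts the batch.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .data_model import (
    MISSING,
    Dataset,
    count_child_nodes,
    is_missing,
    parse_path,
    resolve_path,
)
from .mm_model import (
    AUX_BUILTINS,
    CHARACTERIZATION_REGISTRY,
    Characterization,
    DatasetBinding,
    MeasurementMethod,
    MMFilterBinding,
    compile_expression,
    evaluate_expression,
    evaluate_filter,
    parse_filter,
    validate_mm,
)

__all__ = [
    "InputTable",
    "MMResult",
    "ExecutionError",
    "EmptyFilterError",
    "UnsupportedCombinationError",
    "CycleError",
    "assemble_input",
    "apply_check",
    "apply_grouping",
    "apply_characterization",
    "resolve_execution_order",
    "execute_mm",
    "execute_all",
    "results_to_table",
]

ALL_GROUP = "ALL"
MISSING_GROUP = "MISSING"


class ExecutionError(RuntimeError):
    pass


class EmptyFilterError(ExecutionError):
    """A filter domain path matched no executed MM."""


class UnsupportedCombinationError(ExecutionError):
    """Mixed dataset/filter domain paths, or misaligned filter items."""


class CycleError(ExecutionError):
    def __init__(self, cycle_ids):
        self.cycle_ids = list(cycle_ids)
        super().__init__(f"dependency cycle among MMs: {self.cycle_ids}")


@dataclass
class InputTable:
    """Aligned input vectors plus per-row provenance.

    ``provenance`` holds, per row, either a dataset row index (int) or an
    ``(mm_id, group_label)`` pair for filter-based inputs.
    """

    columns: dict[str, list]
    provenance: list
    check_results: list | None = None

    @property
    def n_rows(self) -> int:
        return len(self.provenance)


@dataclass
class MMResult:
    mm_id: str
    tags: tuple[str, ...]
    groups: list[tuple[str, object]] = field(default_factory=list)
    checked_counts: dict | None = None  # {"true": .., "false": .., "missing": ..}
    failed: bool = False
    error: str | None = None
    n_input_rows: int = 0
    dataset_fingerprint: str | None = None

    def value(self, group: str = ALL_GROUP):
        for label, val in self.groups:
            if label == group:
                return val
        raise KeyError(group)

    def group_labels(self) -> list[str]:
        return [label for label, _ in self.groups]


def dataset_fingerprint(dataset: Dataset) -> str:
    h = hashlib.sha256()
    h.update(str(len(dataset.rows)).encode())
    for v in dataset.variables:
        h.update(f"{v.path}|{v.reference_type}|{v.observed_in_rows}".encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Input assembly
# ---------------------------------------------------------------------------

def _dataset_item_values(row, binding: DatasetBinding) -> list:
    if binding.instruction is not None:
        return [count_child_nodes(row, binding.path, binding.instruction)]
    values = resolve_path(row, parse_path(binding.path))
    return values if values else [MISSING]


def _assemble_from_dataset(mm, dataset: Dataset) -> InputTable:
    columns: dict[str, list] = {dp.item_name: [] for dp in mm.domain_paths}
    provenance: list = []
    for row in dataset.rows:
        per_item = {
            dp.item_name: _dataset_item_values(row, dp.source)
            for dp in mm.domain_paths
        }
        # repeated elements produce one input row per matched node; scalars
        # broadcast, shorter multi-match vectors pad with missing
        width = max(len(v) for v in per_item.values())
        for k in range(width):
            for name, vals in per_item.items():
                if len(vals) == 1:
                    columns[name].append(vals[0])
                elif k < len(vals):
                    columns[name].append(vals[k])
                else:
                    columns[name].append(MISSING)
            provenance.append(row.row_index)
    return InputTable(columns, provenance)


def _select(result: MMResult, label: str, value, selector: str):
    if selector == "resultsValue":
        return value
    if selector == "resultsGroupLabels":
        return label
    if selector == "tags":
        return list(result.tags)
    raise ExecutionError(f"unknown selector {selector!r}")


def _assemble_from_filters(mm, prior: Mapping[str, MMResult]) -> InputTable:
    columns: dict[str, list] = {}
    keys_reference: list | None = None
    for dp in mm.domain_paths:
        src: MMFilterBinding = dp.source
        tree = parse_filter(src.filter)
        matched = [
            r for r in prior.values()
            if not r.failed and evaluate_filter(tree, r.tags)
        ]
        if not matched:
            raise EmptyFilterError(
                f"MM {mm.id}: filter {src.filter!r} matched no executed MM"
            )
        keys, vals = [], []
        for r in matched:
            for label, value in r.groups:
                keys.append((r.mm_id, label))
                vals.append(_select(r, label, value, src.selector))
        if keys_reference is None:
            keys_reference = keys
        elif keys != keys_reference:
            raise UnsupportedCombinationError(
                f"MM {mm.id}: filter items select different (MM, group) rows"
            )
        columns[dp.item_name] = vals
    return InputTable(columns, list(keys_reference or []))


def assemble_input(
    mm: MeasurementMethod,
    dataset: Dataset | None,
    prior: Mapping[str, MMResult] | None = None,
) -> InputTable:
    """Build the aligned input table for one MM.

    Dataset-bound MMs read from ``dataset`` (one row per dataset row, with
    repeated elements flattened); filter-bound MMs read from ``prior``
    results, one row per (matched MM, group). Mixing kinds is rejected.
    """
    kinds = {type(dp.source) for dp in mm.domain_paths}
    if kinds == {DatasetBinding}:
        if dataset is None:
            raise ExecutionError(f"MM {mm.id}: no dataset supplied")
        return _assemble_from_dataset(mm, dataset)
    if kinds == {MMFilterBinding}:
        return _assemble_from_filters(mm, prior or {})
    raise UnsupportedCombinationError(
        f"MM {mm.id}: domain paths must be all-dataset or all-filter"
    )


# ---------------------------------------------------------------------------
# Check / grouping / characterization
# ---------------------------------------------------------------------------

def apply_check(mm: MeasurementMethod, table: InputTable) -> InputTable:
    """Evaluate the check rule per input row; results stored on the table."""
    if mm.check is None:
        return table
    tree = compile_expression(mm.check)
    results = []
    for i in range(table.n_rows):
        bindings = {name: col[i] for name, col in table.columns.items()}
        try:
            results.append(evaluate_expression(tree, bindings))
        except Exception as exc:
            raise ExecutionError(
                f"MM {mm.id}: check failed at input row {i} "
                f"(provenance {table.provenance[i]!r}): {exc}"
            ) from exc
    table.check_results = results
    return table


def apply_grouping(mm: MeasurementMethod, table: InputTable) -> list[str]:
    """Group label per input row; 'ALL' when no grouping rule is set."""
    if mm.grouping is None:
        return [ALL_GROUP] * table.n_rows
    tree = compile_expression(mm.grouping)
    labels = []
    for i in range(table.n_rows):
        bindings = {name: col[i] for name, col in table.columns.items()}
        try:
            value = evaluate_expression(tree, bindings)
        except Exception as exc:
            raise ExecutionError(
                f"MM {mm.id}: grouping failed at input row {i}: {exc}"
            ) from exc
        labels.append(MISSING_GROUP if is_missing(value) else str(value))
    return labels


def _characterize(char: Characterization, values: list, aux: dict):
    if char.builtin is not None:
        fn = CHARACTERIZATION_REGISTRY.get(char.builtin)
        if fn is None:
            raise ExecutionError(f"unknown characterization builtin {char.builtin!r}")
        if char.builtin in AUX_BUILTINS:
            return fn(values, aux=aux, **dict(char.params))
        return fn(values, **dict(char.params))
    # custom expression over whole vectors: items bound as lists, the
    # characterized vector as 'v'
    bindings = {name: list(col) for name, col in aux.items()}
    bindings["v"] = list(values)
    return evaluate_expression(char.custom, bindings)


def apply_characterization(
    mm: MeasurementMethod, table: InputTable, labels: Sequence[str]
) -> MMResult:
    """Summarize each group; consumes the check vector if a check exists,
    otherwise item0's vector. Groups are ordered lexicographically."""
    target = (
        table.check_results
        if mm.check is not None
        else table.columns[mm.domain_paths[0].item_name]
    )
    by_group: dict[str, list[int]] = {}
    for i, label in enumerate(labels):
        by_group.setdefault(label, []).append(i)
    groups = []
    for label in sorted(by_group):
        idx = by_group[label]
        values = [target[i] for i in idx]
        aux = {
            name: [col[i] for i in idx] for name, col in table.columns.items()
        }
        # alias filter-bound items by their selector so characterizations
        # like mean_by_variable can find the '.tags' vector by role
        for dp in mm.domain_paths:
            if isinstance(dp.source, MMFilterBinding):
                aux.setdefault(dp.source.selector, aux[dp.item_name])
        groups.append((label, _characterize(mm.characterization, values, aux)))
    checked = None
    if mm.check is not None:
        checked = {
            "true": sum(1 for v in table.check_results if v is True),
            "false": sum(1 for v in table.check_results if v is False),
            "missing": sum(1 for v in table.check_results if is_missing(v)),
        }
    return MMResult(
        mm_id=mm.id,
        tags=tuple(mm.tags),
        groups=groups,
        checked_counts=checked,
        n_input_rows=table.n_rows,
    )


# ---------------------------------------------------------------------------
# Dependency resolution and batch execution
# ---------------------------------------------------------------------------

def resolve_execution_order(
    mms: Sequence[MeasurementMethod],
) -> list[MeasurementMethod]:
    """Topological order over the filter-dependency graph, stable w.r.t.
    input order for independent MMs; raises :class:`CycleError` on cycles."""
    import networkx as nx

    index = {mm.id: i for i, mm in enumerate(mms)}
    graph = nx.DiGraph()
    graph.add_nodes_from(index)
    for mm in mms:
        for dp in mm.domain_paths:
            if isinstance(dp.source, MMFilterBinding):
                tree = parse_filter(dp.source.filter)
                for other in mms:
                    if other.id != mm.id and evaluate_filter(tree, other.tags):
                        graph.add_edge(other.id, mm.id)
    try:
        order = list(
            nx.lexicographical_topological_sort(graph, key=index.__getitem__)
        )
    except nx.NetworkXUnfeasible:
        cycle_ids = sorted(
            {mid for edge in nx.find_cycle(graph) for mid in edge},
            key=index.__getitem__,
        )
        raise CycleError(cycle_ids) from None
    by_id = {mm.id: mm for mm in mms}
    return [by_id[mid] for mid in order]


def execute_mm(
    mm: MeasurementMethod,
    dataset: Dataset | None,
    prior: Mapping[str, MMResult] | None = None,
) -> MMResult:
    """Run one MM end to end."""
    issues = validate_mm(mm)
    if issues:
        raise ExecutionError(
            f"MM {mm.id} is invalid: {[i.code for i in issues]}"
        )
    table = assemble_input(mm, dataset, prior)
    table = apply_check(mm, table)
    labels = apply_grouping(mm, table)
    result = apply_characterization(mm, table, labels)
    if dataset is not None and not mm.is_filter_based():
        result.dataset_fingerprint = dataset_fingerprint(dataset)
    return result


def execute_all(
    mms: Sequence[MeasurementMethod], dataset: Dataset | None
) -> dict[str, MMResult]:
    """Execute a batch in dependency order; failures are recorded per MM and
    never abort the batch."""
    results: dict[str, MMResult] = {}
    for mm in resolve_execution_order(mms):
        try:
            results[mm.id] = execute_mm(mm, dataset, results)
        except Exception as exc:
            results[mm.id] = MMResult(
                mm_id=mm.id, tags=tuple(mm.tags), failed=True, error=str(exc)
            )
    return results


def results_to_table(results: Mapping[str, MMResult]):
    """Flat (mm_id, tags, group_label, value) table for downstream tooling."""
    import pandas as pd

    records = []
    for r in sorted(results.values(), key=lambda r: r.mm_id):
        if r.failed:
            records.append(
                {"mm_id": r.mm_id, "tags": ";".join(r.tags),
                 "group_label": None, "value": None, "failed": True,
                 "error": r.error}
            )
            continue
        for label, value in r.groups:
            records.append(
                {"mm_id": r.mm_id, "tags": ";".join(r.tags),
                 "group_label": label,
                 "value": value if not is_missing(value) else None,
                 "failed": False, "error": None}
            )
    return pd.DataFrame.from_records(
        records,
        columns=["mm_id", "tags", "group_label", "value", "failed", "error"],
    )
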