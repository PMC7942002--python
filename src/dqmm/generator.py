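"""Automatic derivation of measurement methods.

Two generation routes mirror how DQ knowledge arrives in practice:

* *type-based*: from each variable's reference-model type, profiling MMs are
  derived (distribution measures for numerics, frequencies for categoricals),
  per a pinned, user-overridable generation matrix;
* *constraint-based*: from a constraint schema emulating clinical information
  model (CIM) constraints — ranges (optionally per unit), value sets,
  cardinality/mandatory occurrence, regex patterns — one check MM each,
  characterized by the mean pass fraction.

Dimension variants add a grouping (per site, per patient, per month, ...) and
a ``per_<dimension>`` tag so downstream filters can include or exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .data_model import Dataset, VariableDescriptor, parse_path
from .mm_model import (
    Characterization,
    DatasetBinding,
    DomainPath,
    MeasurementMethod,
    evaluate_filter,
    parse_filter,
)

__all__ = [
    "VariableConstraint",
    "ConstraintSchema",
    "GenerationMatrix",
    "DEFAULT_MATRIX",
    "SchemaError",
    "generate_type_mms",
    "generate_constraint_mms",
    "generate_dimension_variants",
    "filter_mms",
    "parent_path",
]


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class VariableConstraint:
    """Constraints on one variable, addressed by its dataset path."""

    path: str
    reference_type: str  # NUMERIC | TEXT | CODED_TEXT | DATE_TIME | BOOLEAN | COUNT
    mandatory: bool = False
    occurrence: tuple[int, int] | None = None  # (min, max) child occurrences
    range: tuple[float, float] | None = None
    unit_ranges: Mapping[str, tuple[float, float]] | None = None
    value_set: Sequence[str] | None = None
    pattern: str | None = None
    unit_path: str | None = None  # companion unit variable for unit_ranges


@dataclass(frozen=True)
class ConstraintSchema:
    schema_id: str
    variables: tuple[VariableConstraint, ...]

    def __post_init__(self):
        paths = [v.path for v in self.variables]
        if len(set(paths)) != len(paths):
            raise SchemaError(f"duplicate variable paths in {self.schema_id}")
        for v in self.variables:
            parse_path(v.path)
            if v.range is not None and v.range[0] > v.range[1]:
                raise SchemaError(f"{v.path}: range lo > hi")
            if v.unit_ranges:
                if v.unit_path is None:
                    raise SchemaError(f"{v.path}: unit_ranges need unit_path")
                for unit, (lo, hi) in v.unit_ranges.items():
                    if lo > hi:
                        raise SchemaError(f"{v.path} [{unit}]: range lo > hi")


# reference_type -> characterization builtins; pinned for reproducibility,
# overridable by the caller
DEFAULT_MATRIX_MAPPING: dict[str, tuple[str, ...]] = {
    "NUMERIC": ("count_present", "min", "max", "mean", "median", "sd",
                "histogram"),
    "COUNT": ("count_present", "min", "max", "mean", "median", "sd",
              "histogram"),
    "TEXT": ("count_present", "frequency_table", "relative_frequency_table",
             "barplot"),
    "CODED_TEXT": ("count_present", "frequency_table",
                   "relative_frequency_table", "barplot"),
    "DATE_TIME": ("count_present", "min", "max"),
    "BOOLEAN": ("count_present", "frequency_table"),
}

_TYPE_TO_ITEM = {
    "NUMERIC": "numeric", "COUNT": "numeric", "TEXT": "text",
    "CODED_TEXT": "text", "DATE_TIME": "datetime", "BOOLEAN": "boolean",
}

_DATE_DERIVATIONS = ("year", "month", "quarter", "day", "weekday")


@dataclass(frozen=True)
class DimensionSpec:
    name: str  # e.g. "site", "patient", "month"
    path: str  # grouping variable's dataset path
    derivation: str | None = None  # optional date-part derivation


@dataclass(frozen=True)
class GenerationMatrix:
    mapping: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MATRIX_MAPPING)
    )
    dimensions: tuple[DimensionSpec, ...] = ()


DEFAULT_MATRIX = GenerationMatrix()


def load_schema(source) -> ConstraintSchema:
    """Read a constraint schema from a YAML document (path, stream or text).

    Top-level keys: ``schema_id`` and ``variables``; each variable has
    ``path``, ``reference_type`` and optional ``mandatory``, ``occurrence``
    ([min, max]), ``range`` ([lo, hi]), ``unit_ranges`` (unit -> [lo, hi]),
    ``value_set``, ``pattern``, ``unit_path``.
    """
    import yaml
    from pathlib import Path

    if hasattr(source, "read"):
        text = source.read()
    else:
        p = Path(str(source))
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise SchemaError("schema document needs 'schema_id' and 'variables'")
    variables = []
    for v in doc["variables"]:
        variables.append(
            VariableConstraint(
                path=v["path"],
                reference_type=v.get("reference_type", "TEXT"),
                mandatory=bool(v.get("mandatory", False)),
                occurrence=tuple(v["occurrence"]) if v.get("occurrence") else None,
                range=tuple(v["range"]) if v.get("range") else None,
                unit_ranges={
                    u: tuple(r) for u, r in (v.get("unit_ranges") or {}).items()
                } or None,
                value_set=tuple(v["value_set"]) if v.get("value_set") else None,
                pattern=v.get("pattern"),
                unit_path=v.get("unit_path"),
            )
        )
    return ConstraintSchema(
        schema_id=str(doc.get("schema_id", "schema")),
        variables=tuple(variables),
    )


def dump_schema(schema: ConstraintSchema) -> str:
    """Schema as YAML text (inverse of :func:`load_schema`)."""
    import yaml

    variables = []
    for v in schema.variables:
        entry: dict = {"path": v.path, "reference_type": v.reference_type}
        if v.mandatory:
            entry["mandatory"] = True
        if v.occurrence is not None:
            entry["occurrence"] = list(v.occurrence)
        if v.range is not None:
            entry["range"] = list(v.range)
        if v.unit_ranges:
            entry["unit_ranges"] = {u: list(r) for u, r in v.unit_ranges.items()}
        if v.value_set is not None:
            entry["value_set"] = list(v.value_set)
        if v.pattern is not None:
            entry["pattern"] = v.pattern
        if v.unit_path is not None:
            entry["unit_path"] = v.unit_path
        variables.append(entry)
    return yaml.safe_dump(
        {"schema_id": schema.schema_id, "variables": variables},
        sort_keys=False, allow_unicode=True,
    )


def generate_type_mms(
    variables: Sequence[VariableDescriptor],
    matrix: GenerationMatrix = DEFAULT_MATRIX,
) -> list[MeasurementMethod]:
    """One profiling MM per (variable, matrix entry), deterministic order."""
    mms = []
    for var in variables:
        builtins = matrix.mapping.get(var.reference_type, ())
        for builtin in builtins:
            item_type = _TYPE_TO_ITEM.get(var.reference_type, "text")
            mms.append(
                MeasurementMethod(
                    tags=(builtin, var.path, "generated", "type_based"),
                    domain_paths=(
                        DomainPath("item0", item_type,
                                   DatasetBinding(var.path)),
                    ),
                    check=None,
                    grouping=None,
                    characterization=Characterization(builtin=builtin),
                    description=(
                        f"{builtin} of values in {var.path} "
                        f"({var.reference_type})"
                    ),
                )
            )
    return mms


def parent_path(path: str) -> str:
    """Dataset path of a node's parent element (for cardinality checks)."""
    parsed = parse_path(path)
    if len(parsed.segments) < 2:
        raise SchemaError(f"path {path!r} has no parent inside the row")
    from .data_model import ParsedPath, render_path

    return render_path(ParsedPath(parsed.segments[:-1]))


def _range_expr(lo: float, hi: float, item: str = "item0") -> str:
    return f"{item} >= {lo!r} and {item} <= {hi!r}"


def _unit_range_expr(unit_ranges: Mapping[str, tuple[float, float]]) -> str:
    # chained conditional: unknown unit yields MISSING (cannot be judged)
    expr = "MISSING"
    for unit in sorted(unit_ranges, reverse=True):
        lo, hi = unit_ranges[unit]
        expr = f"({_range_expr(lo, hi)}) if item1 == {unit!r} else ({expr})"
    return expr


def _value_set_expr(values: Sequence[str]) -> str:
    rendered = ", ".join(repr(str(v)) for v in values)
    return f"in_list(item0, [{rendered}])"


def _check_mm(kind, path, domain_paths, check, description):
    return MeasurementMethod(
        tags=("check", kind, path, "generated", "cim_based"),
        domain_paths=tuple(domain_paths),
        check=check,
        grouping=None,
        characterization=Characterization(builtin="mean"),
        description=description,
    )


def generate_constraint_mms(schema: ConstraintSchema) -> list[MeasurementMethod]:
    """One ungrouped check MM per constraint, mean pass fraction as result."""
    known_paths = {v.path for v in schema.variables}
    mms = []
    for var in schema.variables:
        if var.unit_path is not None and var.unit_path not in known_paths:
            raise SchemaError(
                f"{var.path}: unit_path {var.unit_path!r} not in schema"
            )
        if var.mandatory or var.occurrence is not None:
            lo, hi = var.occurrence if var.occurrence is not None else (1, 1)
            container = parent_path(var.path)
            mms.append(
                _check_mm(
                    "cardinality", var.path,
                    [DomainPath(
                        "item0", "numeric",
                        DatasetBinding(
                            container + ".countChildnodes(only_child)",
                            "only_child",
                        ),
                    )],
                    _range_expr(lo, hi),
                    f"cardinality [{lo},{hi}] of {var.path}",
                )
            )
        if var.unit_ranges:
            mms.append(
                _check_mm(
                    "range", var.path,
                    [
                        DomainPath("item0", "numeric",
                                   DatasetBinding(var.path)),
                        DomainPath("item1", "text",
                                   DatasetBinding(var.unit_path)),
                    ],
                    _unit_range_expr(var.unit_ranges),
                    f"unit-conditional range of {var.path}",
                )
            )
        elif var.range is not None:
            lo, hi = var.range
            mms.append(
                _check_mm(
                    "range", var.path,
                    [DomainPath("item0", "numeric", DatasetBinding(var.path))],
                    _range_expr(lo, hi),
                    f"range [{lo},{hi}] of {var.path}",
                )
            )
        if var.value_set is not None:
            if not var.value_set:
                raise SchemaError(f"{var.path}: empty value_set")
            mms.append(
                _check_mm(
                    "value_set", var.path,
                    [DomainPath("item0", "text", DatasetBinding(var.path))],
                    _value_set_expr(var.value_set),
                    f"value set of {var.path}",
                )
            )
        if var.pattern is not None:
            mms.append(
                _check_mm(
                    "pattern", var.path,
                    [DomainPath("item0", "text", DatasetBinding(var.path))],
                    f"matches(item0, {var.pattern!r})",
                    f"pattern of {var.path}",
                )
            )
    return mms


def constraint_count(schema: ConstraintSchema) -> int:
    """Number of check MMs generation will emit (enumeration helper)."""
    n = 0
    for v in schema.variables:
        n += int(v.mandatory or v.occurrence is not None)
        n += int(bool(v.unit_ranges) or v.range is not None)
        n += int(v.value_set is not None)
        n += int(v.pattern is not None)
    return n


def generate_dimension_variants(
    mms: Sequence[MeasurementMethod],
    dimensions: Sequence[DimensionSpec],
    dataset: Dataset | None = None,
) -> list[MeasurementMethod]:
    """Grouped copies of each MM, one per dimension; originals untouched.

    Each variant gains a domain path for the dimension variable, a grouping
    expression (optionally a date-part derivation) and a ``per_<name>`` tag.
    Dimensions whose path is absent from ``dataset`` (when given) are skipped.
    """
    known = set(dataset.variable_paths()) if dataset is not None else None
    variants = []
    for dim in dimensions:
        if dim.derivation is not None and dim.derivation not in _DATE_DERIVATIONS:
            raise SchemaError(f"unknown date derivation {dim.derivation!r}")
        if known is not None and dim.path not in known:
            import warnings

            warnings.warn(
                f"dimension {dim.name!r}: path {dim.path!r} not in dataset; "
                "variants skipped",
                stacklevel=2,
            )
            continue
        for mm in mms:
            if mm.is_filter_based():
                continue
            item = f"item{len(mm.domain_paths)}"
            item_type = "datetime" if dim.derivation else "text"
            grouping = (
                f"{dim.derivation}({item})" if dim.derivation else item
            )
            variants.append(
                MeasurementMethod(
                    tags=tuple(mm.tags) + (f"per_{dim.name}",),
                    domain_paths=tuple(mm.domain_paths)
                    + (DomainPath(item, item_type, DatasetBinding(dim.path)),),
                    check=mm.check,
                    grouping=grouping,
                    characterization=mm.characterization,
                    description=(
                        (mm.description or mm.id) + f", per {dim.name}"
                    ),
                )
            )
    return variants


def filter_mms(
    mms: Sequence[MeasurementMethod], predicate: str
) -> list[MeasurementMethod]:
    """MMs whose tags satisfy the filter expression, order preserved."""
    tree = parse_filter(predicate)
    return [mm for mm in mms if evaluate_filter(tree, mm.tags)]
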