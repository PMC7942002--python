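"""Measurement methods (MMs) as 5-tuples and their expression dialect.

An MM is a 5-tuple of (tags, domain paths, optional check, optional grouping,
characterization). Tags are descriptive keywords; domain paths bind the input
vectors, either to dataset paths or — for multi-layered MMs — to other MMs'
results selected by a tag filter; the check rule is applied per input row; the
grouping rule assigns each row to a group; the characterization summarizes
each group into the MM-result.

Executable parts (check, grouping, custom characterizations) are written in a
closed, sandboxed expression dialect: arithmetic, comparisons, boolean
``and``/``or``/``not``, conditional ``a if cond else b``, ``in_list``,
``concat``/``format``, regex ``matches``, and date part extraction
(``year``/``month``/``quarter``/``day``/``weekday``). There is no I/O, no
loop, and no user-defined function, which keeps MMs portable and safe to run
from untrusted knowledge bases. A missing operand makes the result missing.
"""

from __future__ import annotations

import ast
import hashlib
import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Callable, Mapping, Sequence

import numpy as np

from .data_model import MISSING, is_missing, parse_path, render_path

__all__ = [
    "DatasetBinding",
    "MMFilterBinding",
    "DomainPath",
    "Characterization",
    "MeasurementMethod",
    "ExpressionError",
    "FilterSyntaxError",
    "DomainPathSyntaxError",
    "parse_domain_path",
    "render_domain_path",
    "compile_expression",
    "evaluate_expression",
    "expression_variables",
    "parse_filter",
    "evaluate_filter",
    "validate_mm",
    "ValidationIssue",
    "CHARACTERIZATION_REGISTRY",
    "AUX_BUILTINS",
    "mm_to_document",
    "mm_from_document",
    "content_id",
]


# ---------------------------------------------------------------------------
# Domain paths
# ---------------------------------------------------------------------------

class DomainPathSyntaxError(ValueError):
    pass


_TYPE_ALIASES = {
    "numeric": "numeric",
    "number": "numeric",
    "string": "text",
    "text": "text",
    "boolean": "boolean",
    "datetime": "datetime",
}

_SELECTORS = ("resultsValue", "resultsGroupLabels", "tags")


@dataclass(frozen=True)
class DatasetBinding:
    path: str  # path dialect text, including optional instruction suffix
    instruction: str | None = None  # countChildnodes mode, if present


@dataclass(frozen=True)
class MMFilterBinding:
    filter: str  # filter-expression text over candidate MMs' tags
    selector: str  # resultsValue | resultsGroupLabels | tags


@dataclass(frozen=True)
class DomainPath:
    item_name: str
    declared_type: str  # numeric | text | boolean | datetime
    source: DatasetBinding | MMFilterBinding


_DP_RE = re.compile(
    r"^#\s*(?P<item>item\d+)\s*\((?P<type>[A-Za-z]+)\)\s*=\s*(?P<binding>.+)$"
)


def parse_domain_path(text: str) -> DomainPath:
    """Parse one domain-path line, ``# itemN (type) = <binding>``."""
    m = _DP_RE.match(text.strip())
    if m is None:
        raise DomainPathSyntaxError(
            f"domain path must match '# itemN (type) = <binding>': {text!r}"
        )
    item = m.group("item")
    type_kw = m.group("type").lower()
    if type_kw not in _TYPE_ALIASES:
        raise DomainPathSyntaxError(
            f"unknown type keyword {m.group('type')!r} in {text!r}"
        )
    binding_text = m.group("binding").strip()
    if binding_text.startswith("other_data_input:"):
        body = binding_text[len("other_data_input:"):].strip()
        selector = None
        for sel in _SELECTORS:
            if body.endswith("." + sel):
                selector = sel
                body = body[: -len(sel) - 1].strip()
                break
        if selector is None:
            raise DomainPathSyntaxError(
                f"filter binding must end with one of "
                f"{['.' + s for s in _SELECTORS]}: {text!r}"
            )
        parse_filter(body)  # validates
        source: DatasetBinding | MMFilterBinding = MMFilterBinding(body, selector)
    else:
        parsed = parse_path(binding_text)  # raises PathSyntaxError subclass
        source = DatasetBinding(render_path(parsed), parsed.instruction)
    return DomainPath(item, _TYPE_ALIASES[type_kw], source)


def render_domain_path(dp: DomainPath) -> str:
    type_kw = "string" if dp.declared_type == "text" else dp.declared_type
    if isinstance(dp.source, MMFilterBinding):
        binding = f"other_data_input: {dp.source.filter} .{dp.source.selector}"
    else:
        binding = dp.source.path
    return f"# {dp.item_name} ({type_kw}) = {binding}"


# ---------------------------------------------------------------------------
# Expression dialect
# ---------------------------------------------------------------------------

class ExpressionError(ValueError):
    pass


_ALLOWED_NODES = (
    ast.Expression, ast.BoolOp, ast.And, ast.Or, ast.UnaryOp, ast.Not,
    ast.USub, ast.UAdd, ast.BinOp, ast.Add, ast.Sub, ast.Mult, ast.Div,
    ast.Mod, ast.Pow, ast.FloorDiv, ast.Compare, ast.Eq, ast.NotEq, ast.Lt,
    ast.LtE, ast.Gt, ast.GtE, ast.Call, ast.Name, ast.Load, ast.Constant,
    ast.List, ast.IfExp,
)

_DIALECT_FUNCTIONS = frozenset({
    "in_list", "concat", "format", "matches", "year", "month", "quarter",
    "day", "weekday", "abs", "round", "len",
})


def compile_expression(text: str) -> ast.Expression:
    """Parse expression text and reject anything outside the dialect."""
    if not isinstance(text, str) or not text.strip():
        raise ExpressionError("empty expression")
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"invalid expression {text!r}: {exc}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ExpressionError(
                f"construct {type(node).__name__} not allowed in dialect: "
                f"{text!r}"
            )
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.keywords:
                raise ExpressionError(f"bad function call in {text!r}")
            if node.func.id not in _DIALECT_FUNCTIONS:
                raise ExpressionError(
                    f"unknown function {node.func.id!r} in {text!r}"
                )
        if isinstance(node, ast.Constant) and not isinstance(
            node.value, (int, float, str, bool, type(None))
        ):
            raise ExpressionError(f"literal {node.value!r} not allowed")
    return tree


def expression_variables(text: str) -> set[str]:
    """Free variables (item names) referenced by an expression."""
    tree = compile_expression(text)
    names = set()
    for node in ast.walk(tree):
        if isinstance(node, ast.Name) and node.id not in _DIALECT_FUNCTIONS:
            names.add(node.id)
    return names


def _to_date(value):
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    if isinstance(value, str):
        for parser in (date.fromisoformat,):
            try:
                return parser(value[:10])
            except ValueError:
                pass
    raise ExpressionError(f"not a date: {value!r}")


def _is_number(v):
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def _call(name: str, args: list):
    if name == "in_list":
        if len(args) != 2 or not isinstance(args[1], list):
            raise ExpressionError("in_list(value, [..]) expects a list")
        return args[0] in args[1]
    if name == "concat":
        return "".join(str(a) for a in args)
    if name == "format":
        if not args or not isinstance(args[0], str):
            raise ExpressionError("format(fmt, ...) needs a format string")
        return args[0] % tuple(args[1:])
    if name == "matches":
        if len(args) != 2 or not all(isinstance(a, str) for a in args):
            raise ExpressionError("matches(text, pattern) expects two strings")
        return re.search(args[1], args[0]) is not None
    if name in ("year", "month", "day"):
        d = _to_date(args[0])
        return getattr(d, name)
    if name == "quarter":
        return (_to_date(args[0]).month - 1) // 3 + 1
    if name == "weekday":
        return _to_date(args[0]).isoweekday()  # 1=Monday .. 7=Sunday
    if name == "abs":
        if not _is_number(args[0]):
            raise ExpressionError("abs expects a number")
        return abs(args[0])
    if name == "round":
        if not _is_number(args[0]):
            raise ExpressionError("round expects a number")
        return round(*args)
    if name == "len":
        if not isinstance(args[0], (str, list)):
            raise ExpressionError("len expects a string or list")
        return len(args[0])
    raise ExpressionError(f"unknown function {name!r}")


_CMP_OPS = {
    ast.Lt: "lt", ast.LtE: "le", ast.Gt: "gt", ast.GtE: "ge",
    ast.Eq: "eq", ast.NotEq: "ne",
}


def _compare(op, left, right):
    kind = _CMP_OPS[type(op)]
    if kind in ("eq", "ne"):
        same = (
            (_is_number(left) and _is_number(right))
            or type(left) is type(right)
            or (isinstance(left, bool) and isinstance(right, bool))
        )
        eq = left == right if same else False
        return eq if kind == "eq" else not eq
    comparable = (
        (_is_number(left) and _is_number(right))
        or (isinstance(left, str) and isinstance(right, str))
        or (isinstance(left, (date, datetime)) and isinstance(right, (date, datetime)))
    )
    if not comparable:
        raise ExpressionError(
            f"cannot order {type(left).__name__} and {type(right).__name__} "
            f"({left!r} vs {right!r})"
        )
    return {"lt": left < right, "le": left <= right,
            "gt": left > right, "ge": left >= right}[kind]


def _eval_node(node, bindings):
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, bindings)
    if isinstance(node, ast.Constant):
        return node.value
    if isinstance(node, ast.Name):
        if node.id == "MISSING":
            return MISSING
        if node.id not in bindings:
            raise ExpressionError(f"unbound variable {node.id!r}")
        value = bindings[node.id]
        return MISSING if is_missing(value) else value
    if isinstance(node, ast.List):
        return [_eval_node(e, bindings) for e in node.elts]
    if isinstance(node, ast.IfExp):
        cond = _eval_node(node.test, bindings)
        if is_missing(cond):
            return MISSING
        if not isinstance(cond, bool):
            raise ExpressionError("condition must be boolean")
        return _eval_node(node.body if cond else node.orelse, bindings)
    if isinstance(node, ast.BoolOp):
        values = [_eval_node(v, bindings) for v in node.values]
        if any(is_missing(v) for v in values):
            return MISSING
        if not all(isinstance(v, bool) for v in values):
            raise ExpressionError("and/or operands must be boolean")
        return all(values) if isinstance(node.op, ast.And) else any(values)
    if isinstance(node, ast.UnaryOp):
        operand = _eval_node(node.operand, bindings)
        if is_missing(operand):
            return MISSING
        if isinstance(node.op, ast.Not):
            if not isinstance(operand, bool):
                raise ExpressionError("not operand must be boolean")
            return not operand
        if not _is_number(operand):
            raise ExpressionError("unary +/- needs a number")
        return -operand if isinstance(node.op, ast.USub) else +operand
    if isinstance(node, ast.BinOp):
        left = _eval_node(node.left, bindings)
        right = _eval_node(node.right, bindings)
        if is_missing(left) or is_missing(right):
            return MISSING
        if isinstance(node.op, ast.Add) and isinstance(left, str):
            if not isinstance(right, str):
                raise ExpressionError("cannot concatenate string and non-string")
            return left + right
        if not (_is_number(left) and _is_number(right)):
            raise ExpressionError(
                f"arithmetic needs numbers, got {left!r} and {right!r}"
            )
        ops = {
            ast.Add: lambda a, b: a + b, ast.Sub: lambda a, b: a - b,
            ast.Mult: lambda a, b: a * b, ast.Div: lambda a, b: a / b,
            ast.Mod: lambda a, b: a % b, ast.Pow: lambda a, b: a ** b,
            ast.FloorDiv: lambda a, b: a // b,
        }
        try:
            return ops[type(node.op)](left, right)
        except ZeroDivisionError:
            raise ExpressionError("division by zero")
    if isinstance(node, ast.Compare):
        left = _eval_node(node.left, bindings)
        result = True
        for op, comparator in zip(node.ops, node.comparators):
            right = _eval_node(comparator, bindings)
            if is_missing(left) or is_missing(right):
                return MISSING
            result = result and _compare(op, left, right)
            left = right
        return result
    if isinstance(node, ast.Call):
        args = [_eval_node(a, bindings) for a in node.args]
        if any(
            is_missing(a) or (isinstance(a, list) and any(is_missing(x) for x in a))
            for a in args
        ):
            return MISSING
        return _call(node.func.id, args)
    raise ExpressionError(f"unsupported node {type(node).__name__}")


def evaluate_expression(expr: str | ast.Expression, bindings: Mapping) -> object:
    """Evaluate an expression with item bindings; missing propagates."""
    tree = compile_expression(expr) if isinstance(expr, str) else expr
    return _eval_node(tree, bindings)


# ---------------------------------------------------------------------------
# Tag filters (for multi-layered MMs and MM-set filtering)
# ---------------------------------------------------------------------------

class FilterSyntaxError(ValueError):
    pass


_FILTER_FUNCS = ("has_tag", "lacks_tag")


def parse_filter(text: str) -> ast.Expression:
    """Parse a tag-filter expression: has_tag/lacks_tag atoms, and/or/not.

    A tag argument ending in ``*`` matches any tag with that prefix (so
    ``lacks_tag('per_*')`` excludes every dimension variant).
    """
    if not isinstance(text, str) or not text.strip():
        raise FilterSyntaxError("empty filter")
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise FilterSyntaxError(f"invalid filter {text!r}: {exc}") from exc
    for node in ast.walk(tree):
        if isinstance(node, (ast.Expression, ast.BoolOp, ast.And, ast.Or,
                             ast.Load)):
            continue
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
            continue
        if isinstance(node, ast.Not):
            continue
        if isinstance(node, ast.Call):
            if (
                isinstance(node.func, ast.Name)
                and node.func.id in _FILTER_FUNCS
                and len(node.args) == 1
                and isinstance(node.args[0], ast.Constant)
                and isinstance(node.args[0].value, str)
                and not node.keywords
            ):
                continue
            raise FilterSyntaxError(f"bad filter atom in {text!r}")
        if isinstance(node, (ast.Name, ast.Constant)):
            continue  # validated inside Call above; bare names rejected next
        raise FilterSyntaxError(
            f"construct {type(node).__name__} not allowed in filter {text!r}"
        )
    # reject bare names / constants outside call atoms
    def _check(node):
        if isinstance(node, ast.Expression):
            return _check(node.body)
        if isinstance(node, ast.BoolOp):
            return all(_check(v) for v in node.values)
        if isinstance(node, ast.UnaryOp):
            return _check(node.operand)
        return isinstance(node, ast.Call)

    if not _check(tree):
        raise FilterSyntaxError(f"filter must be built from tag atoms: {text!r}")
    return tree


def _tag_matches(pattern: str, tags: Sequence[str]) -> bool:
    if pattern.endswith("*"):
        prefix = pattern[:-1]
        return any(t.startswith(prefix) for t in tags)
    return pattern in tags


def _eval_filter(node, tags):
    if isinstance(node, ast.Expression):
        return _eval_filter(node.body, tags)
    if isinstance(node, ast.BoolOp):
        vals = [_eval_filter(v, tags) for v in node.values]
        return all(vals) if isinstance(node.op, ast.And) else any(vals)
    if isinstance(node, ast.UnaryOp):
        return not _eval_filter(node.operand, tags)
    if isinstance(node, ast.Call):
        pattern = node.args[0].value
        hit = _tag_matches(pattern, tags)
        return hit if node.func.id == "has_tag" else not hit
    raise FilterSyntaxError(f"unsupported filter node {type(node).__name__}")


def evaluate_filter(filter_expr: str | ast.Expression, tags: Sequence[str]) -> bool:
    tree = parse_filter(filter_expr) if isinstance(filter_expr, str) else filter_expr
    return _eval_filter(tree, list(tags))


# ---------------------------------------------------------------------------
# Characterizations
# ---------------------------------------------------------------------------

def _present(values):
    return [v for v in values if not is_missing(v)]


def _numbers(values):
    out = []
    for v in _present(values):
        if isinstance(v, bool):
            out.append(1.0 if v else 0.0)
        elif _is_number(v):
            out.append(float(v))
        else:
            raise ExpressionError(f"numeric characterization got {v!r}")
    return out


def _freq(values):
    counts: dict[str, int] = {}
    for v in _present(values):
        key = str(v)
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items()))


def _histogram(values, bins=10):
    nums = _numbers(values)
    if not nums:
        return {"bin_edges": [], "counts": []}
    counts, edges = np.histogram(nums, bins=int(bins))
    return {"bin_edges": [float(e) for e in edges],
            "counts": [int(c) for c in counts]}


def _barplot(values, aux=None, label_item=None):
    labels = None
    if aux and label_item and label_item in aux:
        labels = [str(x) for x in aux[label_item]]
    if labels is None:
        labels = [str(i) for i in range(len(values))]
    return {"labels": labels,
            "heights": [None if is_missing(v) else v for v in values],
            "kind": "barplot"}


def _mean_by_variable(values, aux=None):
    """Per-variable unweighted mean, keyed by the contributing MM's path tag.

    Used by the constraint-summary measure: ``values`` are pass fractions of
    contributing check MMs and ``aux['tags']`` their tag lists; the variable
    is identified by the tag that is a dataset path.
    """
    if not aux or "tags" not in aux:
        raise ExpressionError("mean_by_variable requires a '.tags' item")
    tag_lists = aux["tags"]
    buckets: dict[str, list[float]] = {}
    for v, tags in zip(values, tag_lists):
        variable = next(
            (t for t in tags if t.startswith("dataset-row/")), "(unknown)"
        )
        if not is_missing(v):
            buckets.setdefault(variable, []).append(float(v))
    return {
        var: float(np.mean(vals)) for var, vals in sorted(buckets.items())
    }


def _sd(values):
    nums = _numbers(values)
    if len(nums) < 2:
        return MISSING
    return float(np.std(nums, ddof=1))


def _variance(values):
    nums = _numbers(values)
    if len(nums) < 2:
        return MISSING
    return float(np.var(nums, ddof=1))


def _stat(fn):
    def wrapped(values):
        nums = _numbers(values)
        return float(fn(nums)) if nums else MISSING
    return wrapped


def _extremum(fn):
    # min/max also order date/time values and ISO strings (lexicographic
    # order is chronological for ISO-8601)
    def wrapped(values):
        present = _present(values)
        if not present:
            return MISSING
        if all(isinstance(v, str) for v in present) or all(
            isinstance(v, (date, datetime)) for v in present
        ):
            return fn(present)
        return float(fn(_numbers(values)))
    return wrapped


CHARACTERIZATION_REGISTRY: dict[str, Callable] = {
    "count_present": lambda values: len(_present(values)),
    "count_total": lambda values: len(values),
    "count_missing": lambda values: sum(1 for v in values if is_missing(v)),
    "count_false": lambda values: sum(1 for v in values if v is False),
    "min": _extremum(min),
    "max": _extremum(max),
    "mean": _stat(np.mean),
    "median": _stat(np.median),
    "sd": _sd,
    "variance": _variance,
    "fraction_present": lambda values: (
        len(_present(values)) / len(values) if values else MISSING
    ),
    "frequency_table": _freq,
    "relative_frequency_table": lambda values: (
        {k: c / len(_present(values)) for k, c in _freq(values).items()}
        if _present(values) else {}
    ),
    "mean_density": lambda values: (
        float(np.mean(np.abs(np.diff(_numbers(values)))))
        if len(_numbers(values)) >= 2 else MISSING
    ),
    "histogram": _histogram,
    "barplot": _barplot,
    "mean_by_variable": _mean_by_variable,
}

# builtins that need access to the raw item vectors (labels, tags)
AUX_BUILTINS = frozenset({"barplot", "mean_by_variable"})


@dataclass(frozen=True)
class Characterization:
    builtin: str | None = None
    params: Mapping = field(default_factory=dict)
    custom: str | None = None

    def __post_init__(self):
        if (self.builtin is None) == (self.custom is None):
            raise ValueError(
                "characterization needs exactly one of builtin / custom"
            )


# ---------------------------------------------------------------------------
# The 5-tuple
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementMethod:
    tags: tuple[str, ...]
    domain_paths: tuple[DomainPath, ...]
    check: str | None
    grouping: str | None
    characterization: Characterization
    description: str | None = None
    id: str = ""

    def __post_init__(self):
        if not self.id:
            object.__setattr__(self, "id", content_id(self))

    def item_names(self) -> list[str]:
        return [dp.item_name for dp in self.domain_paths]

    def is_filter_based(self) -> bool:
        return any(
            isinstance(dp.source, MMFilterBinding) for dp in self.domain_paths
        )


def mm_to_document(mm: MeasurementMethod) -> dict:
    """Serializable document form with stable key order (diff-friendly)."""
    char: dict = {}
    if mm.characterization.builtin is not None:
        char["builtin"] = mm.characterization.builtin
        if mm.characterization.params:
            char["params"] = dict(sorted(mm.characterization.params.items()))
    else:
        char["custom"] = mm.characterization.custom
    doc = {
        "tags": list(mm.tags),
        "domain_paths": [render_domain_path(dp) for dp in mm.domain_paths],
        "check": mm.check,
        "grouping": mm.grouping,
        "characterization": char,
        "description": mm.description,
    }
    return doc


def mm_from_document(doc: Mapping) -> MeasurementMethod:
    char_doc = doc.get("characterization") or {}
    characterization = Characterization(
        builtin=char_doc.get("builtin"),
        params=dict(char_doc.get("params") or {}),
        custom=char_doc.get("custom"),
    )
    return MeasurementMethod(
        tags=tuple(doc.get("tags") or ()),
        domain_paths=tuple(
            parse_domain_path(t) for t in doc.get("domain_paths") or ()
        ),
        check=doc.get("check"),
        grouping=doc.get("grouping"),
        characterization=characterization,
        description=doc.get("description"),
    )


def content_id(mm: MeasurementMethod) -> str:
    """Stable content hash of the 5-tuple (identity across KB round-trips)."""
    char: dict = {}
    if mm.characterization.builtin is not None:
        char = {"builtin": mm.characterization.builtin,
                "params": dict(sorted(mm.characterization.params.items()))}
    else:
        char = {"custom": mm.characterization.custom}
    payload = json.dumps(
        {
            "tags": list(mm.tags),
            "domain_paths": [render_domain_path(dp) for dp in mm.domain_paths],
            "check": mm.check,
            "grouping": mm.grouping,
            "characterization": char,
            "description": mm.description,
        },
        sort_keys=True,
        ensure_ascii=False,
    )
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    code: str
    message: str


def validate_mm(mm: MeasurementMethod) -> list[ValidationIssue]:
    """All invariant violations of an MM; empty list means valid."""
    issues: list[ValidationIssue] = []
    if not mm.tags:
        issues.append(ValidationIssue("EMPTY_TAGS", "tags must be non-empty"))
    if not mm.domain_paths:
        issues.append(
            ValidationIssue("EMPTY_DOMAIN_PATHS", "domain_paths must be non-empty")
        )
    names = mm.item_names()
    if len(set(names)) != len(names):
        issues.append(ValidationIssue("DUPLICATE_ITEM", f"duplicate items {names}"))
    expected = [f"item{i}" for i in range(len(names))]
    if names and names != expected:
        issues.append(
            ValidationIssue(
                "BAD_ITEM_NUMBERING",
                f"items must be {expected}, got {names}",
            )
        )
    kinds = {type(dp.source).__name__ for dp in mm.domain_paths}
    if len(kinds) > 1:
        issues.append(
            ValidationIssue(
                "MIXED_BINDINGS",
                "domain paths must be all-dataset or all-filter",
            )
        )
    declared = set(names)
    for label, expr in (("check", mm.check), ("grouping", mm.grouping)):
        if expr is None:
            continue
        try:
            used = expression_variables(expr)
        except ExpressionError as exc:
            issues.append(ValidationIssue("BAD_EXPRESSION", f"{label}: {exc}"))
            continue
        undeclared = sorted((used - declared) - {"MISSING"})
        if undeclared:
            issues.append(
                ValidationIssue(
                    "UNDECLARED_ITEM",
                    f"{label} references undeclared {undeclared}",
                )
            )
    char = mm.characterization
    if char.builtin is not None and char.builtin not in CHARACTERIZATION_REGISTRY:
        issues.append(
            ValidationIssue("UNKNOWN_BUILTIN", f"no builtin {char.builtin!r}")
        )
    if char.custom is not None:
        try:
            used = expression_variables(char.custom)
            undeclared = sorted((used - declared) - {"MISSING"})
            if undeclared:
                issues.append(
                    ValidationIssue(
                        "UNDECLARED_ITEM",
                        f"characterization references undeclared {undeclared}",
                    )
                )
        except ExpressionError as exc:
            issues.append(
                ValidationIssue("BAD_EXPRESSION", f"characterization: {exc}")
            )
    return issues
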