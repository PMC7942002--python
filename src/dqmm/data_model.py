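"""Datasets of nested clinical records and path resolution against them.

A dataset row holds one *composition*: a finite tree of named nodes. A node
carries either a scalar payload (text, number, boolean, date/time, optionally
with a unit attribute) or an ordered list of child nodes, never both. Nodes
may be annotated with an archetype identifier or a node-id (``at0001``-style)
plus an optional human-readable name, and paths address nodes through those
annotations the way archetype-paths do in openEHR-based systems.

Values whose text form is a configured *null flavor* token (``""``, ``"NA"``,
``"ND"`` by default) are normalized to a single missing marker at load time.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MISSING",
    "Missing",
    "Node",
    "Composition",
    "DatasetRow",
    "Dataset",
    "VariableDescriptor",
    "ParsedPath",
    "PathSyntaxError",
    "DatasetFormatError",
    "AmbiguousParentError",
    "DEFAULT_MISSING_TOKENS",
    "parse_path",
    "render_path",
    "resolve_path",
    "resolve_nodes",
    "count_child_nodes",
    "load_dataset",
    "list_variables",
    "infer_reference_type",
]

DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "ND"})


class Missing:
    """Singleton marker for a missing value (any null flavor, or absence)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        return False


MISSING = Missing()


def is_missing(value) -> bool:
    return value is MISSING or value is None


class PathSyntaxError(ValueError):
    """A path string does not conform to the path dialect."""


class DatasetFormatError(ValueError):
    """Malformed dataset input (bad record, duplicate column, ...)."""


class AmbiguousParentError(ValueError):
    """countChildnodes(only_child) matched more than one parent node."""


@dataclass
class Node:
    """One element of a composition tree.

    ``value``/``unit`` form the scalar payload; ``children`` the subtree.
    Exactly one of payload / children may be populated.
    """

    name: str
    value: object = None
    unit: str | None = None
    children: list["Node"] = field(default_factory=list)
    node_id: str | None = None
    archetype_id: str | None = None
    display_name: str | None = None

    def __post_init__(self):
        if self.children and self.value is not None:
            raise ValueError(
                f"node {self.name!r} has both a payload and children"
            )

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Composition:
    """One nested record; ``root`` is a synthetic unnamed container."""

    root: Node


@dataclass
class DatasetRow:
    row_index: int
    composition: Composition
    template_id: str | None = None


@dataclass
class VariableDescriptor:
    path: str
    reference_type: str  # NUMERIC | TEXT | CODED_TEXT | DATE_TIME | BOOLEAN | COUNT
    observed_in_rows: int


@dataclass
class Dataset:
    rows: list[DatasetRow]
    variables: list[VariableDescriptor]
    missing_tokens: frozenset = DEFAULT_MISSING_TOKENS

    def __len__(self):
        return len(self.rows)

    def variable_paths(self) -> list[str]:
        return [v.path for v in self.variables]


# ---------------------------------------------------------------------------
# Path dialect
#
# Grammar:  "dataset-row/" seg ("/" seg)*  [ "." attribute ]
#                                          [ ".countChildnodes(" mode ")" ]
#   seg        := name [ "[" predicate "]" ]  |  "[" predicate "]"
#   predicate  := id [ "," "'" human-name "'" ]
#
# A bare "[...]" segment matches any node whose archetype id or node-id equals
# the predicate id (archetype roots in real compositions are addressed by the
# archetype id alone).
# ---------------------------------------------------------------------------

_SEGMENT_RE = re.compile(
    r"^(?P<name>[^\[\]/]*)"
    r"(?:\[(?P<pred>[^\]]+)\])?$"
)
_INSTR_RE = re.compile(r"\.countChildnodes\((?P<mode>[A-Za-z_]+)\)$")
_ATTRS = ("value", "magnitude", "unit")


@dataclass(frozen=True)
class PathSegment:
    name: str | None  # None for bare-[predicate] segments
    pred_id: str | None = None
    pred_name: str | None = None


@dataclass(frozen=True)
class ParsedPath:
    segments: tuple[PathSegment, ...]
    attribute: str | None = None  # trailing ".value"/".magnitude"/".unit"
    instruction: str | None = None  # countChildnodes mode, if any


def parse_path(text: str) -> ParsedPath:
    """Parse a path in the dialect; raise :class:`PathSyntaxError` if invalid."""
    if not isinstance(text, str) or not text.strip():
        raise PathSyntaxError("empty path")
    raw = text.strip()
    instruction = None
    m = _INSTR_RE.search(raw)
    if m:
        mode = m.group("mode")
        if mode not in ("only_child", "all"):
            raise PathSyntaxError(
                f"unknown countChildnodes mode {mode!r} in {text!r}"
            )
        instruction = mode
        raw = raw[: m.start()]
    attribute = None
    for attr in _ATTRS:
        suffix = "." + attr
        if raw.endswith(suffix):
            attribute = attr
            raw = raw[: -len(suffix)]
            break
    if not raw.startswith("dataset-row/"):
        raise PathSyntaxError(
            f"path must start with 'dataset-row/': {text!r}"
        )
    body = raw[len("dataset-row/"):]
    if not body:
        raise PathSyntaxError(f"path has no segments: {text!r}")
    segments = []
    for pos, part in enumerate(body.split("/")):
        m = _SEGMENT_RE.match(part)
        if m is None or (not m.group("name") and not m.group("pred")):
            raise PathSyntaxError(
                f"bad segment {part!r} at position {pos} in {text!r}"
            )
        name = m.group("name") or None
        pred_id = pred_name = None
        pred = m.group("pred")
        if pred is not None:
            if "," in pred:
                pid, _, pname = pred.partition(",")
                pname = pname.strip()
                if not (pname.startswith("'") and pname.endswith("'")):
                    raise PathSyntaxError(
                        f"predicate name must be single-quoted in {part!r}"
                    )
                pred_id, pred_name = pid.strip(), pname[1:-1]
            else:
                pred_id = pred.strip()
            if not pred_id:
                raise PathSyntaxError(f"empty predicate in {part!r}")
        segments.append(PathSegment(name, pred_id, pred_name))
    return ParsedPath(tuple(segments), attribute, instruction)


def render_path(parsed: ParsedPath) -> str:
    parts = []
    for seg in parsed.segments:
        s = seg.name or ""
        if seg.pred_id is not None:
            if seg.pred_name is not None:
                s += f"[{seg.pred_id},'{seg.pred_name}']"
            else:
                s += f"[{seg.pred_id}]"
        parts.append(s)
    out = "dataset-row/" + "/".join(parts)
    if parsed.attribute:
        out += "." + parsed.attribute
    if parsed.instruction:
        out += f".countChildnodes({parsed.instruction})"
    return out


def _segment_matches(seg: PathSegment, node: Node) -> bool:
    if seg.name is not None and node.name != seg.name:
        return False
    if seg.name is None:
        # bare [predicate]: match on archetype id or node id only
        if seg.pred_id is None:
            return False
        if node.archetype_id != seg.pred_id and node.node_id != seg.pred_id:
            return False
    elif seg.pred_id is not None:
        if node.node_id != seg.pred_id and node.archetype_id != seg.pred_id:
            return False
    if seg.pred_name is not None and node.display_name != seg.pred_name:
        return False
    return True


def resolve_nodes(row: DatasetRow, path: str | ParsedPath) -> list[Node]:
    """All nodes matched by *path* in document order (ignores attribute/instruction)."""
    parsed = parse_path(path) if isinstance(path, str) else path
    frontier = [row.composition.root]
    for seg in parsed.segments:
        nxt = []
        for node in frontier:
            for child in node.children:
                if _segment_matches(seg, child):
                    nxt.append(child)
        frontier = nxt
        if not frontier:
            return []
    return frontier


def _project(node: Node, attribute: str | None):
    if attribute == "unit":
        return node.unit if node.unit is not None else MISSING
    # "value" and "magnitude" both project the scalar payload
    return node.value if node.value is not None else MISSING


def resolve_path(row: DatasetRow, path: str | ParsedPath) -> list[object]:
    """Payloads of all nodes matched by *path*, in document order.

    Returns ``[]`` when nothing matches. A trailing attribute selector
    projects the named payload attribute; a missing payload yields
    :data:`MISSING`.
    """
    parsed = parse_path(path) if isinstance(path, str) else path
    nodes = resolve_nodes(row, parsed)
    if parsed.instruction is not None:
        raise PathSyntaxError(
            "paths with a countChildnodes instruction must be resolved via "
            "count_child_nodes"
        )
    return [_project(n, parsed.attribute) for n in nodes]


def _counts_as_child(node: Node) -> bool:
    # A leaf whose payload is the missing marker is treated as absent: the
    # cardinality rule must catch null-flavor tokens as well as absent trees.
    if node.is_leaf:
        return not is_missing(node.value)
    return True


def count_child_nodes(
    row: DatasetRow, path: str | ParsedPath, mode: str = "only_child"
) -> int:
    """Number of (non-missing) child nodes under the node(s) matched by *path*.

    ``mode="only_child"`` requires at most one matched parent and raises
    :class:`AmbiguousParentError` otherwise; ``mode="all"`` sums over all
    matched parents. An absent parent counts 0.
    """
    if mode not in ("only_child", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    parsed = parse_path(path) if isinstance(path, str) else path
    parsed = ParsedPath(parsed.segments, parsed.attribute, None)
    parents = resolve_nodes(row, parsed)
    if mode == "only_child" and len(parents) > 1:
        raise AmbiguousParentError(
            f"countChildnodes(only_child): {len(parents)} parents matched "
            f"{render_path(parsed)!r}"
        )
    return sum(
        sum(1 for c in p.children if _counts_as_child(c)) for p in parents
    )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_iso(text: str):
    for parser in (datetime.fromisoformat, date.fromisoformat):
        try:
            return parser(text)
        except (ValueError, TypeError):
            continue
    return None


def _normalize_scalar(value, missing_tokens):
    if value is None or value is MISSING:
        return MISSING
    if isinstance(value, str) and value.strip() in missing_tokens:
        return MISSING
    return value


def _node_from_json(obj: dict, missing_tokens, where: str) -> Node:
    if not isinstance(obj, dict):
        raise DatasetFormatError(f"node must be an object ({where})")
    unknown = set(obj) - {
        "name", "value", "unit", "children", "node_id", "archetype_id",
        "display_name",
    }
    if unknown:
        raise DatasetFormatError(f"unknown node keys {sorted(unknown)} ({where})")
    children = [
        _node_from_json(c, missing_tokens, where)
        for c in obj.get("children", [])
    ]
    value = obj.get("value")
    if children and value is not None:
        raise DatasetFormatError(
            f"node {obj.get('name')!r} has both value and children ({where})"
        )
    return Node(
        name=obj.get("name", ""),
        value=_normalize_scalar(value, missing_tokens) if not children else None,
        unit=obj.get("unit"),
        children=children,
        node_id=obj.get("node_id"),
        archetype_id=obj.get("archetype_id"),
        display_name=obj.get("display_name"),
    )


def node_to_json(node: Node) -> dict:
    out: dict = {"name": node.name}
    for key in ("node_id", "archetype_id", "display_name", "unit"):
        val = getattr(node, key)
        if val is not None:
            out[key] = val
    if node.children:
        out["children"] = [node_to_json(c) for c in node.children]
    else:
        out["value"] = None if node.value is MISSING else node.value
    return out


def _rows_from_nested(text: str, missing_tokens) -> list[DatasetRow]:
    rows = []
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise DatasetFormatError(f"row {i}: invalid record: {exc}") from exc
        if not isinstance(obj, dict):
            raise DatasetFormatError(f"row {i}: record must be an object")
        template_id = obj.get("template_id")
        children = [
            _node_from_json(c, missing_tokens, f"row {i}")
            for c in obj.get("children", [])
        ]
        root = Node(name="", children=children)
        rows.append(DatasetRow(len(rows), Composition(root), template_id))
    return rows


def _rows_from_flat(text: str, missing_tokens) -> list[DatasetRow]:
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        return []
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DatasetFormatError(f"duplicate column header(s): {dupes}")
    parsed_cols = []
    for col in header:
        try:
            parsed_cols.append(parse_path(col))
        except PathSyntaxError as exc:
            raise DatasetFormatError(f"column header is not a valid path: {exc}")
    rows = []
    for i, record in enumerate(reader):
        if len(record) != len(header):
            raise DatasetFormatError(
                f"row {i}: expected {len(header)} fields, got {len(record)}"
            )
        root = Node(name="")
        for parsed, cell in zip(parsed_cols, record):
            value = _normalize_scalar(cell, missing_tokens)
            if isinstance(value, str) and _NUM_RE.match(value.strip()):
                value = float(value)
            _insert_leaf(root, parsed, value)
        rows.append(DatasetRow(len(rows), Composition(root)))
    return rows


def _insert_leaf(root: Node, parsed: ParsedPath, value):
    node = root
    *parents, leaf = parsed.segments
    for seg in parents:
        for child in node.children:
            if _segment_matches(seg, child):
                node = child
                break
        else:
            child = Node(
                name=seg.name or "",
                node_id=seg.pred_id if seg.name else None,
                archetype_id=seg.pred_id if seg.name is None else None,
                display_name=seg.pred_name,
            )
            node.children.append(child)
            node = child
    node.children.append(
        Node(
            name=leaf.name or "",
            value=value,
            node_id=leaf.pred_id if leaf.name else None,
            archetype_id=leaf.pred_id if leaf.name is None else None,
            display_name=leaf.pred_name,
        )
    )


def _leaf_paths(node: Node, prefix: list[str]) -> Iterable[tuple[str, object]]:
    for child in node.children:
        seg = child.name
        if child.node_id is not None:
            if child.display_name is not None:
                seg += f"[{child.node_id},'{child.display_name}']"
            else:
                seg += f"[{child.node_id}]"
        elif child.archetype_id is not None:
            seg += f"[{child.archetype_id}]"
        here = prefix + [seg]
        if child.is_leaf:
            yield "dataset-row/" + "/".join(here), child.value
        else:
            yield from _leaf_paths(child, here)


def infer_reference_type(values: Sequence[object]) -> str:
    """Infer a reference-model type from observed non-missing values.

    Declared schema types take precedence upstream; this rule covers bare
    files: NUMERIC if everything parses as a number, DATE_TIME if ISO-8601,
    BOOLEAN for true/false, CODED_TEXT up to 50 distinct values, else TEXT.
    """
    observed = [v for v in values if not is_missing(v)]
    if not observed:
        return "TEXT"
    if all(isinstance(v, bool) for v in observed):
        return "BOOLEAN"
    if all(
        isinstance(v, (int, float)) and not isinstance(v, bool)
        or (isinstance(v, str) and _NUM_RE.match(v.strip()))
        for v in observed
    ):
        return "NUMERIC"
    if all(isinstance(v, (datetime, date)) for v in observed) or all(
        isinstance(v, str) and _parse_iso(v) is not None for v in observed
    ):
        return "DATE_TIME"
    if all(
        isinstance(v, str) and v.strip().lower() in ("true", "false")
        for v in observed
    ):
        return "BOOLEAN"
    texts = {str(v) for v in observed}
    return "CODED_TEXT" if len(texts) <= 50 else "TEXT"


def _discover_variables(rows: list[DatasetRow]) -> list[VariableDescriptor]:
    values_by_path: dict[str, list] = {}
    rows_by_path: dict[str, set] = {}
    for row in rows:
        for path, value in _leaf_paths(row.composition.root, []):
            values_by_path.setdefault(path, []).append(value)
            rows_by_path.setdefault(path, set()).add(row.row_index)
    return [
        VariableDescriptor(
            path=path,
            reference_type=infer_reference_type(values_by_path[path]),
            observed_in_rows=len(rows_by_path[path]),
        )
        for path in sorted(values_by_path)
    ]


def load_dataset(
    source,
    format: str = "nested-records",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> Dataset:
    """Load a dataset from a file path, stream, or literal text.

    ``format`` is ``"nested-records"`` (newline-delimited JSON compositions)
    or ``"flat-table"`` (CSV whose header row holds leaf paths).
    """
    if format not in ("nested-records", "flat-table"):
        raise ValueError(f"unknown format {format!r}")
    tokens = frozenset(missing_tokens)
    if hasattr(source, "read"):
        text = source.read()
    elif "\n" in str(source) or str(source).strip().startswith("{"):
        text = str(source)
    else:
        p = Path(str(source))
        if not p.exists():
            raise FileNotFoundError(source)
        text = p.read_text(encoding="utf-8")
    if format == "nested-records":
        rows = _rows_from_nested(text, tokens)
    else:
        rows = _rows_from_flat(text, tokens)
    return Dataset(rows=rows, variables=_discover_variables(rows),
                   missing_tokens=tokens)


def list_variables(dataset: Dataset) -> list[VariableDescriptor]:
    """Variables of the dataset, ordered lexicographically by path."""
    return list(dataset.variables)


def dump_dataset(dataset: Dataset, format: str = "nested-records") -> str:
    """Serialize a dataset back to text in either supported format.

    Flat-table output covers leaf paths only and keeps the first value per
    path and row (the nested format is lossless).
    """
    if format == "nested-records":
        lines = []
        for row in dataset.rows:
            obj: dict = {}
            if row.template_id is not None:
                obj["template_id"] = row.template_id
            obj["children"] = [
                node_to_json(c) for c in row.composition.root.children
            ]
            lines.append(json.dumps(obj, ensure_ascii=False, sort_keys=False))
        return "\n".join(lines) + ("\n" if lines else "")
    if format == "flat-table":
        paths = [v.path for v in dataset.variables]
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(paths)
        parsed = [parse_path(p) for p in paths]
        for row in dataset.rows:
            record = []
            for p in parsed:
                values = resolve_path(row, p)
                v = values[0] if values else MISSING
                record.append("" if is_missing(v) else v)
            writer.writerow(record)
        return buf.getvalue()
    raise ValueError(f"unknown format {format!r}")
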