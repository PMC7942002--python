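"""Synthetic datasets with known ground-truth data-quality properties.

Real multi-site clinical datasets are access-restricted, so every stage of
the toolchain is exercised against generated fixtures that emulate one: per
row a site name, a patient identifier, coded categoricals (German gender
codes), numeric lab values with units, and date variables — with
configurable per-variable missingness (including non-standard null-flavor
tokens such as ``"ND"``) and per-constraint violation rates.

Missingness and violations are independent Bernoulli draws per cell; a cell
is never both (missing wins), which keeps completeness and correctness
measures separable in the ground truth. The seed fully determines the
output: the emitted dataset text is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import numpy as np

from .data_model import (
    Dataset,
    load_dataset,
    parse_path,
)
from .generator import ConstraintSchema, SchemaError, VariableConstraint

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_dataset",
    "make_study_fixture",
    "make_study_spec",
    "SITE_PATH",
    "PATIENT_PATH",
]

SITE_PATH = "dataset-row/composition/context/health_care_facility/name"
PATIENT_PATH = "dataset-row/composition/context/patient_id/id"

DEFAULT_NULL_FLAVORS: dict[str, float] = {"NA": 0.6, "ND": 0.3, "": 0.1}


@dataclass
class FixtureSpec:
    schema: ConstraintSchema
    n_rows: int = 200
    n_sites: int = 2
    n_patients: int = 100
    missing_rate: float | Mapping[str, float] = 0.0
    violation_rate: float | Mapping[str, float] = 0.0
    null_flavor_tokens: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NULL_FLAVORS)
    )
    seed: int = 0

    def rate(self, which: str, path: str) -> float:
        raw = getattr(self, which)
        rate = raw.get(path, 0.0) if isinstance(raw, Mapping) else float(raw)
        if not 0.0 <= rate <= 1.0:
            raise SchemaError(f"{which} for {path} must be in [0,1]: {rate}")
        return rate


@dataclass
class GroundTruth:
    """Injected per-cell statuses and their realized counts."""

    statuses: dict  # (row_index, path) -> "ok" | "missing" | "violated:<kind>"
    missing_counts: dict  # path -> int
    violation_counts: dict  # (path, kind) -> int
    n_rows: int = 0

    def record(self, row: int, path: str, status: str):
        self.statuses[(row, path)] = status
        if status == "missing":
            self.missing_counts[path] = self.missing_counts.get(path, 0) + 1
        elif status.startswith("violated:"):
            kind = status.split(":", 1)[1]
            key = (path, kind)
            self.violation_counts[key] = self.violation_counts.get(key, 0) + 1


def _violation_kind(var: VariableConstraint) -> str | None:
    if var.mandatory or var.occurrence is not None:
        return "cardinality"
    if var.unit_ranges or var.range is not None:
        return "range"
    if var.value_set is not None:
        return "value_set"
    if var.pattern is not None:
        return "pattern"
    return None


def _clean_value(var: VariableConstraint, rng: np.random.Generator):
    """Draw a value inside the variable's constraints."""
    if var.unit_ranges:
        units = sorted(var.unit_ranges)
        unit = units[int(rng.integers(len(units)))]
        lo, hi = var.unit_ranges[unit]
        return round(float(rng.uniform(lo, hi)), 3), unit
    if var.range is not None:
        lo, hi = var.range
        return round(float(rng.uniform(lo, hi)), 3), None
    if var.value_set:
        return str(var.value_set[int(rng.integers(len(var.value_set)))]), None
    if var.reference_type == "DATE_TIME":
        start = date(2018, 1, 1)
        return (start + timedelta(days=int(rng.integers(0, 1461)))).isoformat(), None
    if var.reference_type in ("NUMERIC", "COUNT"):
        return round(float(rng.uniform(0.0, 100.0)), 3), None
    if var.pattern is not None:
        return f"P{int(rng.integers(10000)):04d}", None
    return f"text_{int(rng.integers(1000))}", None


def _violating_value(var: VariableConstraint, unit: str | None,
                     rng: np.random.Generator):
    kind = _violation_kind(var)
    if kind == "range":
        if var.unit_ranges:
            lo, hi = var.unit_ranges[unit]
        else:
            lo, hi = var.range
        # above the admissible band, clearly out of range
        return round(hi + 1.0 + float(rng.uniform(0.0, hi - lo + 1.0)), 3)
    if kind == "value_set":
        return f"INVALID_{int(rng.integers(1000)):03d}"
    if kind == "pattern":
        return f"bad value {int(rng.integers(1000))}"
    raise SchemaError(f"no violating value for constraint kind {kind!r}")


def _draw_token(tokens: Mapping[str, float], rng: np.random.Generator) -> str:
    names = sorted(tokens)
    weights = np.array([tokens[n] for n in names], dtype=float)
    weights = weights / weights.sum()
    return names[int(rng.choice(len(names), p=weights))]


def _insert(tree: dict, path: str, value, unit=None):
    """Insert a leaf into the nested-JSON row under construction."""
    parsed = parse_path(path)
    node = tree
    *parents, leaf = parsed.segments
    for seg in parents:
        children = node.setdefault("children", [])
        for child in children:
            if child.get("name") == (seg.name or ""):
                node = child
                break
        else:
            child = {"name": seg.name or ""}
            if seg.pred_id and seg.name:
                child["node_id"] = seg.pred_id
            children.append(child)
            node = child
    leaf_obj: dict = {"name": leaf.name or ""}
    if leaf.pred_id and leaf.name:
        leaf_obj["node_id"] = leaf.pred_id
    leaf_obj["value"] = value
    if unit is not None:
        leaf_obj["unit"] = unit
    node.setdefault("children", []).append(leaf_obj)


def generate_dataset(spec: FixtureSpec) -> tuple[Dataset, GroundTruth]:
    """Generate a dataset and its ground truth; deterministic given the seed.

    Clean values are drawn inside each variable's constraints, then each cell
    is independently flipped to missing (a null-flavor token, or an absent
    subtree for cardinality-constrained variables) or to a violating value.
    """
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema
    unit_companions = {
        v.unit_path for v in schema.variables if v.unit_path is not None
    }
    truth = GroundTruth({}, {}, {}, n_rows=spec.n_rows)
    sites = [f"Site{chr(65 + i)}" for i in range(spec.n_sites)]
    lines = []
    for i in range(spec.n_rows):
        tree: dict = {}
        site = sites[int(rng.integers(spec.n_sites))]
        patient = f"P{int(rng.integers(spec.n_patients)):04d}"
        pending_units: dict[str, str] = {}
        for var in schema.variables:
            if var.path in unit_companions:
                continue  # written alongside its measured variable
            if var.path == SITE_PATH:
                value, unit = site, None
            elif var.path == PATIENT_PATH:
                value, unit = patient, None
            else:
                value, unit = _clean_value(var, rng)
            status = "ok"
            m_rate = spec.rate("missing_rate", var.path)
            v_rate = spec.rate("violation_rate", var.path)
            kind = _violation_kind(var)
            if m_rate and rng.random() < m_rate:
                status = "missing"
            elif v_rate and rng.random() < v_rate:
                if kind is None:
                    raise SchemaError(
                        f"{var.path}: violation requested but no constraint"
                    )
                status = f"violated:{kind}"
            truth.record(i, var.path, status)
            if status == "missing":
                _insert(tree, var.path,
                        _draw_token(spec.null_flavor_tokens, rng))
            elif status == "violated:cardinality":
                pass  # absent mandatory subtree: leaf not written at all
            elif status.startswith("violated:"):
                _insert(tree, var.path, _violating_value(var, unit, rng))
            else:
                _insert(tree, var.path, value)
            if var.unit_path is not None and status != "violated:cardinality":
                _insert(tree, var.unit_path, unit)
                truth.record(i, var.unit_path, "ok")
        lines.append(json.dumps(tree, ensure_ascii=False))
    text = "\n".join(lines) + "\n"
    dataset = load_dataset(
        text, format="nested-records",
        missing_tokens=set(spec.null_flavor_tokens) | {""},
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# The transplant-study-like fixture
# ---------------------------------------------------------------------------

GENDER_PATH = "dataset-row/composition/content/gender/sex_at_birth"
RECIPIENT_AGE_PATH = "dataset-row/composition/content/recipient_age/value"
DONOR_AGE_PATH = "dataset-row/composition/content/donor_age/value"
WEIGHT_PATH = "dataset-row/composition/content/body_weight/weight_value"
WEIGHT_UNIT_PATH = "dataset-row/composition/content/body_weight/weight_unit"
TRANSPLANT_DATE_PATH = (
    "dataset-row/composition/content/transplantation/date_of_transplant"
)
BIOPSY_DATE_PATH = "dataset-row/composition/content/biopsy/date_of_biopsy"
MONTHS_SINCE_PATH = (
    "dataset-row/composition/content/followup/months_since_transplant"
)

GENDER_CODES = ("Weiblich", "Männlich", "Divers")


def make_study_spec(
    seed: int = 0,
    n_rows: int = 200,
    missing_rate: float | Mapping[str, float] = 0.0,
    violation_rate: float | Mapping[str, float] = 0.0,
) -> FixtureSpec:
    """Fixture spec emulating a two-site kidney-transplant study dataset:
    recipient/donor age, gender codes, transplant and biopsy dates, a weight
    variable with kg/g unit-conditional ranges, a mandatory facility name."""
    schema = ConstraintSchema(
        schema_id="transplant-study",
        variables=(
            VariableConstraint(SITE_PATH, "CODED_TEXT", mandatory=True),
            VariableConstraint(PATIENT_PATH, "TEXT", pattern=r"^P\d{4}$"),
            VariableConstraint(GENDER_PATH, "CODED_TEXT",
                               value_set=GENDER_CODES),
            VariableConstraint(RECIPIENT_AGE_PATH, "NUMERIC",
                               range=(18.0, 90.0)),
            VariableConstraint(DONOR_AGE_PATH, "NUMERIC", range=(0.0, 99.0)),
            VariableConstraint(
                WEIGHT_PATH, "NUMERIC",
                unit_ranges={"kg": (0.0, 1000.0), "g": (0.0, 1000000.0)},
                unit_path=WEIGHT_UNIT_PATH,
            ),
            VariableConstraint(WEIGHT_UNIT_PATH, "CODED_TEXT"),
            VariableConstraint(TRANSPLANT_DATE_PATH, "DATE_TIME"),
            VariableConstraint(BIOPSY_DATE_PATH, "DATE_TIME"),
            VariableConstraint(MONTHS_SINCE_PATH, "NUMERIC",
                               range=(0.0, 120.0)),
        ),
    )
    return FixtureSpec(
        schema=schema,
        n_rows=n_rows,
        n_sites=2,
        n_patients=max(1, n_rows // 2),
        missing_rate=missing_rate,
        violation_rate=violation_rate,
        seed=seed,
    )


def make_study_fixture(seed: int = 0, **kwargs) -> tuple[Dataset, ConstraintSchema]:
    """Small clean two-site study dataset plus its constraint schema."""
    spec = make_study_spec(seed=seed, **kwargs)
    dataset, _ = generate_dataset(spec)
    return dataset, spec.schema
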