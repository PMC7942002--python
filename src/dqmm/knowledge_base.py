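"""Portable knowledge bases: MM compilations on disk.

A knowledge base is a directory of one-MM-per-file YAML documents plus a
manifest carrying name, description, free-text task/domain tags, a format
version and a content hash per file. Field order in the documents is stable
and export is byte-deterministic, so knowledge bases diff and merge cleanly
under external version control; no VCS operations are performed here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .data_model import Dataset, parse_path, resolve_nodes
from .mm_model import (
    DatasetBinding,
    MeasurementMethod,
    mm_from_document,
    mm_to_document,
    validate_mm,
)

__all__ = [
    "FORMAT_VERSION",
    "KnowledgeBase",
    "KBError",
    "KBIntegrityError",
    "KBVersionError",
    "export_kb",
    "import_kb",
    "bind_kb_to_dataset",
    "BindingReport",
]

FORMAT_VERSION = "1"
MANIFEST_NAME = "manifest.yaml"


class KBError(ValueError):
    pass


class KBIntegrityError(KBError):
    """A file's content hash does not match the manifest."""


class KBVersionError(KBError):
    """Unknown knowledge-base format version."""


@dataclass
class KnowledgeBase:
    name: str
    description: str = ""
    tags: tuple[str, ...] = ()
    mms: tuple[MeasurementMethod, ...] = ()


def _mm_bytes(mm: MeasurementMethod) -> bytes:
    doc = mm_to_document(mm)
    return yaml.safe_dump(
        doc, sort_keys=False, allow_unicode=True, default_flow_style=False
    ).encode("utf-8")


def export_kb(
    mms: Sequence[MeasurementMethod],
    destination,
    name: str = "knowledge-base",
    description: str = "",
    tags: Sequence[str] = (),
) -> Path:
    """Write a knowledge base; deterministic bytes for identical input."""
    for mm in mms:
        issues = validate_mm(mm)
        if issues:
            raise KBError(
                f"MM {mm.id} invalid, not exported: "
                f"{[i.code for i in issues]}"
            )
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    files = {}
    for mm in sorted(mms, key=lambda m: m.id):
        data = _mm_bytes(mm)
        fname = f"{mm.id}.yaml"
        (dest / fname).write_bytes(data)
        files[fname] = hashlib.sha256(data).hexdigest()
    manifest = {
        "format_version": FORMAT_VERSION,
        "name": name,
        "description": description,
        "tags": list(tags),
        "files": dict(sorted(files.items())),
    }
    (dest / MANIFEST_NAME).write_bytes(
        yaml.safe_dump(manifest, sort_keys=False, allow_unicode=True).encode()
    )
    return dest


def import_kb(source) -> list[MeasurementMethod]:
    """Load a knowledge base, verifying the manifest and file hashes."""
    src = Path(source)
    manifest_path = src / MANIFEST_NAME
    if not manifest_path.exists():
        raise KBError(f"no {MANIFEST_NAME} in {src}")
    manifest = yaml.safe_load(manifest_path.read_text(encoding="utf-8"))
    version = str(manifest.get("format_version"))
    if version != FORMAT_VERSION:
        raise KBVersionError(
            f"unknown format version {version!r} (expected {FORMAT_VERSION})"
        )
    mms = []
    for fname, expected_hash in sorted((manifest.get("files") or {}).items()):
        fpath = src / fname
        if not fpath.exists():
            raise KBIntegrityError(f"missing MM file {fname}")
        data = fpath.read_bytes()
        actual = hashlib.sha256(data).hexdigest()
        if actual != expected_hash:
            raise KBIntegrityError(
                f"hash mismatch for {fname}: manifest {expected_hash[:12]}…, "
                f"file {actual[:12]}…"
            )
        mms.append(mm_from_document(yaml.safe_load(data.decode("utf-8"))))
    return mms


def load_kb(source) -> KnowledgeBase:
    manifest = yaml.safe_load(
        (Path(source) / MANIFEST_NAME).read_text(encoding="utf-8")
    )
    return KnowledgeBase(
        name=manifest.get("name", ""),
        description=manifest.get("description", ""),
        tags=tuple(manifest.get("tags") or ()),
        mms=tuple(import_kb(source)),
    )


@dataclass
class BindingReport:
    applicable: list[MeasurementMethod] = field(default_factory=list)
    unmatched: list[tuple[MeasurementMethod, list[str]]] = field(
        default_factory=list
    )


def bind_kb_to_dataset(
    mms: Sequence[MeasurementMethod], dataset: Dataset
) -> BindingReport:
    """Split MMs into applicable / unmatched against a concrete dataset.

    An MM is applicable iff every dataset-binding path resolves to at least
    one node in at least one row, or the MM is filter-only (multi-layered MMs
    bind to other MMs' results, not to the dataset). Sharing archetype-paths
    is what lets one knowledge base run against datasets from different
    templates or sites without modification.
    """
    report = BindingReport()
    for mm in mms:
        missing_paths = []
        for dp in mm.domain_paths:
            if not isinstance(dp.source, DatasetBinding):
                continue
            parsed = parse_path(dp.source.path)
            if dp.source.instruction is not None:
                from .data_model import ParsedPath

                parsed = ParsedPath(parsed.segments, parsed.attribute, None)
            if not any(
                resolve_nodes(row, parsed) for row in dataset.rows
            ):
                missing_paths.append(dp.source.path)
        if missing_paths:
            report.unmatched.append((mm, missing_paths))
        else:
            report.applicable.append(mm)
    return report
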