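"""Three harmonized data-quality measures expressed as measurement methods.

* **RepresentationComplete** — fraction of non-missing entries per variable
  (denominator: dataset row count; an absent subtree counts as missing).
* **TaskComplete** — number of missing values in mandatory variables,
  detected through the countChildnodes cardinality pattern so both absent
  subtrees and null-flavor tokens are counted.
* **TDConstraints** — a multi-layered MM that summarizes all constraint-check
  MMs: per variable the unweighted mean of its contributing checks' pass
  fractions. Because it selects inputs by tag filter, the same MM applies
  unchanged to check MMs derived from any constraint schema.

The three measures are summarized into a per-variable heatmap: cells in
[0, 1], white where a measure is not applicable to a variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import VariableDescriptor
from .executor import ALL_GROUP, MMResult
from .generator import ConstraintSchema, parent_path
from .mm_model import (
    Characterization,
    DatasetBinding,
    DomainPath,
    MeasurementMethod,
    MMFilterBinding,
)

__all__ = [
    "MEASURE_NAMES",
    "HeatmapTable",
    "build_representation_complete",
    "build_task_complete",
    "build_td_constraints",
    "build_hdqf_mms",
    "build_heatmap",
    "render_heatmap",
]

MEASURE_NAMES = ("RepresentationComplete", "TaskComplete", "TDConstraints")

NOT_APPLICABLE = float("nan")


def build_representation_complete(
    variables: Sequence[VariableDescriptor | str],
) -> list[MeasurementMethod]:
    """One MM per variable returning its fraction of non-missing entries."""
    mms = []
    for var in variables:
        path = var if isinstance(var, str) else var.path
        mms.append(
            MeasurementMethod(
                tags=("hdqf", "representation_complete", path),
                domain_paths=(
                    DomainPath("item0", "text", DatasetBinding(path)),
                ),
                check=None,
                grouping=None,
                characterization=Characterization(builtin="fraction_present"),
                description=f"fraction of non-missing entries in {path}",
            )
        )
    return mms


def build_task_complete(schema: ConstraintSchema) -> list[MeasurementMethod]:
    """One MM per mandatory variable counting rows with the value missing."""
    mms = []
    for var in schema.variables:
        if not var.mandatory:
            continue
        container = parent_path(var.path)
        mms.append(
            MeasurementMethod(
                tags=("hdqf", "task_complete", var.path),
                domain_paths=(
                    DomainPath(
                        "item0", "numeric",
                        DatasetBinding(
                            container + ".countChildnodes(only_child)",
                            "only_child",
                        ),
                    ),
                ),
                check="item0 >= 1",
                grouping=None,
                characterization=Characterization(builtin="count_false"),
                description=(
                    f"count of rows missing the mandatory value {var.path}"
                ),
            )
        )
    return mms


def build_td_constraints() -> MeasurementMethod:
    """The constraint-summary MM over all ungrouped check MMs.

    Selects every executed MM tagged ``check`` (excluding ``per_*`` dimension
    variants), pairs each pass fraction with its source MM's tags, and
    averages per variable path.
    """
    flt = "has_tag('check') and lacks_tag('per_*')"
    return MeasurementMethod(
        tags=("hdqf", "td_constraints"),
        domain_paths=(
            DomainPath("item0", "numeric",
                       MMFilterBinding(flt, "resultsValue")),
            DomainPath("item1", "text", MMFilterBinding(flt, "tags")),
        ),
        check=None,
        grouping=None,
        characterization=Characterization(builtin="mean_by_variable"),
        description=(
            "per-variable mean pass fraction over all constraint checks"
        ),
    )


def build_hdqf_mms(
    variables: Sequence[VariableDescriptor | str], schema: ConstraintSchema
) -> list[MeasurementMethod]:
    """The full HDQF MM compilation for a dataset + schema."""
    return (
        build_representation_complete(variables)
        + build_task_complete(schema)
        + [build_td_constraints()]
    )


@dataclass
class HeatmapTable:
    """Per-variable summary of the three measures.

    ``values`` holds the [0, 1] goodness scores used for coloring (NaN =
    not applicable); ``task_complete_counts`` retains the raw missing counts.
    """

    values: pd.DataFrame  # index: variable name, columns: MEASURE_NAMES
    task_complete_counts: pd.Series
    contributing: dict  # (variable, measure) -> mm_id


def build_heatmap(
    results: Mapping[str, MMResult],
    variable_name_map: Mapping[str, str] | None = None,
    n_rows: int | None = None,
) -> HeatmapTable:
    """Assemble the heatmap table from executed HDQF MM results.

    ``variable_name_map`` maps domain paths to short display names;
    ``n_rows`` (dataset row count) normalizes TaskComplete counts into a
    [0, 1] goodness score ``1 - missing/n_rows`` for coloring.
    """
    name_map = dict(variable_name_map or {})
    rep: dict[str, float] = {}
    task: dict[str, float] = {}
    td: dict[str, float] = {}
    contributing: dict = {}
    for r in results.values():
        if r.failed or "hdqf" not in r.tags:
            continue
        if "representation_complete" in r.tags:
            path = next(t for t in r.tags if t.startswith("dataset-row/"))
            rep[path] = float(r.value(ALL_GROUP))
            contributing[(path, "RepresentationComplete")] = r.mm_id
        elif "task_complete" in r.tags:
            path = next(t for t in r.tags if t.startswith("dataset-row/"))
            task[path] = float(r.value(ALL_GROUP))
            contributing[(path, "TaskComplete")] = r.mm_id
            if n_rows is None and r.n_input_rows:
                n_rows = r.n_input_rows
        elif "td_constraints" in r.tags:
            table = r.value(ALL_GROUP)
            for path, mean_pass in table.items():
                td[path] = float(mean_pass)
                contributing[(path, "TDConstraints")] = r.mm_id
    paths = sorted(set(rep) | set(task) | set(td))
    rows = []
    counts = []
    for path in paths:
        rep_v = rep.get(path, NOT_APPLICABLE)
        raw_task = task.get(path, NOT_APPLICABLE)
        if not np.isnan(raw_task) and n_rows:
            task_v = 1.0 - raw_task / n_rows
        else:
            task_v = NOT_APPLICABLE
        rows.append((rep_v, task_v, td.get(path, NOT_APPLICABLE)))
        counts.append(raw_task)
    names = [name_map.get(p, p) for p in paths]
    values = pd.DataFrame(rows, index=names, columns=list(MEASURE_NAMES))
    return HeatmapTable(
        values=values,
        task_complete_counts=pd.Series(counts, index=names, dtype=float),
        contributing={
            (name_map.get(p, p), m): mid
            for (p, m), mid in contributing.items()
        },
    )


def render_heatmap(table: HeatmapTable, path=None):
    """Render the heatmap; green = 1.0, yellow ~ 0.8, red = 0.0, white = n/a."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "dq", [(0.0, "#c0392b"), (0.8, "#f1c40f"), (1.0, "#27ae60")]
    )
    cmap.set_bad("white")
    data = table.values.to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(6, max(2.0, 0.4 * len(table.values) + 1.5))
    )
    im = ax.imshow(np.ma.masked_invalid(data), cmap=cmap, vmin=0.0, vmax=1.0,
                   aspect="auto")
    ax.set_xticks(range(len(table.values.columns)))
    ax.set_xticklabels(table.values.columns, rotation=30, ha="right")
    ax.set_yticks(range(len(table.values.index)))
    ax.set_yticklabels(table.values.index)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            if not np.isnan(data[i, j]):
                ax.text(j, i, f"{data[i, j]:.2f}", ha="center", va="center",
                        fontsize=8)
    fig.colorbar(im, ax=ax, label="DQ score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
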