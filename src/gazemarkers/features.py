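"""Participant-level feature table.

Each trial-level biomarker is expanded across task type and target
eccentricity while trials sharing a (task, eccentricity) cell — the two
sides x two orders, up to 4 trials — are averaged.  A metric applicable
to all three tasks therefore contributes 9 columns (e.g. ``P7_N_Fix`` ...
``D20_N_Fix``); summing over the catalog yields exactly 183 feature
columns.  Boolean biomarkers average into incidence proportions.

Column order is deterministic: metrics in catalog order, then task
(P, A, D), then eccentricity (7, 15, 20).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .biomarkers import METRIC_CATALOG, MetricDef
from .geometry import ECCENTRICITIES_DEG, TASK_CODES

LABEL_COLUMN = "label"  # ADHD = 1, TD = 0
ATTRIBUTE_COLUMNS = ["sex", "age", "age_group"]


def column_name(metric: str, task: str, eccentricity: int) -> str:
    return f"{TASK_CODES[task]}{eccentricity}_{metric}"


def expand_variable_names(
    catalog: tuple[MetricDef, ...] = METRIC_CATALOG,
) -> list[str]:
    """Ordered feature-column names; 183 for the standard catalog."""
    names: list[str] = []
    for metric in catalog:
        for task in ("prosaccade", "antisaccade", "delayed"):
            if task not in metric.tasks:
                continue
            for ecc in ECCENTRICITIES_DEG:
                names.append(column_name(metric.name, task, ecc))
    return names


def column_schema(catalog: tuple[MetricDef, ...] = METRIC_CATALOG) -> pd.DataFrame:
    """Provenance sidecar: one row per feature column."""
    rows = []
    for metric in catalog:
        for task in ("prosaccade", "antisaccade", "delayed"):
            if task not in metric.tasks:
                continue
            for ecc in ECCENTRICITIES_DEG:
                rows.append(
                    {
                        "column": column_name(metric.name, task, ecc),
                        "metric": metric.name,
                        "category": metric.category,
                        "task": task,
                        "eccentricity_deg": ecc,
                        "boolean": metric.boolean,
                    }
                )
    return pd.DataFrame(rows)


def aggregate_participant(trial_rows: pd.DataFrame) -> pd.Series:
    """Collapse one participant's trial biomarkers into a feature row.

    ``trial_rows`` must carry ``task`` and ``eccentricity_deg`` attribute
    columns plus biomarker columns.  Cell values are means over available
    (non-NaN) trials; a cell with no usable trials yields NaN.
    """
    if len(trial_rows) == 0:
        raise ValueError("participant has zero trials")
    names = expand_variable_names()
    out = pd.Series(np.nan, index=names, dtype=float)
    grouped = trial_rows.groupby(["task", "eccentricity_deg"], sort=False)
    for (task, ecc), cell in grouped:
        for metric in METRIC_CATALOG:
            if task not in metric.tasks or metric.name not in cell.columns:
                continue
            vals = cell[metric.name].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                out[column_name(metric.name, task, int(ecc))] = float(vals.mean())
    return out


def build_feature_table(
    trial_table: pd.DataFrame,
    participants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Feature table from a per-trial biomarker table.

    ``trial_table`` needs a ``participant_id`` column alongside the trial
    attributes and biomarkers.  ``participants`` (optional) is indexed or
    keyed by ``participant_id`` and contributes label/sex/age columns.
    """
    rows = {}
    for pid, block in trial_table.groupby("participant_id", sort=False):
        rows[pid] = aggregate_participant(block)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "participant_id"
    if participants is not None:
        meta = participants.set_index("participant_id") \
            if "participant_id" in participants.columns else participants
        keep = [c for c in [LABEL_COLUMN, *ATTRIBUTE_COLUMNS] if c in meta.columns]
        table = table.join(meta[keep])
    return table


def feature_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table into (X features, y labels)."""
    names = [c for c in expand_variable_names() if c in table.columns]
    y = table[LABEL_COLUMN].to_numpy(dtype=int)
    return table[names], y


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    table.to_csv(path)
    column_schema().to_csv(path.with_suffix(".schema.csv"), index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")
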