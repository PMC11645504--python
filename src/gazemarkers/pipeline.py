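"""End-to-end orchestration: raw gaze -> trials -> biomarkers -> features.

Ties the modules together for the two common entry points: extracting a
per-trial biomarker table from gaze + marker data, and running the whole
chain on a synthetic cohort without materializing it on disk.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarkers import compute_trial_biomarkers
from .features import build_feature_table
from .gaze_io import IVTConfig, segment_trials, validity_fraction, include_participant
from .geometry import ScreenConfig, build_aois, entropy_partition_for
from .synthetic import CohortConfig, PhenotypeParams, TD_PRESET, ADHD_PRESET, iter_cohort

TRIAL_ATTRIBUTE_COLUMNS = [
    "participant_id",
    "trial_id",
    "task",
    "eccentricity_deg",
    "side",
    "order",
]


def extract_trial_table(
    gaze: pd.DataFrame,
    markers: pd.DataFrame,
    screen: ScreenConfig | None = None,
    ivt: IVTConfig | None = None,
) -> pd.DataFrame:
    """Per-trial biomarker table from a gaze stream and its trial markers."""
    screen = screen or ScreenConfig()
    records = segment_trials(gaze, markers, screen, ivt)
    partitions = {
        task: entropy_partition_for(task, screen)
        for task in ("prosaccade", "antisaccade", "delayed")
    }
    rows = []
    for rec in records:
        aois = build_aois(rec.spec, screen)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = compute_trial_biomarkers(rec, aois, partitions[rec.spec.task])
        rows.append(
            {
                "participant_id": rec.participant_id,
                "trial_id": rec.trial_id,
                "task": rec.spec.task,
                "eccentricity_deg": rec.spec.eccentricity_deg,
                "side": rec.spec.side,
                "order": rec.spec.order,
                **metrics,
            }
        )
    return pd.DataFrame(rows)


def screen_participants(gaze: pd.DataFrame, threshold: float = 0.8) -> list[str]:
    """Participant ids passing the >80%-valid-data inclusion rule."""
    keep = []
    for pid, block in gaze.groupby("participant_id", sort=False):
        if include_participant(validity_fraction(block), threshold):
            keep.append(pid)
    return keep


def extract_features(
    gaze: pd.DataFrame,
    markers: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    screen: ScreenConfig | None = None,
    ivt: IVTConfig | None = None,
    validity_threshold: float = 0.8,
) -> pd.DataFrame:
    """Gaze + markers (+ roster) -> participant-level feature table."""
    keep = set(screen_participants(gaze, validity_threshold))
    gaze = gaze[gaze["participant_id"].isin(keep)]
    markers = markers[markers["participant_id"].isin(keep)]
    trial_table = extract_trial_table(gaze, markers, screen, ivt)
    return build_feature_table(trial_table, participants)


def synthetic_feature_table(
    config: CohortConfig | None = None,
    td: PhenotypeParams = TD_PRESET,
    adhd: PhenotypeParams = ADHD_PRESET,
    return_trials: bool = False,
):
    """Generate a synthetic cohort and run the full extraction chain.

    Processes one participant at a time so memory stays flat at any
    sampling rate.  Returns the labeled feature table (and optionally the
    per-trial biomarker table).
    """
    config = config or CohortConfig()
    screen = ScreenConfig(sampling_rate_hz=config.sampling_rate_hz)
    roster_rows = []
    trial_blocks = []
    for row, gaze, markers, _ in iter_cohort(config, td, adhd, screen):
        if not include_participant(validity_fraction(gaze)):
            continue
        roster_rows.append(row)
        trial_blocks.append(extract_trial_table(gaze, markers, screen))
    roster = pd.DataFrame(roster_rows)
    trial_table = pd.concat(trial_blocks, ignore_index=True)
    table = build_feature_table(trial_table, roster)
    if return_trials:
        return table, trial_table
    return table


def extract_features_from_files(
    gaze_path: str | Path,
    marker_path: str | Path,
    participants_path: str | Path | None = None,
    screen: ScreenConfig | None = None,
) -> pd.DataFrame:
    from .gaze_io import read_gaze_file, read_marker_file

    gaze = read_gaze_file(gaze_path)
    markers = read_marker_file(marker_path)
    participants = (
        pd.read_csv(participants_path, dtype={"participant_id": str})
        if participants_path
        else None
    )
    return extract_features(gaze, markers, participants, screen)
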