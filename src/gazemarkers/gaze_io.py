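"""Raw gaze-stream I/O, validity screening, I-VT event detection, segmentation.

The on-disk dialect is plain UTF-8 CSV.  Gaze files carry one row per
sample::

    participant_id,trial_id,timestamp_ms,gaze_x_px,gaze_y_px,
    pupil_left_mm,pupil_right_mm,valid_left,valid_right

Marker files carry one row per trial::

    participant_id,trial_id,task,eccentricity_deg,side,order,onset_ms

Missing gaze/pupil fields are empty cells and parse to NaN, never zeros.
Timestamps are milliseconds on the recording clock; per-trial times are
re-expressed relative to the trial's onset marker during segmentation.

Event detection re-implements the velocity-threshold (I-VT) classifier:
samples whose angular gaze velocity exceeds a threshold are saccade
samples, the rest fixation samples; contiguous runs become events.  The
study relied on vendor software for this step; the defaults here (30 deg/s
threshold, 60 ms minimum fixation, 75 ms gap-fill) are the vendor's
published filter defaults, and everything is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ScreenConfig, TrialSpec

GAZE_COLUMNS = [
    "participant_id",
    "trial_id",
    "timestamp_ms",
    "gaze_x_px",
    "gaze_y_px",
    "pupil_left_mm",
    "pupil_right_mm",
    "valid_left",
    "valid_right",
]

MARKER_COLUMNS = [
    "participant_id",
    "trial_id",
    "task",
    "eccentricity_deg",
    "side",
    "order",
    "onset_ms",
]


class GazeFormatError(ValueError):
    """Malformed gaze or marker file."""


def read_gaze_file(path: str | Path) -> pd.DataFrame:
    """Read a gaze CSV into a DataFrame, validating the dialect.

    Raises :class:`GazeFormatError` on unknown/missing columns, an empty
    file, or timestamps that decrease within a participant-trial block
    (the error message carries the first offending line number).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError as exc:
        raise GazeFormatError(f"{path}: empty gaze file") from exc
    if list(df.columns) != GAZE_COLUMNS:
        raise GazeFormatError(
            f"{path}: expected columns {GAZE_COLUMNS}, found {list(df.columns)}"
        )
    if len(df) == 0:
        raise GazeFormatError(f"{path}: gaze file has a header but no samples")
    df["valid_left"] = df["valid_left"].astype(bool)
    df["valid_right"] = df["valid_right"].astype(bool)
    for key, block in df.groupby(["participant_id", "trial_id"], sort=False):
        t = block["timestamp_ms"].to_numpy()
        bad = np.nonzero(np.diff(t) < 0)[0]
        if bad.size:
            line = block.index[bad[0] + 1] + 2  # +1 diff offset, +1 header line
            raise GazeFormatError(
                f"{path}: nonmonotone timestamp at line {line} (trial {key})"
            )
    return df


def write_gaze_file(df: pd.DataFrame, path: str | Path) -> None:
    """Write samples in the canonical dialect (round-trips with the reader)."""
    out = df[GAZE_COLUMNS].copy()
    out["valid_left"] = out["valid_left"].astype(int)
    out["valid_right"] = out["valid_right"].astype(int)
    out.to_csv(path, index=False, float_format="%.6g")


def read_marker_file(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError as exc:
        raise GazeFormatError(f"{path}: empty marker file") from exc
    if list(df.columns) != MARKER_COLUMNS:
        raise GazeFormatError(
            f"{path}: expected columns {MARKER_COLUMNS}, found {list(df.columns)}"
        )
    return df


def write_marker_file(df: pd.DataFrame, path: str | Path) -> None:
    df[MARKER_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def validity_fraction(samples: pd.DataFrame) -> float:
    """Fraction of samples with at least one valid eye."""
    if len(samples) == 0:
        raise ValueError("validity fraction of an empty stream is undefined")
    ok = samples["valid_left"].to_numpy() | samples["valid_right"].to_numpy()
    return float(np.mean(ok))


def include_participant(fraction: float, threshold: float = 0.8) -> bool:
    """Inclusion rule: strictly more than 80% valid samples."""
    return fraction > threshold


@dataclass(frozen=True)
class IVTConfig:
    """Velocity-threshold classifier settings."""

    velocity_threshold_deg_s: float = 30.0
    min_fixation_ms: float = 60.0
    max_gap_ms: float = 75.0
    smooth_window: int = 3  # moving-average width on angular position


@dataclass
class FixationEvent:
    t_start: float
    t_end: float
    x: float
    y: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SaccadeEvent:
    t_start: float
    t_end: float
    amplitude_deg: float
    mean_velocity: float
    peak_velocity: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _smooth(a: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or a.size < w:
        return a
    kernel = np.ones(w) / w
    out = np.convolve(a, kernel, mode="same")
    # Undo edge shrinkage from zero-padding.
    norm = np.convolve(np.ones_like(a), kernel, mode="same")
    return out / norm


def detect_events(
    samples: pd.DataFrame,
    screen: ScreenConfig,
    config: IVTConfig | None = None,
) -> tuple[list[FixationEvent], list[SaccadeEvent]]:
    """Classify a (single-trial) sample stream into fixations and saccades.

    Angular position is the tangent-model visual angle of the gaze point;
    velocity is a central difference on the 3-sample-smoothed position.
    Invalid samples inside an event are bridged when the surrounding gap is
    at most ``max_gap_ms``; longer gaps split events.  Fixations shorter
    than ``min_fixation_ms`` are discarded.
    """
    config = config or IVTConfig()
    valid = (
        (samples["valid_left"].to_numpy() | samples["valid_right"].to_numpy())
        & samples["gaze_x_px"].notna().to_numpy()
        & samples["gaze_y_px"].notna().to_numpy()
    )
    if valid.sum() < 2:
        warnings.warn("fewer than 2 valid samples; no events detected", stacklevel=2)
        return [], []

    t = samples["timestamp_ms"].to_numpy(dtype=float)[valid]
    x = samples["gaze_x_px"].to_numpy(dtype=float)[valid]
    y = samples["gaze_y_px"].to_numpy(dtype=float)[valid]

    # Split the valid stream into contiguous segments at long temporal gaps.
    gap_split = np.nonzero(np.diff(t) > config.max_gap_ms)[0] + 1
    fixations: list[FixationEvent] = []
    saccades: list[SaccadeEvent] = []
    for seg in np.split(np.arange(t.size), gap_split):
        if seg.size < 2:
            continue
        _classify_segment(
            t[seg], x[seg], y[seg], screen, config, fixations, saccades
        )
    fixations.sort(key=lambda e: e.t_start)
    saccades.sort(key=lambda e: e.t_start)
    return fixations, saccades


def _classify_segment(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    screen: ScreenConfig,
    config: IVTConfig,
    fixations: list[FixationEvent],
    saccades: list[SaccadeEvent],
) -> None:
    ax = np.asarray(screen.px_to_deg_x(_smooth(x, config.smooth_window)))
    ay = np.asarray(screen.px_to_deg_y(_smooth(y, config.smooth_window)))

    n = t.size
    vel = np.zeros(n)
    if n >= 3:
        dt = t[2:] - t[:-2]
        dist = np.hypot(ax[2:] - ax[:-2], ay[2:] - ay[:-2])
        vel[1:-1] = 1000.0 * dist / np.maximum(dt, 1e-9)
    # Endpoints: one-sided difference.
    vel[0] = 1000.0 * np.hypot(ax[1] - ax[0], ay[1] - ay[0]) / max(t[1] - t[0], 1e-9)
    vel[-1] = 1000.0 * np.hypot(ax[-1] - ax[-2], ay[-1] - ay[-2]) / max(
        t[-1] - t[-2], 1e-9
    )

    is_sac = vel > config.velocity_threshold_deg_s
    # Runs of identical labels become candidate events.
    change = np.nonzero(np.diff(is_sac.astype(int)))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        t0, t1 = t[s], t[e - 1]
        if is_sac[s]:
            amp = float(np.hypot(ax[e - 1] - ax[s], ay[e - 1] - ay[s]))
            v = vel[s:e]
            saccades.append(
                SaccadeEvent(
                    t_start=float(t0),
                    t_end=float(t1),
                    amplitude_deg=amp,
                    mean_velocity=float(np.mean(v)),
                    peak_velocity=float(np.max(v)),
                )
            )
        else:
            if t1 - t0 < config.min_fixation_ms:
                continue
            fixations.append(
                FixationEvent(
                    t_start=float(t0),
                    t_end=float(t1),
                    x=float(np.mean(x[s:e])),
                    y=float(np.mean(y[s:e])),
                )
            )


@dataclass
class TrialRecord:
    """One trial of one participant: spec, samples, and detected events.

    Sample timestamps and event times are relative to the trial onset
    (``t = 0`` at fixation-cross onset).
    """

    participant_id: str
    trial_id: int
    spec: TrialSpec
    samples: pd.DataFrame
    fixations: list[FixationEvent] = field(default_factory=list)
    saccades: list[SaccadeEvent] = field(default_factory=list)
    group: str = "unknown"  # ADHD | TD | unknown
    complete: bool = True

    @property
    def duration_ms(self) -> float:
        if len(self.samples) == 0:
            return 0.0
        t = self.samples["timestamp_ms"].to_numpy()
        return float(t[-1] - t[0])


def segment_trials(
    gaze: pd.DataFrame,
    markers: pd.DataFrame,
    screen: ScreenConfig,
    ivt: IVTConfig | None = None,
    detect: bool = True,
) -> list[TrialRecord]:
    """Cut a gaze stream into TrialRecords using the marker table.

    Samples are matched by ``(participant_id, trial_id)``; timestamps are
    shifted so the marker's ``onset_ms`` becomes 0.  Trials with no samples
    are flagged incomplete.  Events are detected per trial, so an event
    always belongs to the trial containing its start.
    """
    markers = markers.sort_values(["participant_id", "onset_ms"], kind="stable")
    last_t = gaze.groupby(["participant_id", "trial_id"])["timestamp_ms"].max()
    for pid, block in markers.groupby("participant_id", sort=False):
        onsets = block["onset_ms"].to_numpy()
        trial_ids = block["trial_id"].to_numpy()
        for i in range(len(block) - 1):
            end_i = last_t.get((pid, trial_ids[i]), -np.inf)
            if end_i > onsets[i + 1]:
                raise GazeFormatError(
                    f"overlapping markers for {pid}: trial {trial_ids[i]} samples "
                    f"extend past the onset of trial {trial_ids[i + 1]}"
                )

    grouped = dict(tuple(gaze.groupby(["participant_id", "trial_id"], sort=False)))
    records: list[TrialRecord] = []
    for row in markers.itertuples(index=False):
        spec = TrialSpec(
            task=row.task,
            eccentricity_deg=int(row.eccentricity_deg),
            side=row.side,
            order=int(row.order),
        )
        block = grouped.get((row.participant_id, row.trial_id))
        if block is None or len(block) == 0:
            records.append(
                TrialRecord(
                    participant_id=row.participant_id,
                    trial_id=int(row.trial_id),
                    spec=spec,
                    samples=pd.DataFrame(columns=GAZE_COLUMNS),
                    complete=False,
                )
            )
            continue
        block = block.copy()
        block["timestamp_ms"] = block["timestamp_ms"] - float(row.onset_ms)
        rec = TrialRecord(
            participant_id=row.participant_id,
            trial_id=int(row.trial_id),
            spec=spec,
            samples=block.reset_index(drop=True),
        )
        if detect:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec.fixations, rec.saccades = detect_events(rec.samples, screen, ivt)
        records.append(rec)
    return records
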