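"""Physical setup, trial timelines, and screen-area partitions.

The paradigm presents three horizontal-saccade tasks (prosaccade,
antisaccade, delayed saccade) on a fixed screen viewed from a fixed
distance.  Everything downstream — fixation hit-testing, area-based
biomarkers, entropy grids — reduces to rectangle geometry defined here.

Coordinate convention: 0-based pixels, origin at the top-left corner,
x increasing rightward, y increasing downward.  All rectangles are
half-open, ``[x0, x1) x [y0, y1)``, so a point on a shared edge belongs
to the rectangle on its right/below and hit-testing is unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Task = Literal["prosaccade", "antisaccade", "delayed"]
Side = Literal["left", "right"]

#: Short codes used in feature-column names.
TASK_CODES: dict[str, str] = {"prosaccade": "P", "antisaccade": "A", "delayed": "D"}
ECCENTRICITIES_DEG: tuple[int, int, int] = (7, 15, 20)

#: Timeline anchors shared by all tasks (ms from trial start).
CROSS_ONSET_MS = 0.0
STIMULUS_ONSET_MS = 1500.0
#: Delayed task only: auditory go-cue 1000 ms after the stimulus.
CUE_ONSET_MS = 2500.0
#: Delayed trials end a fixed 3000 ms after the cue.
DELAYED_TRIAL_END_MS = CUE_ONSET_MS + 3000.0
#: Dwell required inside the target square to complete a pro/antisaccade trial.
DWELL_COMPLETE_MS = 300.0

#: Physical stimulus / center square edge, cm.
AOI_EDGE_CM = 5.0


class InvalidGeometryError(ValueError):
    """Raised when a requested stimulus layout cannot fit the screen."""


@dataclass(frozen=True)
class ScreenConfig:
    """Monitor geometry and recording rate.

    Defaults describe a 24-inch 16:9 panel (53.14 x 29.89 cm) at
    1920 x 1080 px viewed from 65 cm, sampled at 1200 Hz.
    """

    resolution_px: tuple[int, int] = (1920, 1080)
    physical_size_cm: tuple[float, float] = (53.14, 29.89)
    viewing_distance_cm: float = 65.0
    sampling_rate_hz: float = 1200.0

    def __post_init__(self) -> None:
        if min(self.resolution_px) <= 0 or min(self.physical_size_cm) <= 0:
            raise InvalidGeometryError("screen dimensions must be positive")
        if self.viewing_distance_cm <= 0 or self.sampling_rate_hz <= 0:
            raise InvalidGeometryError("distance and sampling rate must be positive")
        # A sane monitor has (near-)square pixels; tolerate 1% anisotropy.
        if abs(self.px_per_cm_x / self.px_per_cm_y - 1.0) > 0.01:
            raise InvalidGeometryError("pixel aspect ratio deviates more than 1%")

    @property
    def px_per_cm_x(self) -> float:
        return self.resolution_px[0] / self.physical_size_cm[0]

    @property
    def px_per_cm_y(self) -> float:
        return self.resolution_px[1] / self.physical_size_cm[1]

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.resolution_px[0] / 2.0, self.resolution_px[1] / 2.0)

    def px_to_deg_x(self, x_px: np.ndarray | float) -> np.ndarray | float:
        """Horizontal visual angle (deg) of a pixel column, relative to center."""
        cm = (np.asarray(x_px, dtype=float) - self.center_px[0]) / self.px_per_cm_x
        return np.degrees(np.arctan2(cm, self.viewing_distance_cm))

    def px_to_deg_y(self, y_px: np.ndarray | float) -> np.ndarray | float:
        cm = (np.asarray(y_px, dtype=float) - self.center_px[1]) / self.px_per_cm_y
        return np.degrees(np.arctan2(cm, self.viewing_distance_cm))


def eccentricity_to_px(eccentricity_deg: float, screen: ScreenConfig) -> float:
    """Horizontal pixel offset of a stimulus placed ``eccentricity_deg`` from center.

    Uses the flat-screen tangent model: ``offset_cm = d * tan(theta)`` at the
    configured viewing distance, converted with the horizontal pixel density.
    """
    if not 0.0 <= eccentricity_deg < 90.0:
        raise InvalidGeometryError(
            f"eccentricity must be in [0, 90) deg, got {eccentricity_deg}"
        )
    offset_cm = screen.viewing_distance_cm * math.tan(math.radians(eccentricity_deg))
    return offset_cm * screen.px_per_cm_x


@dataclass(frozen=True)
class TrialSpec:
    """One paradigm trial: task, stimulus placement, and timeline anchors."""

    task: Task
    eccentricity_deg: int
    side: Side
    order: int = 1
    trial_end_ms: float | None = None  # None: pro/anti end on completion/timeout

    def __post_init__(self) -> None:
        if self.task not in TASK_CODES:
            raise ValueError(f"unknown task {self.task!r}")
        if self.eccentricity_deg not in ECCENTRICITIES_DEG:
            raise ValueError(f"eccentricity must be one of {ECCENTRICITIES_DEG}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")

    @property
    def stimulus_onset_ms(self) -> float:
        return STIMULUS_ONSET_MS

    @property
    def cue_onset_ms(self) -> float | None:
        return CUE_ONSET_MS if self.task == "delayed" else None

    @property
    def response_onset_ms(self) -> float:
        """Earliest moment a saccade toward the target is permitted."""
        return CUE_ONSET_MS if self.task == "delayed" else STIMULUS_ONSET_MS

    @property
    def end_ms(self) -> float | None:
        if self.task == "delayed":
            return DELAYED_TRIAL_END_MS
        return self.trial_end_ms


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle [x0, x1) x [y0, y1) in pixels."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    @property
    def width(self) -> float:
        return self.x1 - self.x0


def _square(cx: float, cy: float, edge_px: float) -> Rect:
    h = edge_px / 2.0
    return Rect(cx - h, cy - h, cx + h, cy + h)


# Delayed-task time windows (ms from trial start), half-open.
INTRUSIVE_WINDOW = (0.0, STIMULUS_ONSET_MS)
WRONG_PERIOD = (STIMULUS_ONSET_MS, CUE_ONSET_MS)
PROPER_PERIOD = (CUE_ONSET_MS, DELAYED_TRIAL_END_MS)


@dataclass(frozen=True)
class AOISet:
    """Screen-area partition for one trial.

    Areas: CA (center), SA (stimulus), TA (target), UA (unrelated) for every
    task, plus PSA (proper-side) and WSA (wrong-side) in the antisaccade
    task.  SA and TA coincide for prosaccade and delayed trials; in the
    antisaccade task TA mirrors SA across the vertical screen midline.

    The horizontal stimulus band (height = one AOI edge, centered on the
    stimulus axis through screen center) carries all the task-relevant
    areas; everything outside the band is UA.  Within the band, space not
    covered by a square belongs to PSA/WSA (antisaccade) or UA (otherwise).
    """

    task: Task
    ca: Rect
    sa: Rect
    ta: Rect
    band: Rect
    psa: Rect | None = None
    wsa: Rect | None = None

    @property
    def ta_edge_px(self) -> float:
        return self.ta.width

    def label(self, x: float, y: float) -> str:
        """Area label of an on-screen point; every pixel gets exactly one."""
        if not self.band.contains(x, y):
            return "UA"
        if self.ca.contains(x, y):
            return "CA"
        if self.ta.contains(x, y):
            return "TA"
        if self.task == "antisaccade":
            if self.sa.contains(x, y):
                return "SA"
            assert self.psa is not None and self.wsa is not None
            if self.psa.contains(x, y):
                return "PSA"
            if self.wsa.contains(x, y):
                return "WSA"
        return "UA"


def build_aois(spec: TrialSpec, screen: ScreenConfig) -> AOISet:
    """Construct the area partition for one trial.

    Raises :class:`InvalidGeometryError` if the stimulus square would
    extend off-screen.
    """
    w, h = screen.resolution_px
    cx, cy = screen.center_px
    edge = AOI_EDGE_CM * screen.px_per_cm_x
    offset = eccentricity_to_px(spec.eccentricity_deg, screen)
    sign = 1.0 if spec.side == "right" else -1.0

    sa = _square(cx + sign * offset, cy, edge)
    if sa.x0 < 0 or sa.x1 > w or sa.y0 < 0 or sa.y1 > h:
        raise InvalidGeometryError(
            f"{spec.eccentricity_deg} deg stimulus square extends off-screen"
        )
    ca = _square(cx, cy, edge)
    band = Rect(0.0, cy - edge / 2.0, float(w), cy + edge / 2.0)

    if spec.task == "antisaccade":
        ta = _square(cx - sign * offset, cy, edge)
        # Proper side = target side of the band; wrong side = stimulus side.
        if spec.side == "right":  # target on the left
            psa = Rect(0.0, band.y0, ca.x0, band.y1)
            wsa = Rect(ca.x1, band.y0, float(w), band.y1)
        else:
            psa = Rect(ca.x1, band.y0, float(w), band.y1)
            wsa = Rect(0.0, band.y0, ca.x0, band.y1)
        return AOISet(task=spec.task, ca=ca, sa=sa, ta=ta, band=band, psa=psa, wsa=wsa)
    return AOISet(task=spec.task, ca=ca, sa=sa, ta=sa, band=band)


def delayed_period(t_start_ms: float) -> str:
    """Time-window label of a delayed-trial fixation from its start time."""
    if t_start_ms < 0:
        raise ValueError("fixation start time must be nonnegative")
    if t_start_ms < INTRUSIVE_WINDOW[1]:
        return "intrusive-window"
    if t_start_ms < WRONG_PERIOD[1]:
        return "wrong-period"
    return "proper-period"


def classify_point(
    x: float, y: float, t_start_ms: float, aois: AOISet
) -> tuple[str, str | None]:
    """Label a fixation centroid with its area and, for delayed trials, period."""
    label = aois.label(x, y)
    period = delayed_period(t_start_ms) if aois.task == "delayed" else None
    return label, period


@dataclass(frozen=True)
class EntropyPartition:
    """Regular grid tiling the screen for gaze-entropy state spaces.

    6 cells (3 x 2) for prosaccade/delayed, 8 (4 x 2) for antisaccade.
    """

    n_cols: int
    n_rows: int
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    @property
    def n_areas(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def h_max_bits(self) -> float:
        return math.log2(self.n_areas)

    def area_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cell index of each point; off-screen points clamp to the edge cell."""
        w, h = self.screen.resolution_px
        col = np.clip((np.asarray(x) * self.n_cols / w).astype(int), 0, self.n_cols - 1)
        row = np.clip((np.asarray(y) * self.n_rows / h).astype(int), 0, self.n_rows - 1)
        return row * self.n_cols + col


def entropy_partition_for(task: Task, screen: ScreenConfig | None = None) -> EntropyPartition:
    screen = screen or ScreenConfig()
    if task == "antisaccade":
        return EntropyPartition(n_cols=4, n_rows=2, screen=screen)
    return EntropyPartition(n_cols=3, n_rows=2, screen=screen)


def standard_trial_specs(rng: np.random.Generator | None = None) -> list[TrialSpec]:
    """The 36 formal trials of a full assessment: 12 per task, 2 per position.

    Within each task the 6 positions x 2 repetitions are shuffled when an
    ``rng`` is supplied; the ``order`` attribute records the first/second
    occurrence of each position.
    """
    specs: list[TrialSpec] = []
    for task in ("prosaccade", "antisaccade", "delayed"):
        cells = [(e, s) for e in ECCENTRICITIES_DEG for s in ("left", "right")]
        sequence = cells * 2
        if rng is not None:
            perm = rng.permutation(len(sequence))
            sequence = [sequence[i] for i in perm]
        seen: dict[tuple[int, str], int] = {}
        for ecc, side in sequence:
            seen[(ecc, side)] = seen.get((ecc, side), 0) + 1
            specs.append(
                TrialSpec(task=task, eccentricity_deg=ecc, side=side, order=seen[(ecc, side)])
            )
    return specs
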