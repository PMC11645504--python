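"""Per-trial digital biomarkers.

28 metric definitions in five categories:

* general (8): fixation/saccade counts and durations, trial duration,
  saccade velocity (mean, peak) and amplitude;
* pupil-based (4): mean/max/min/SD of the cleaned pupil trace
  (computed in :mod:`gazemarkers.pupil`);
* area-based (11): hit/latency/count metrics over the screen-area
  partition, with per-period variants for the delayed task;
* search-based (3): runs of near-target fixations in the antisaccade
  task, capturing difficulty localizing the mirror landing point;
* entropy-based (2): normalized stationary gaze entropy (spatial
  dispersion of fixations) and gaze transition entropy (randomness of
  area-to-area transitions) over a regular screen grid.

Not every metric applies to every task; ``applicable_metrics`` encodes
the applicability and ``compute_trial_biomarkers`` returns only the
applicable subset for a trial.  Booleans are stored as 0/1 so that
participant-level averaging turns them into incidences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    AOISet,
    EntropyPartition,
    TrialSpec,
    classify_point,
    entropy_partition_for,
)
from .gaze_io import FixationEvent, SaccadeEvent, TrialRecord
from .pupil import PupilMetrics, trial_pupil_metrics

SEARCH_RADIUS_FACTOR = 1.5
SEARCH_MIN_RUN = 2


@dataclass(frozen=True)
class MetricDef:
    name: str
    category: str  # general | pupil | area | search | entropy
    tasks: tuple[str, ...]
    boolean: bool = False


_ALL = ("prosaccade", "antisaccade", "delayed")
_PA = ("prosaccade", "antisaccade")
_A = ("antisaccade",)
_D = ("delayed",)

#: The full biomarker catalog, in canonical (reporting) order.
METRIC_CATALOG: tuple[MetricDef, ...] = (
    # general
    MetricDef("N_Fix", "general", _ALL),
    MetricDef("N_Sac", "general", _ALL),
    MetricDef("T_Total", "general", _ALL),
    MetricDef("T_Fix_Avg", "general", _ALL),
    MetricDef("T_Sac_Avg", "general", _ALL),
    MetricDef("V_Sac_Avg", "general", _ALL),
    MetricDef("V_Sac_Peak", "general", _ALL),
    MetricDef("A_Sac_Avg", "general", _ALL),
    # pupil-based
    MetricDef("D_Pupil_Avg", "pupil", _ALL),
    MetricDef("D_Pupil_Max", "pupil", _ALL),
    MetricDef("D_Pupil_Min", "pupil", _ALL),
    MetricDef("D_Pupil_Sd", "pupil", _ALL),
    # area-based
    MetricDef("B_TA_Fix", "area", _ALL, boolean=True),
    MetricDef("L_TA_Fix", "area", _ALL),
    MetricDef("N_UA_Fix", "area", _PA),
    MetricDef("N_TA_Fix", "area", _D),
    MetricDef("N_TA-P_Fix", "area", _D),
    MetricDef("N_TA-W_Fix", "area", _D),
    MetricDef("N_SA_Fix", "area", _A),
    MetricDef("B_PSA_Fix", "area", _A, boolean=True),
    MetricDef("B_WSA_Fix", "area", _A, boolean=True),
    MetricDef("B_PSA_Fix_1st", "area", _A, boolean=True),
    MetricDef("B_Intrusive_Sac", "area", _D, boolean=True),
    # search-based
    MetricDef("B_Search", "search", _A, boolean=True),
    MetricDef("N_Search", "search", _A),
    MetricDef("T_Search", "search", _A),
    # entropy-based
    MetricDef("SGE_norm", "entropy", _ALL),
    MetricDef("GTE_norm", "entropy", _ALL),
)

CATEGORY_COUNTS = {"general": 8, "pupil": 4, "area": 11, "search": 3, "entropy": 2}


def applicable_metrics(task: str) -> list[MetricDef]:
    return [m for m in METRIC_CATALOG if task in m.tasks]


def general_metrics(
    fixations: list[FixationEvent],
    saccades: list[SaccadeEvent],
    duration_ms: float,
) -> dict[str, float]:
    out: dict[str, float] = {
        "N_Fix": float(len(fixations)),
        "N_Sac": float(len(saccades)),
        "T_Total": float(duration_ms),
        "T_Fix_Avg": np.nan,
        "T_Sac_Avg": np.nan,
        "V_Sac_Avg": np.nan,
        "V_Sac_Peak": np.nan,
        "A_Sac_Avg": np.nan,
    }
    if fixations:
        out["T_Fix_Avg"] = float(np.mean([f.duration for f in fixations]))
    if saccades:
        out["T_Sac_Avg"] = float(np.mean([s.duration for s in saccades]))
        out["V_Sac_Avg"] = float(np.mean([s.mean_velocity for s in saccades]))
        out["V_Sac_Peak"] = float(np.max([s.peak_velocity for s in saccades]))
        out["A_Sac_Avg"] = float(np.mean([s.amplitude_deg for s in saccades]))
    return out


def _labels(
    fixations: list[FixationEvent], aois: AOISet
) -> list[tuple[str, str | None]]:
    return [classify_point(f.x, f.y, f.t_start, aois) for f in fixations]


def area_metrics(
    fixations: list[FixationEvent], aois: AOISet, spec: TrialSpec
) -> dict[str, float]:
    """Area-based metrics applicable to the trial's task.

    Fixation latency ``L_TA_Fix`` is measured from the earliest permitted
    response: stimulus onset for pro/antisaccade, the auditory cue for
    delayed trials (where only proper-period target fixations count).
    """
    labels = _labels(fixations, aois)
    task = spec.task
    out: dict[str, float] = {}

    if task == "delayed":
        ta_hits = [
            (f, per)
            for f, (lab, per) in zip(fixations, labels)
            if lab == "TA"
        ]
        proper = [f for f, per in ta_hits if per == "proper-period"]
        wrong = [f for f, per in ta_hits if per == "wrong-period"]
        out["B_TA_Fix"] = float(bool(proper))
        out["L_TA_Fix"] = (
            proper[0].t_start - spec.response_onset_ms if proper else np.nan
        )
        out["N_TA_Fix"] = float(len(ta_hits))
        out["N_TA-P_Fix"] = float(len(proper))
        out["N_TA-W_Fix"] = float(len(wrong))
        out["B_Intrusive_Sac"] = float(
            any(
                lab != "CA" and per == "intrusive-window"
                for (lab, per) in labels
            )
        )
        return out

    ta_fixes = [f for f, (lab, _) in zip(fixations, labels) if lab == "TA"]
    out["B_TA_Fix"] = float(bool(ta_fixes))
    out["L_TA_Fix"] = (
        ta_fixes[0].t_start - spec.response_onset_ms if ta_fixes else np.nan
    )
    out["N_UA_Fix"] = float(sum(lab == "UA" for lab, _ in labels))

    if task == "antisaccade":
        out["N_SA_Fix"] = float(sum(lab == "SA" for lab, _ in labels))
        out["B_PSA_Fix"] = float(any(lab == "PSA" for lab, _ in labels))
        out["B_WSA_Fix"] = float(any(lab == "WSA" for lab, _ in labels))
        # First post-stimulus fixation outside the center area.
        first = next(
            (
                lab
                for f, (lab, _) in zip(fixations, labels)
                if f.t_start >= spec.stimulus_onset_ms and lab != "CA"
            ),
            None,
        )
        out["B_PSA_Fix_1st"] = float(first == "PSA")
    return out


@dataclass(frozen=True)
class SearchEvent:
    """A run of >=2 consecutive fixations near but outside the target square."""

    start_index: int
    n_fixations: int
    duration_ms: float


def detect_search(
    fixations: list[FixationEvent], aois: AOISet
) -> tuple[dict[str, float], list[SearchEvent]]:
    """Search behavior: maximal runs of >=2 consecutive fixations that land
    outside the TA square but within 1.5 x (TA edge) of the TA center."""
    cx, cy = aois.ta.center
    radius = SEARCH_RADIUS_FACTOR * aois.ta_edge_px
    marked = [
        (not aois.ta.contains(f.x, f.y))
        and math.hypot(f.x - cx, f.y - cy) <= radius
        for f in fixations
    ]
    events: list[SearchEvent] = []
    i = 0
    while i < len(marked):
        if marked[i]:
            j = i
            while j < len(marked) and marked[j]:
                j += 1
            if j - i >= SEARCH_MIN_RUN:
                dur = sum(f.duration for f in fixations[i:j])
                events.append(SearchEvent(i, j - i, dur))
            i = j
        else:
            i += 1
    metrics = {
        "B_Search": float(bool(events)),
        "N_Search": float(len(events)),
        "T_Search": float(sum(e.duration_ms for e in events)),
    }
    return metrics, events


def gaze_entropy(
    fixations: list[FixationEvent],
    partition: EntropyPartition,
    count_self_transitions: bool = True,
) -> tuple[float, float]:
    """Normalized stationary and transition gaze entropy.

    SGE = -sum_i p_i log2 p_i over the empirical fixation distribution
    across grid cells; GTE = -sum_i p_i sum_j p(j|i) log2 p(j|i) with
    p(j|i) the first-order transition probabilities of the chronological
    fixation sequence and p_i the same stationary distribution as SGE.
    Both are divided by log2(n areas).  0 * log 0 is taken as 0.
    """
    if not fixations:
        return np.nan, np.nan
    x = np.array([f.x for f in fixations])
    y = np.array([f.y for f in fixations])
    areas = partition.area_of(x, y)
    n = partition.n_areas
    h_max = partition.h_max_bits

    counts = np.bincount(areas, minlength=n).astype(float)
    p = counts / counts.sum()
    nz = p > 0
    sge = float(-(p[nz] * np.log2(p[nz])).sum())

    trans = np.zeros((n, n))
    for a, b in zip(areas[:-1], areas[1:]):
        if a == b and not count_self_transitions:
            continue
        trans[a, b] += 1
    gte = 0.0
    row_sums = trans.sum(axis=1)
    for i in range(n):
        if row_sums[i] == 0 or p[i] == 0:
            continue
        cond = trans[i] / row_sums[i]
        cz = cond > 0
        gte += p[i] * float(-(cond[cz] * np.log2(cond[cz])).sum())
    return sge / h_max + 0.0, gte / h_max + 0.0  # +0.0 normalizes -0.0


def compute_trial_biomarkers(
    trial: TrialRecord,
    aois: AOISet,
    partition: EntropyPartition | None = None,
    pupil: PupilMetrics | None = None,
) -> dict[str, float]:
    """Assemble the applicable biomarker subset for one trial."""
    spec = trial.spec
    if partition is None:
        partition = entropy_partition_for(spec.task)
    out = general_metrics(trial.fixations, trial.saccades, trial.duration_ms)

    if pupil is None:
        pupil = trial_pupil_metrics(trial.samples) if len(trial.samples) else \
            PupilMetrics(np.nan, np.nan, np.nan, np.nan)
    out["D_Pupil_Avg"] = pupil.avg
    out["D_Pupil_Max"] = pupil.max
    out["D_Pupil_Min"] = pupil.min
    out["D_Pupil_Sd"] = pupil.sd

    out.update(area_metrics(trial.fixations, aois, spec))
    if spec.task == "antisaccade":
        search, _ = detect_search(trial.fixations, aois)
        out.update(search)
    sge, gte = gaze_entropy(trial.fixations, partition)
    out["SGE_norm"] = sge
    out["GTE_norm"] = gte

    # Skipped / non-completed trials keep their recorded data; B_TA_Fix
    # already reflects whether the target was ever fixated.
    allowed = {m.name for m in applicable_metrics(spec.task)}
    return {k: v for k, v in out.items() if k in allowed}
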