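"""Synthetic gaze recordings for the three saccade tasks.

No recordings were deposited by the study this pipeline reproduces, so
every stage is exercised end-to-end on generated data.  The generator
scripts each trial as a sequence of intended fixations (center hold,
optional unrelated-area excursions, direction errors, search runs,
intrusive saccades, the target landing) joined by minimum-jerk saccades
whose peak velocity is a phenotype parameter, then renders the script
into noisy raw samples at a configurable rate with a binocular pupil
trace (baseline + slow drift + noise + occasional artifact spikes and
blinks).  A ground-truth log of every intended event is returned for
oracle testing.

Two presets describe a typically-developing-like and an ADHD-like
phenotype.  Their separations are directional — longer latency, lower
completion, more unrelated/search/intrusive fixations, slower saccades,
larger pupil variability, more dispersed fixation targets for the
ADHD-like preset — not calibrated to any published magnitudes.

Phenotype latency is defined as the interval from the go signal
(stimulus onset, or auditory cue in the delayed task) to the onset of
the first target fixation, which is exactly what the extracted
``L_TA_Fix`` biomarker measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .geometry import (
    AOISet,
    Rect,
    ScreenConfig,
    TrialSpec,
    build_aois,
    standard_trial_specs,
)
from .gaze_io import GAZE_COLUMNS, MARKER_COLUMNS

#: Pro/antisaccade trials time out this long after stimulus onset if the
#: target is never held; delayed trials always end 3000 ms after the cue.
PRO_ANTI_TIMEOUT_MS = 3500.0
INTER_TRIAL_GAP_MS = 100.0
DWELL_MS = 300.0
MIN_JERK_PEAK_FACTOR = 1.875  # peak velocity = 1.875 * amplitude / duration


@dataclass(frozen=True)
class PhenotypeParams:
    """Behavioral and physiological parameters of one simulated group."""

    latency_mean_ms: float = 250.0
    latency_sd_ms: float = 50.0
    direction_error_prob: float = 0.15  # antisaccade: first saccade to the stimulus
    search_prob: float = 0.15  # antisaccade: annulus search run before landing
    search_fix_mean: float = 2.0  # mean fixations per search run (>= 2)
    ua_fix_rate: float = 0.3  # Poisson rate of unrelated-area excursions per trial
    intrusive_prob: float = 0.10  # delayed: off-center fixation before 1500 ms
    ta_w_prob: float = 0.10  # delayed: premature target fixation in [1500, 2500)
    completion_prob: float = 0.97  # probability the target is fixated and held
    peak_velocity_mean: float = 450.0  # deg/s
    peak_velocity_sd: float = 50.0
    pupil_baseline_mm: float = 4.0
    pupil_baseline_sd_mm: float = 0.3  # between participants
    pupil_sd_mm: float = 0.10  # within-trial slow-drift SD
    pupil_noise_mm: float = 0.01
    artifact_prob: float = 0.3  # per trial: step spike to exercise the MAD filter
    blink_prob: float = 0.2  # per trial: 100 ms invalid run
    fixation_jitter_px: float = 10.0  # dispersion of intended fixation points
    gaze_noise_px: float = 3.0  # per-sample measurement noise

    def __post_init__(self) -> None:
        for name in (
            "direction_error_prob",
            "search_prob",
            "intrusive_prob",
            "ta_w_prob",
            "completion_prob",
            "artifact_prob",
            "blink_prob",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


TD_PRESET = PhenotypeParams()
ADHD_PRESET = PhenotypeParams(
    latency_mean_ms=420.0,
    latency_sd_ms=120.0,
    direction_error_prob=0.5,
    search_prob=0.5,
    search_fix_mean=3.0,
    ua_fix_rate=1.5,
    intrusive_prob=0.45,
    ta_w_prob=0.4,
    completion_prob=0.80,
    peak_velocity_mean=360.0,
    peak_velocity_sd=50.0,
    pupil_sd_mm=0.25,
    fixation_jitter_px=25.0,
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition; defaults mirror the study's enrollment."""

    n_td: int = 122
    n_adhd: int = 94
    sampling_rate_hz: float = 250.0
    seed: int = 0
    #: Age-group proportions (5-6 y, 7-8 y, 9-10 y) per group.
    td_age_weights: tuple[float, float, float] = (44, 45, 33)
    adhd_age_weights: tuple[float, float, float] = (36, 37, 21)
    td_male_fraction: float = 0.5
    adhd_male_fraction: float = 84 / 94

    def __post_init__(self) -> None:
        if self.n_td < 1 or self.n_adhd < 1:
            raise ValueError("need at least one participant per group")
        if self.sampling_rate_hz < 60:
            raise ValueError("sampling rate below 60 Hz is not supported")

    @property
    def n_total(self) -> int:
        return self.n_td + self.n_adhd


# ---------------------------------------------------------------------------
# trial scripting


class _Script:
    """Sequence of intended fixations joined by minimum-jerk saccades."""

    def __init__(self, x: float, y: float):
        self.segments: list[dict] = []
        self._open = {"t0": 0.0, "x": x, "y": y, "tag": "center"}

    @property
    def pos(self) -> tuple[float, float]:
        return self._open["x"], self._open["y"]

    @property
    def open_since(self) -> float:
        return self._open["t0"]

    def saccade_to(
        self,
        x: float,
        y: float,
        screen: ScreenConfig,
        peak_velocity: float,
        tag: str,
        leave_at: float | None = None,
        arrive_at: float | None = None,
    ) -> float:
        """Close the open fixation, insert a saccade, open a new fixation.

        Returns the arrival time.  The saccade duration follows the
        minimum-jerk relation ``T = 1.875 * amplitude / peak_velocity``.
        """
        x0, y0 = self.pos
        amp = math.hypot(
            float(screen.px_to_deg_x(x)) - float(screen.px_to_deg_x(x0)),
            float(screen.px_to_deg_y(y)) - float(screen.px_to_deg_y(y0)),
        )
        sdur = max(1000.0 * MIN_JERK_PEAK_FACTOR * amp / peak_velocity, 4.0)
        if arrive_at is not None:
            leave = arrive_at - sdur
        elif leave_at is not None:
            leave = leave_at
        else:
            leave = self._open["t0"]
        leave = max(leave, self._open["t0"] + 100.0)  # keep fixations detectable
        self._open["t1"] = leave
        self.segments.append(self._open)
        self._open = {"t0": leave + sdur, "x": x, "y": y, "tag": tag}
        return leave + sdur

    def finish(self, t_end: float) -> list[dict]:
        self._open["t1"] = max(t_end, self._open["t0"] + 100.0)
        self.segments.append(self._open)
        return self.segments


def _clamped_point(rect: Rect, rng: np.random.Generator, jitter: float, margin: float = 20.0) -> tuple[float, float]:
    """A jittered point around a rectangle's center, clamped inside it."""
    cx, cy = rect.center
    m = min(margin, rect.width / 4.0, (rect.y1 - rect.y0) / 4.0)
    x = float(np.clip(cx + rng.normal(0, jitter), rect.x0 + m, rect.x1 - m))
    y = float(np.clip(cy + rng.normal(0, jitter), rect.y0 + m, rect.y1 - m))
    return x, y


def _ua_point(screen: ScreenConfig, aois: AOISet, rng: np.random.Generator) -> tuple[float, float]:
    """Random point in the unrelated area (outside the stimulus band)."""
    w, h = screen.resolution_px
    band = aois.band
    above = band.y0 - 40.0
    below = h - band.y1 - 40.0
    if rng.random() < above / max(above + below, 1e-9):
        y = rng.uniform(20.0, band.y0 - 20.0)
    else:
        y = rng.uniform(band.y1 + 20.0, h - 20.0)
    return float(rng.uniform(40.0, w - 40.0)), float(y)


def _wsa_point(aois: AOISet, rng: np.random.Generator) -> tuple[float, float]:
    """Point in the wrong-side area proper (inside the band, clear of SA)."""
    assert aois.wsa is not None
    w = aois.wsa
    for _ in range(100):
        x = rng.uniform(w.x0 + 20, w.x1 - 20)
        y = rng.uniform(w.y0 + 20, w.y1 - 20)
        if not (aois.sa.x0 - 15 <= x < aois.sa.x1 + 15):
            return float(x), float(y)
    return float((w.x0 + aois.sa.x0) / 2.0), float(w.center[1])


def _annulus_point(
    aois: AOISet, screen: ScreenConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Point outside the TA square but within 1.5 edge-lengths of its center."""
    cx, cy = aois.ta.center
    edge = aois.ta_edge_px
    w, h = screen.resolution_px
    for _ in range(50):
        r = rng.uniform(0.75 * edge, 1.45 * edge)
        theta = rng.uniform(0, 2 * math.pi)
        x, y = cx + r * math.cos(theta), cy + r * math.sin(theta)
        if 10 <= x < w - 10 and 10 <= y < h - 10 and not aois.ta.contains(x, y):
            return float(x), float(y)
    # Degenerate geometry; fall back to a point straight above the TA.
    return float(cx), float(max(cy - edge, 10.0))


def _script_trial(
    phenotype: PhenotypeParams,
    spec: TrialSpec,
    aois: AOISet,
    screen: ScreenConfig,
    rng: np.random.Generator,
) -> tuple[list[dict], dict]:
    """Build the intended fixation script and ground-truth flags for one trial."""
    p = phenotype
    jitter = p.fixation_jitter_px
    vp = max(100.0, rng.normal(p.peak_velocity_mean, p.peak_velocity_sd))
    latency = max(120.0, rng.normal(p.latency_mean_ms, p.latency_sd_ms))
    completed = rng.random() < p.completion_prob
    go = spec.response_onset_ms

    script = _Script(*_clamped_point(aois.ca, rng, jitter / 2.0))
    truth = {
        "task": spec.task,
        "latency_ms": latency,
        "completed": completed,
        "n_ua": 0,
        "direction_error": False,
        "search": False,
        "intrusive": False,
        "ta_wrong": False,
    }

    def sac(x, y, tag, **kw):
        return script.saccade_to(x, y, screen, vp, tag, **kw)

    if spec.task == "delayed":
        if rng.random() < p.intrusive_prob:
            truth["intrusive"] = True
            t = sac(*_ua_point(screen, aois, rng), "intrusive", leave_at=rng.uniform(350, 900))
            sac(*_clamped_point(aois.ca, rng, jitter / 2.0), "center", leave_at=t + rng.uniform(150, 250))
        if rng.random() < p.ta_w_prob:
            truth["ta_wrong"] = True
            t = sac(*_clamped_point(aois.ta, rng, jitter), "ta_wrong", leave_at=rng.uniform(1600, 2000))
            sac(*_clamped_point(aois.ca, rng, jitter / 2.0), "center", leave_at=t + rng.uniform(150, 250))
        if completed:
            sac(*_clamped_point(aois.ta, rng, jitter), "target", arrive_at=go + latency)
        elif rng.random() < 0.5:
            sac(*_ua_point(screen, aois, rng), "ua_wander", leave_at=go + rng.uniform(300, 1200))
        return script.finish(spec.end_ms), truth

    # Pro/antisaccade: center hold, optional excursions, then (maybe) target.
    n_ua = int(rng.poisson(p.ua_fix_rate))
    truth["n_ua"] = n_ua
    t = go + rng.uniform(150, 250)
    for _ in range(n_ua):
        t = sac(*_ua_point(screen, aois, rng), "ua", leave_at=t)
        t += rng.uniform(150, 300)

    if spec.task == "antisaccade":
        if rng.random() < p.direction_error_prob:
            # A direction error looks at the stimulus, then hangs on the
            # wrong side before the corrective saccade.
            truth["direction_error"] = True
            t = sac(*_clamped_point(aois.sa, rng, jitter), "error_sa", leave_at=t)
            t += rng.uniform(150, 250)
            t = sac(*_wsa_point(aois, rng), "error_wsa", leave_at=t)
            t += rng.uniform(150, 300)
        if rng.random() < p.search_prob:
            truth["search"] = True
            k = max(2, int(rng.poisson(p.search_fix_mean)))
            for _ in range(k):
                t = sac(*_annulus_point(aois, screen, rng), "search", leave_at=t)
                t += rng.uniform(130, 220)

    if completed:
        arrive_target = max(go + latency, t if (n_ua or truth["direction_error"] or truth["search"]) else go + latency)
        arrival = sac(*_clamped_point(aois.ta, rng, jitter), "target", arrive_at=arrive_target)
        return script.finish(arrival + DWELL_MS), truth
    if n_ua == 0:
        sac(*_ua_point(screen, aois, rng), "ua_wander", leave_at=go + rng.uniform(400, 1500))
    return script.finish(spec.stimulus_onset_ms + PRO_ANTI_TIMEOUT_MS), truth


# ---------------------------------------------------------------------------
# rendering scripts into raw samples


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def render_script(
    segments: list[dict],
    phenotype: PhenotypeParams,
    rate_hz: float,
    rng: np.random.Generator,
    pupil_baseline_mm: float | None = None,
) -> pd.DataFrame:
    """Render an intended-fixation script into raw gaze samples."""
    p = phenotype
    t_end = segments[-1]["t1"]
    dt = 1000.0 / rate_hz
    t = np.arange(0.0, t_end, dt)
    x = np.empty_like(t)
    y = np.empty_like(t)

    # Fixation spans hold position; inter-segment spans follow minimum jerk.
    prev = None
    for seg in segments:
        inside = (t >= seg["t0"]) & (t < seg["t1"])
        x[inside], y[inside] = seg["x"], seg["y"]
        if prev is not None and seg["t0"] > prev["t1"]:
            moving = (t >= prev["t1"]) & (t < seg["t0"])
            tau = (t[moving] - prev["t1"]) / (seg["t0"] - prev["t1"])
            s = _min_jerk(tau)
            x[moving] = prev["x"] + s * (seg["x"] - prev["x"])
            y[moving] = prev["y"] + s * (seg["y"] - prev["y"])
        prev = seg
    tail = t >= prev["t1"]
    x[tail], y[tail] = prev["x"], prev["y"]

    if p.gaze_noise_px > 0:
        x = x + rng.normal(0, p.gaze_noise_px, t.size)
        y = y + rng.normal(0, p.gaze_noise_px, t.size)

    base = pupil_baseline_mm if pupil_baseline_mm is not None else p.pupil_baseline_mm
    amp = p.pupil_sd_mm * math.sqrt(2.0)
    phase = rng.uniform(0, 2 * math.pi)
    pupil = base + amp * np.sin(2 * math.pi * t / 3000.0 + phase)
    pl = pupil + rng.normal(0, p.pupil_noise_mm, t.size) if p.pupil_noise_mm > 0 else pupil.copy()
    pr = pupil + rng.normal(0, p.pupil_noise_mm, t.size) if p.pupil_noise_mm > 0 else pupil.copy()

    valid = np.ones(t.size, dtype=bool)
    if rng.random() < p.artifact_prob and t.size > 10:
        i = rng.integers(2, t.size - 5)
        k = max(1, int(round(12.0 / dt)))  # ~12 ms spike
        pl[i : i + k] += 3.5
        pr[i : i + k] += 3.5
    if rng.random() < p.blink_prob and t.size > 10:
        i = rng.integers(0, t.size - 1)
        k = max(1, int(round(100.0 / dt)))
        valid[i : i + k] = False

    xg, yg = x.copy(), y.copy()
    xg[~valid] = np.nan
    yg[~valid] = np.nan
    pl[~valid] = np.nan
    pr[~valid] = np.nan
    return pd.DataFrame(
        {
            "timestamp_ms": t,
            "gaze_x_px": xg,
            "gaze_y_px": yg,
            "pupil_left_mm": pl,
            "pupil_right_mm": pr,
            "valid_left": valid,
            "valid_right": valid.copy(),
        }
    )


def generate_trial(
    phenotype: PhenotypeParams,
    spec: TrialSpec,
    screen: ScreenConfig,
    rng: np.random.Generator,
    rate_hz: float = 250.0,
    pupil_baseline_mm: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One trial's raw samples (trial-relative timestamps) and ground truth."""
    aois = build_aois(spec, screen)
    segments, truth = _script_trial(phenotype, spec, aois, screen, rng)
    samples = render_script(segments, phenotype, rate_hz, rng, pupil_baseline_mm)
    truth["segments"] = segments
    return samples, truth


# ---------------------------------------------------------------------------
# cohorts


def build_roster(config: CohortConfig | None = None) -> pd.DataFrame:
    """Deterministic participant roster: ids, labels, sex, age, age group."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, n, age_w, male_frac in (
        ("TD", config.n_td, config.td_age_weights, config.td_male_fraction),
        ("ADHD", config.n_adhd, config.adhd_age_weights, config.adhd_male_fraction),
    ):
        weights = np.asarray(age_w, dtype=float)
        weights = weights / weights.sum()
        n_male = int(round(n * male_frac))
        for i in range(n):
            age_group = int(rng.choice([1, 2, 3], p=weights))
            age = float(rng.uniform(*{1: (5, 7), 2: (7, 9), 3: (9, 11)}[age_group]))
            rows.append(
                {
                    "participant_id": f"{group}{i + 1:03d}",
                    "label": 1 if group == "ADHD" else 0,
                    "group": group,
                    "sex": "M" if i < n_male else "F",
                    "age": round(age, 1),
                    "age_group": age_group,
                }
            )
    return pd.DataFrame(rows)


def generate_participant(
    participant_id: str,
    phenotype: PhenotypeParams,
    screen: ScreenConfig,
    rng: np.random.Generator,
    rate_hz: float = 250.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """All 36 trials of one participant.

    Returns (gaze samples with recording-clock timestamps, trial markers,
    ground-truth log)."""
    baseline = float(
        np.clip(
            rng.normal(phenotype.pupil_baseline_mm, phenotype.pupil_baseline_sd_mm),
            2.5,
            7.0,
        )
    )
    specs = standard_trial_specs(rng)
    onset = 0.0
    sample_blocks = []
    marker_rows = []
    truths = []
    for trial_id, spec in enumerate(specs, start=1):
        samples, truth = generate_trial(
            phenotype, spec, screen, rng, rate_hz, pupil_baseline_mm=baseline
        )
        block = samples.copy()
        block.insert(0, "trial_id", trial_id)
        block.insert(0, "participant_id", participant_id)
        block["timestamp_ms"] = block["timestamp_ms"] + onset
        sample_blocks.append(block)
        marker_rows.append(
            {
                "participant_id": participant_id,
                "trial_id": trial_id,
                "task": spec.task,
                "eccentricity_deg": spec.eccentricity_deg,
                "side": spec.side,
                "order": spec.order,
                "onset_ms": onset,
            }
        )
        truth["participant_id"] = participant_id
        truth["trial_id"] = trial_id
        truths.append(truth)
        onset += float(samples["timestamp_ms"].iloc[-1]) + INTER_TRIAL_GAP_MS
    gaze = pd.concat(sample_blocks, ignore_index=True)[GAZE_COLUMNS]
    markers = pd.DataFrame(marker_rows)[MARKER_COLUMNS]
    return gaze, markers, truths


def iter_cohort(
    config: CohortConfig | None = None,
    td: PhenotypeParams = TD_PRESET,
    adhd: PhenotypeParams = ADHD_PRESET,
    screen: ScreenConfig | None = None,
) -> Iterator[tuple[pd.Series, pd.DataFrame, pd.DataFrame, list[dict]]]:
    """Yield (roster row, gaze, markers, truth) per participant, lazily.

    Each participant gets an independent child RNG seeded from the cohort
    seed, so generation is deterministic and order-independent.
    """
    config = config or CohortConfig()
    screen = screen or ScreenConfig(sampling_rate_hz=config.sampling_rate_hz)
    roster = build_roster(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(roster))
    for (_, row), seq in zip(roster.iterrows(), children):
        phenotype = adhd if row["label"] == 1 else td
        rng = np.random.default_rng(seq)
        gaze, markers, truths = generate_participant(
            row["participant_id"], phenotype, screen, rng, config.sampling_rate_hz
        )
        yield row, gaze, markers, truths


def generate_cohort(
    out_dir: str | Path,
    config: CohortConfig | None = None,
    td: PhenotypeParams = TD_PRESET,
    adhd: PhenotypeParams = ADHD_PRESET,
) -> pd.DataFrame:
    """Write gaze, marker, participant, and ground-truth files for a cohort.

    Returns the roster.  Deterministic given ``config.seed``.
    """
    import json

    config = config or CohortConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gaze_path = out / "gaze.csv"
    marker_path = out / "markers.csv"
    truth_path = out / "ground_truth.json"

    roster_rows = []
    all_truths = []
    first = True
    for row, gaze, markers, truths in iter_cohort(config, td, adhd):
        roster_rows.append(row)
        g = gaze.copy()
        g["valid_left"] = g["valid_left"].astype(int)
        g["valid_right"] = g["valid_right"].astype(int)
        g.to_csv(gaze_path, mode="w" if first else "a", header=first, index=False,
                 float_format="%.6g")
        markers.to_csv(marker_path, mode="w" if first else "a", header=first,
                       index=False, float_format="%.6g")
        for tr in truths:
            tr = {k: v for k, v in tr.items() if k != "segments"}
            all_truths.append(tr)
        first = False
    roster = pd.DataFrame(roster_rows)
    roster.to_csv(out / "participants.csv", index=False)
    with open(truth_path, "w") as fh:
        json.dump(all_truths, fh, default=float)
    return roster
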