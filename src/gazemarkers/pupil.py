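"""Pupil-diameter preprocessing and per-trial pupil metrics.

The raw binocular pupil signal is cleaned in five steps before any
statistic is computed:

1. drop invalid samples and diameters outside the physiologically
   feasible 1.5-9.0 mm range;
2. compute the normalized dilation speed

       s_i = max(|(p_i - p_{i-1}) / (t_i - t_{i-1})|,
                 |(p_{i+1} - p_i) / (t_{i+1} - t_i)|)

   and remove samples whose speed exceeds the robust threshold
   T = median(s) + n * MAD(s) with n = 1.5, where
   MAD = median(|s - median(s)|).  Steps 1-2 run per eye;
3. keep only timestamps surviving in both eyes and average them;
4. resample to a uniform 500 Hz grid with a timestamp-weighted
   exponential moving average over a 20-sample sliding window, never
   interpolating across gaps of 50 ms or more;
5. summarize the cleaned trace as mean / max / min / SD diameter.

Dilation-speed thresholding targets blink edges and tracker glitches,
which produce physically impossible diameter slews; the MAD keeps the
threshold robust to the very outliers being removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

PUPIL_MIN_MM = 1.5
PUPIL_MAX_MM = 9.0
MAD_SCALAR = 1.5
RESAMPLE_HZ = 500.0
EMA_WINDOW = 20
EMA_HALFLIFE_MS = 10.0
GAP_MS = 50.0


@dataclass(frozen=True)
class PupilMetrics:
    """Per-trial summary of the cleaned pupil trace (mm)."""

    avg: float
    max: float
    min: float
    sd: float


def range_filter(
    t: np.ndarray, p: np.ndarray, valid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: keep valid samples with diameter in [1.5, 9.0] mm (inclusive)."""
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    keep = np.isfinite(p) & (p >= PUPIL_MIN_MM) & (p <= PUPIL_MAX_MM)
    if valid is not None:
        keep &= np.asarray(valid, dtype=bool)
    if not keep.any():
        warnings.warn("range filter removed every pupil sample", stacklevel=2)
    return t[keep], p[keep]


def dilation_speed(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Two-sided maximum absolute dilation speed, mm/ms.

    Interior samples take the larger of the backward and forward slopes;
    the endpoints use their single available one-sided slope.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.size < 3:
        raise ValueError("dilation speed needs at least 3 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    slope = np.abs(np.diff(p) / np.diff(t))  # slope[i] between samples i and i+1
    s = np.empty_like(p)
    s[0] = slope[0]
    s[-1] = slope[-1]
    s[1:-1] = np.maximum(slope[:-1], slope[1:])
    return s


def mad_threshold(s: np.ndarray, n: float = MAD_SCALAR) -> float:
    """Robust outlier threshold T = median(s) + n * MAD(s)."""
    med = float(np.median(s))
    mad = float(np.median(np.abs(s - med)))
    return med + n * mad


def mad_outlier_filter(
    t: np.ndarray, p: np.ndarray, n: float = MAD_SCALAR
) -> tuple[np.ndarray, np.ndarray]:
    """Step 2: drop samples whose dilation speed is strictly above T.

    With fewer than 3 samples the speed is undefined and the trace passes
    through unchanged (with a warning).  When MAD = 0, T collapses to the
    median and only samples strictly above it are removed.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.size < 3:
        warnings.warn("too few samples for outlier filtering", stacklevel=2)
        return t, p
    s = dilation_speed(t, p)
    keep = s <= mad_threshold(s, n)
    return t[keep], p[keep]


def merge_eyes(
    t_left: np.ndarray,
    p_left: np.ndarray,
    t_right: np.ndarray,
    p_right: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 3: intersect surviving timestamps and average the two eyes."""
    t_common, il, ir = np.intersect1d(
        np.asarray(t_left, dtype=float),
        np.asarray(t_right, dtype=float),
        return_indices=True,
    )
    if t_common.size == 0:
        warnings.warn("no common timestamps between eyes", stacklevel=2)
        return t_common, np.array([])
    merged = (np.asarray(p_left, dtype=float)[il] + np.asarray(p_right, dtype=float)[ir]) / 2.0
    return t_common, merged


def resample_smooth(
    t: np.ndarray,
    p: np.ndarray,
    out_hz: float = RESAMPLE_HZ,
    window: int = EMA_WINDOW,
    halflife_ms: float = EMA_HALFLIFE_MS,
    gap_ms: float = GAP_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 4: uniform resampling with a gap-aware exponential moving average.

    The input is split into segments wherever consecutive samples are
    ``gap_ms`` or more apart; each segment gets its own uniform grid at
    ``out_hz`` starting at the segment's first timestamp, so no value is
    ever synthesized inside a gap.  Each output value is the normalized
    exponentially-weighted mean (half-life ``halflife_ms``) of at most the
    ``window`` nearest preceding input samples.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.size == 0:
        return t, p
    step = 1000.0 / out_hz
    decay = np.log(2.0) / halflife_ms

    splits = np.nonzero(np.diff(t) >= gap_ms)[0] + 1
    out_t: list[np.ndarray] = []
    out_p: list[np.ndarray] = []
    for seg in np.split(np.arange(t.size), splits):
        ts, ps = t[seg], p[seg]
        n_out = int(np.floor((ts[-1] - ts[0]) / step)) + 1
        grid = ts[0] + step * np.arange(n_out)
        # For each grid point, the `window` input samples at or before it.
        hi = np.searchsorted(ts, grid, side="right")  # first index > grid point
        ids = hi[:, None] - window + np.arange(window)[None, :]
        mask = ids >= 0
        ids = np.clip(ids, 0, ts.size - 1)
        w = np.exp(-decay * (grid[:, None] - ts[ids])) * mask
        out_p.append((w * ps[ids]).sum(axis=1) / w.sum(axis=1))
        out_t.append(grid)
    return np.concatenate(out_t), np.concatenate(out_p)


def pupil_metrics(p: np.ndarray) -> PupilMetrics:
    """Step 5: mean / max / min / sample-SD of the cleaned trace."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return PupilMetrics(np.nan, np.nan, np.nan, np.nan)
    sd = float(np.std(p, ddof=1)) if p.size > 1 else 0.0
    return PupilMetrics(
        avg=float(np.mean(p)), max=float(np.max(p)), min=float(np.min(p)), sd=sd
    )


def preprocess_trial(
    t: np.ndarray,
    p_left: np.ndarray,
    p_right: np.ndarray,
    valid_left: np.ndarray | None = None,
    valid_right: np.ndarray | None = None,
    n: float = MAD_SCALAR,
) -> tuple[np.ndarray, np.ndarray]:
    """Run steps 1-4 on one trial's binocular trace; returns (t, p) uniform."""
    tl, pl = range_filter(t, p_left, valid_left)
    tr, pr = range_filter(t, p_right, valid_right)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tl, pl = mad_outlier_filter(tl, pl, n)
        tr, pr = mad_outlier_filter(tr, pr, n)
        tm, pm = merge_eyes(tl, pl, tr, pr)
    if tm.size == 0:
        return tm, pm
    return resample_smooth(tm, pm)


def trial_pupil_metrics(samples, n: float = MAD_SCALAR) -> PupilMetrics:
    """Full pipeline from a trial's raw sample table to the four metrics."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = preprocess_trial(
            samples["timestamp_ms"].to_numpy(dtype=float),
            samples["pupil_left_mm"].to_numpy(dtype=float),
            samples["pupil_right_mm"].to_numpy(dtype=float),
            samples["valid_left"].to_numpy(dtype=bool),
            samples["valid_right"].to_numpy(dtype=bool),
            n=n,
        )
    return pupil_metrics(p)
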