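"""The five-step pupil cleaning pipeline on a small worked trace.

Shows the feasible-range filter, the two-sided dilation speed, the
MAD-based outlier threshold, eye merging, and gap-aware resampling.
"""

import numpy as np

import gazemarkers as gm
from gazemarkers.pupil import mad_threshold

# Step 1: range filter — 0.9 mm is physiologically impossible.
t, p = gm.range_filter([0, 10, 20], [3.0, 0.9, 3.1])
print("after range filter:", list(p), "mm")

# Step 2: dilation speed and MAD threshold.
t = np.array([0.0, 10.0, 20.0])
p = np.array([3.0, 3.1, 3.3])
s = gm.dilation_speed(t, p)
print("dilation speeds:", s, "mm/ms")  # interior sample takes max(0.01, 0.02)

s_demo = np.array([1.0, 2.0, 100.0])
print(f"speeds {s_demo}: threshold T = {mad_threshold(s_demo)} "
      "(median 2 + 1.5 * MAD 1); the 100 is rejected as a blink/glitch edge")

# Steps 3-4: merge the eyes, then resample to a uniform 500 Hz grid.
tl = np.arange(0, 200, 8.3)              # nonuniform-ish left eye
pl = 4.0 + 0.05 * np.sin(tl / 30)
tm, pm = gm.merge_eyes(tl, pl, tl, pl + 0.2)
tg, pg = gm.resample_smooth(tm, pm)
print(f"\nmerged {tm.size} samples -> {tg.size} samples at "
      f"{1000 / (tg[1] - tg[0]):.0f} Hz")

# Step 5: the four per-trial pupil metrics.
m = gm.pupil_metrics(pg)
print(f"pupil metrics: avg {m.avg:.3f}  max {m.max:.3f}  "
      f"min {m.min:.3f}  sd {m.sd:.4f} mm")
# The mean of the two eyes is 0.1 mm above the left eye's trace; the SD
# reflects only the slow sinusoidal drift that survives smoothing.
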