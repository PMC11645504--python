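"""Screen geometry and area-of-interest partitions.

Places the three stimulus eccentricities on the default screen and
builds the antisaccade area partition, showing how a fixation centroid
is labeled.
"""

import gazemarkers as gm

screen = gm.ScreenConfig()  # 1920x1080, 24-inch 16:9, 65 cm, 1200 Hz
print("pixels per cm:", round(screen.px_per_cm_x, 2))
for deg in (7, 15, 20):
    px = gm.eccentricity_to_px(deg, screen)
    print(f"  {deg:2d} deg eccentricity -> {px:6.1f} px from screen center")
# Each offset is viewing_distance * tan(angle) converted at the panel's
# pixel density: where the stimulus square lands for that eccentricity.

spec = gm.TrialSpec("antisaccade", 15, "right")
aois = gm.build_aois(spec, screen)
print("\nantisaccade, 15 deg, stimulus right:")
print("  SA (stimulus) center:", tuple(round(v) for v in aois.sa.center))
print("  TA (target)  center:", tuple(round(v) for v in aois.ta.center))
# The target mirrors the stimulus across the vertical midline; a correct
# antisaccade lands in TA, a direction error in SA or the wrong-side area.

for point, why in [
    (screen.center_px, "screen center"),
    (aois.ta.center, "target center"),
    ((aois.ta.center[0], 100.0), "above the stimulus band"),
]:
    label, _ = gm.classify_point(point[0], point[1], 2000.0, aois)
    print(f"  fixation at {why}: area = {label}")
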