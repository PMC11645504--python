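# Methods

## Paradigm model

Three screen-based saccade tasks are presented on a 1920×1080 px,
24-inch 16:9 monitor (53.14 × 29.89 cm) viewed from 65 cm. A central
fixation cross appears at trial start; after 1500 ms a 5 × 5 cm stimulus
square appears at ±7°, ±15°, or ±20° of horizontal eccentricity. In the
prosaccade task the participant looks at the stimulus; in the
antisaccade task at its mirror position across the vertical midline; in
the delayed task the participant must hold central fixation until an
auditory cue 1000 ms after stimulus onset (t = 2500 ms) and the trial
ends 3000 ms after the cue. Pro/antisaccade trials complete when gaze
dwells 300 ms inside the target square. A full assessment is 12 formal
trials per task: two per (eccentricity, side) position.

Degrees map to pixels by the flat-screen tangent model,
`offset = d·tan θ` at d = 65 cm, converted with the panel's pixel
density (36.13 px/cm): 7° → 288 px, 15° → 629 px, 20° → 855 px.

### Screen-area partition

Coordinates are 0-based pixels, origin top-left; all rectangles are
half-open so every pixel receives exactly one label. A horizontal band
of height 5 cm through the screen center carries the task-relevant
areas; everything outside it is the unrelated area (UA). Inside the
band: the center area (CA) is a 5 × 5 cm square at the cross; the
stimulus area (SA) is the stimulus square; the target area (TA) equals
SA for prosaccade/delayed and is its horizontal mirror for antisaccade.
In the antisaccade task the remaining band splits at the CA edges into
the proper-side area (PSA, target side) and wrong-side area (WSA,
stimulus side). Label priority CA > TA > SA > PSA/WSA > UA resolves the
nested rectangles. The published figures do not define the exact
off-band shapes machine-readably; the band construction here is the
package's own declared geometry and is configurable.

Delayed-task fixations additionally carry a time-window label from
their start time: intrusive window [0, 1500) ms, wrong period
[1500, 2500) ms, proper period [2500, 5500) ms.

### Entropy grids

Gaze-entropy state spaces are regular grids tiling the screen: 3 × 2
cells (n = 6) for prosaccade/delayed, 4 × 2 (n = 8) for antisaccade.
The published figure gives the cell counts but not the layout; equal
rectangles are the package's default and are configurable.

## Event detection (I-VT)

The study used vendor software for fixation/saccade extraction; this
package re-implements the velocity-threshold classifier so results do
not depend on proprietary tooling. Gaze positions are converted to
visual angle, smoothed with a 3-sample moving average, and
differentiated centrally; samples above 30 °/s are saccade samples, the
rest fixation samples, and contiguous runs become events. Fixations
shorter than 60 ms are discarded; invalid-sample gaps of at most 75 ms
are bridged, longer gaps split events. The defaults are the vendor's
published filter values and every parameter is configurable. On
noise-free scripted trajectories the detected boundaries sit within two
samples of the construction.

## Pupil preprocessing

Per trial and per eye: (1) drop invalid samples and diameters outside
1.5–9.0 mm (inclusive); (2) compute the two-sided maximum dilation speed
`s_i` (endpoints use their single one-sided slope — the sequence ends
are otherwise undefined) and remove samples with
`s_i > median(s) + 1.5·MAD(s)`; when MAD = 0 the threshold collapses to
the median and only strictly larger speeds are removed. (3) Keep
timestamps surviving in both eyes and average them. (4) Resample to a
uniform 500 Hz grid with a timestamp-weighted exponential moving average
over at most the 20 nearest preceding samples (window read literally as
samples, not milliseconds; half-life 10 ms, the package's own choice of
decay constant — both configurable), never emitting values across gaps
of ≥ 50 ms. (5) Summarize as mean/max/min/SD; SD uses the sample (n−1)
denominator. The pipeline provably never emits a value outside
1.5–9.0 mm.

## Biomarkers

28 definitions: 8 general, 4 pupil-based, 11 area-based, 3 search-based,
2 entropy-based; applicability varies by task (e.g. stimulus-area
fixation counts exist only for antisaccade, period-split target counts
only for delayed). Booleans are stored as 0/1 so participant-level
averaging yields incidences. Target-fixation latency `L_TA_Fix` is
measured from the earliest permitted response — stimulus onset for
pro/antisaccade, the auditory cue for delayed trials — because latency
relative to the go signal is the behaviorally meaningful quantity.
Search behavior (antisaccade) is a maximal run of ≥ 2 consecutive
fixations landing outside the target square but within 1.5 target-edge
lengths of its center (Euclidean distance). Transition entropy counts
self-transitions by default (configurable) and weights row entropies by
the same empirical stationary distribution used for SGE; `0·log 0 ≡ 0`.
Skipped or non-completed trials keep their recorded data; `B_TA_Fix`
simply records that the target was never fixated.

## Feature table

Each biomarker expands across task (P/A/D) and eccentricity (7/15/20),
averaging over side and order within each (task, eccentricity) cell (up
to 4 trials); missing trials reduce the denominator, an empty cell is
missing. Column order is fixed — metrics in catalog order, then task,
then eccentricity — and the catalog yields exactly 183 columns. Latency
from non-completed trials is missing and simply drops out of the cell
mean. Downstream models impute remaining missing values with the
training-fold median.

## Statistics

Pooled-variance t tests (df = n₁+n₂−2, matching the study's printed
df = 214) with a summary-statistic entry point so published group tables
can be re-checked; Pearson χ² without continuity correction (which
reproduces the published sex χ² of 37.28 exactly); Mann-Whitney U with
exact enumeration for small tie-free samples and the tie-corrected
normal approximation otherwise; Kruskal-Wallis with Bonferroni-adjusted
pairwise follow-ups. The classifier's variable filter retains columns
with two-sided Mann-Whitney p < α (default α = 0.05; the study states
only "significantly different"). Reconstructing the inattentive-scale t
from the rounded printed summaries gives −199.19 against a printed
−199.20; the inputs' two-decimal rounding limits the recoverable
precision of a statistic that large.

## Classification

XGBoost with library-default hyperparameters (the study design this
package models reports using defaults without adjustment),
evaluated by stratified 5-fold cross-validation repeated 500 times by
default. Stratification is the package's choice given the 94/122 class
imbalance. Within every training fold the variable filter and median
imputation are fit on training data only; filtering outside CV is
available but off by default because it leaks label information.
Held-out scores are pooled within each repeat before computing AUC
(rank/Mann-Whitney formulation), accuracy, sensitivity, specificity,
precision, and F1 at a 0.5 threshold — pooling stabilizes AUC with
~43-sample folds. Aggregates are means with 2.5/97.5-percentile 95% CIs
across repeats. Importance is total split gain per variable summed over
trees and averaged over all fitted ensembles. Everything is
deterministic given the base seed: fold partitions and per-fold tree
seeds derive from (seed, repeat, fold).

## Synthetic cohort generator

Each trial is scripted as a sequence of intended fixations joined by
minimum-jerk saccades (duration `T = 1.875·A/V_peak`), then rendered
into raw samples at a configurable rate (default 250 Hz; 1200 Hz
supported) with Gaussian gaze noise, a binocular pupil trace
(participant baseline + slow sinusoidal drift + white noise + occasional
+3.5 mm artifact spikes to exercise the MAD filter), and occasional
100 ms blink dropouts. Phenotype latency is defined go-signal →
target-fixation onset, which is exactly what `L_TA_Fix` measures, so
planted latencies are directly recoverable. The per-trial event
repertoire follows the task: unrelated-area excursions (Poisson),
direction errors (stimulus fixation then a wrong-side hang), search runs
(≥ 2 annulus fixations), intrusive and premature target fixations in
the delayed task, and a completion probability governing whether the
target is ever held.

Default cohort composition mirrors the study's enrollment: 122 TD-like
and 94 ADHD-like participants (43.5% ADHD) with matching age-group and
sex proportions, 36 trials each. The two presets differ directionally —
TD vs ADHD: latency 250±50 vs 420±120 ms; direction-error probability
0.15 vs 0.5; search probability 0.15 vs 0.5; unrelated-fixation rate 0.3
vs 1.5 per trial; intrusive probability 0.10 vs 0.45; premature-target
probability 0.10 vs 0.40; completion 0.97 vs 0.80; peak velocity 450 vs
360 °/s; within-trial pupil SD 0.10 vs 0.25 mm; fixation dispersion 10
vs 25 px. The magnitudes are the package's own choices of plausible
values (no per-metric clinical summaries are published to calibrate
against); the directions match the reported group differences.

What the generator does **not** model: oculomotor dynamics beyond the
minimum-jerk profile, luminance-driven pupil responses, head movement,
calibration drift, developmental age trends, or any correlation
structure between biomarkers beyond what the shared phenotype induces.
Consequently, a high cross-validated AUC on generated cohorts shows that
the pipeline extracts and recovers planted group structure end to end —
it says nothing about clinical discrimination on real recordings, and
the published headline classification numbers are deliberately not
treated as reproducible targets here.

## Problem sizes and numerical choices

The test suite and acceptance script use n = 50 per group at 250 Hz
with 50 cross-validation repeats for end-to-end checks, and 500–1000
random instances for oracle-agreement checks; these sizes were chosen as
the smallest at which the statistical checks are stable. Brute-force
oracles (entropy by direct summation, U by pair counting, AUC by
pairwise comparison, MAD by sorting) agree with the implementations to
1e-8 or better. Ties in rectangle hit-testing are resolved by the
half-open convention; entropy of an empty fixation set is missing, not
zero; degenerate statistical inputs (zero variance, all-identical
pooled samples, single-class score sets) return the documented flagged
values rather than raising.
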