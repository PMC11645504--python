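"""Per-trial biomarkers: general, area-based, search, and entropy metrics."""

import math

import numpy as np
import pytest

import gazemarkers as gm
from gazemarkers.biomarkers import CATEGORY_COUNTS, METRIC_CATALOG, SearchEvent
from gazemarkers.gaze_io import FixationEvent, SaccadeEvent

from conftest import fixation_at


def naive_entropies(areas, n):
    """Independent direct-summation oracle for SGE and GTE (bits)."""
    counts = {}
    for a in areas:
        counts[a] = counts.get(a, 0) + 1
    total = len(areas)
    p = {a: c / total for a, c in counts.items()}
    sge = -sum(pi * math.log2(pi) for pi in p.values())
    trans = {}
    for a, b in zip(areas[:-1], areas[1:]):
        trans.setdefault(a, {}).setdefault(b, 0)
        trans[a][b] += 1
    gte = 0.0
    for i, row in trans.items():
        tot = sum(row.values())
        h_row = -sum((c / tot) * math.log2(c / tot) for c in row.values())
        gte += p[i] * h_row
    return sge, gte


def fixations_in_cells(cells, partition, screen):
    """Build fixations whose centroids sit at the given grid-cell centers."""
    w, h = screen.resolution_px
    cw, ch = w / partition.n_cols, h / partition.n_rows
    out = []
    for k, cell in enumerate(cells):
        row, col = divmod(cell, partition.n_cols)
        out.append(fixation_at(col * cw + cw / 2, row * ch + ch / 2, t_start=k * 100.0))
    return out


class TestCatalog:
    def test_28_metrics_partitioned_by_category(self):
        assert len(METRIC_CATALOG) == 28
        counts = {}
        for m in METRIC_CATALOG:
            counts[m.category] = counts.get(m.category, 0) + 1
        assert counts == CATEGORY_COUNTS == {
            "general": 8, "pupil": 4, "area": 11, "search": 3, "entropy": 2
        }

    @pytest.mark.parametrize(
        "task,expected",
        [
            ("prosaccade", {"N_UA_Fix"}),
            ("antisaccade", {"N_UA_Fix", "N_SA_Fix", "B_PSA_Fix", "B_WSA_Fix",
                             "B_PSA_Fix_1st", "B_Search", "N_Search", "T_Search"}),
            ("delayed", {"N_TA_Fix", "N_TA-P_Fix", "N_TA-W_Fix", "B_Intrusive_Sac"}),
        ],
    )
    def test_task_applicability(self, task, expected):
        names = {m.name for m in gm.applicable_metrics(task)}
        shared = {
            "N_Fix", "N_Sac", "T_Total", "T_Fix_Avg", "T_Sac_Avg", "V_Sac_Avg",
            "V_Sac_Peak", "A_Sac_Avg", "D_Pupil_Avg", "D_Pupil_Max",
            "D_Pupil_Min", "D_Pupil_Sd", "B_TA_Fix", "L_TA_Fix",
            "SGE_norm", "GTE_norm",
        }
        assert names == shared | expected


class TestGeneralMetrics:
    def test_counts_and_mean_durations(self):
        fixations = [fixation_at(0, 0, t, d) for t, d in [(0, 100), (200, 200), (500, 300)]]
        out = gm.general_metrics(fixations, [], 1000.0)
        assert out["N_Fix"] == 3
        assert out["T_Fix_Avg"] == pytest.approx(200.0)
        assert out["N_Sac"] == 0
        assert np.isnan(out["V_Sac_Avg"])

    def test_velocity_aggregation(self):
        saccades = [
            SaccadeEvent(0, 40, amplitude_deg=5, mean_velocity=100, peak_velocity=150),
            SaccadeEvent(100, 150, amplitude_deg=7, mean_velocity=300, peak_velocity=400),
        ]
        out = gm.general_metrics([], saccades, 500.0)
        assert out["V_Sac_Avg"] == pytest.approx(200.0)
        assert out["V_Sac_Peak"] == pytest.approx(400.0)  # max of per-saccade peaks
        assert out["A_Sac_Avg"] == pytest.approx(6.0)


class TestAreaMetrics:
    def test_antisaccade_sequence_ca_wsa_ta(self, screen):
        spec = gm.TrialSpec("antisaccade", 15, "right")
        aois = gm.build_aois(spec, screen)
        wsa_pt = ((aois.ca.x1 + aois.sa.x0) / 2.0, aois.band.center[1])
        fixations = [
            fixation_at(*aois.ca.center, 0.0, 1500.0),
            fixation_at(*wsa_pt, 1600.0, 200.0),
            fixation_at(*aois.ta.center, 1900.0, 400.0),
        ]
        out = gm.area_metrics(fixations, aois, spec)
        assert out["B_WSA_Fix"] == 1.0
        assert out["B_PSA_Fix_1st"] == 0.0  # first non-CA landed in WSA
        assert out["B_TA_Fix"] == 1.0
        assert out["L_TA_Fix"] == pytest.approx(1900.0 - 1500.0)

    def test_delayed_period_counting(self, screen):
        """TA fixations at 2000 and 2600 ms split into wrong/proper counts."""
        spec = gm.TrialSpec("delayed", 15, "right")
        aois = gm.build_aois(spec, screen)
        fixations = [
            fixation_at(*aois.ca.center, 0.0, 1500.0),
            fixation_at(*aois.ta.center, 2000.0, 300.0),
            fixation_at(*aois.ta.center, 2600.0, 300.0),
        ]
        out = gm.area_metrics(fixations, aois, spec)
        assert out["N_TA-W_Fix"] == 1.0
        assert out["N_TA-P_Fix"] == 1.0
        assert out["N_TA_Fix"] == 2.0
        assert out["B_TA_Fix"] == 1.0
        assert out["L_TA_Fix"] == pytest.approx(2600.0 - 2500.0)

    def test_delayed_intrusive_saccade(self, screen):
        spec = gm.TrialSpec("delayed", 7, "left")
        aois = gm.build_aois(spec, screen)
        fixations = [
            fixation_at(*aois.ca.center, 0.0, 600.0),
            fixation_at(100.0, 100.0, 800.0, 200.0),  # off-center before 1500
        ]
        out = gm.area_metrics(fixations, aois, spec)
        assert out["B_Intrusive_Sac"] == 1.0

    def test_no_target_fixation_leaves_latency_missing(self, screen):
        spec = gm.TrialSpec("prosaccade", 7, "left")
        aois = gm.build_aois(spec, screen)
        out = gm.area_metrics([fixation_at(*aois.ca.center)], aois, spec)
        assert out["B_TA_Fix"] == 0.0
        assert np.isnan(out["L_TA_Fix"])


class TestSearchDetection:
    def _aois(self, screen):
        return gm.build_aois(gm.TrialSpec("antisaccade", 15, "right"), screen)

    def _annulus_pt(self, aois, frac=1.2, angle=0.0):
        cx, cy = aois.ta.center
        r = frac * aois.ta_edge_px
        return cx + r * math.cos(angle), cy + r * math.sin(angle)

    def test_run_of_two_annulus_fixations_is_one_event(self, screen):
        aois = self._aois(screen)
        fixations = [
            fixation_at(*self._annulus_pt(aois, angle=1.2), 0.0, 150.0),
            fixation_at(*self._annulus_pt(aois, angle=2.0), 200.0, 150.0),
            fixation_at(*aois.ta.center, 400.0, 300.0),
        ]
        out, events = gm.detect_search(fixations, aois)
        assert out["N_Search"] == 1.0 and out["B_Search"] == 1.0
        assert out["T_Search"] == pytest.approx(300.0)
        assert events == [SearchEvent(0, 2, 300.0)]

    def test_single_annulus_fixation_is_not_search(self, screen):
        aois = self._aois(screen)
        fixations = [
            fixation_at(*self._annulus_pt(aois), 0.0, 150.0),
            fixation_at(*aois.ta.center, 200.0, 300.0),
        ]
        out, _ = gm.detect_search(fixations, aois)
        assert out["N_Search"] == 0.0 and out["B_Search"] == 0.0

    def test_fixation_inside_ta_never_counts(self, screen):
        aois = self._aois(screen)
        fixations = [fixation_at(*aois.ta.center, t * 200.0, 150.0) for t in range(4)]
        out, _ = gm.detect_search(fixations, aois)
        assert out["N_Search"] == 0.0

    def test_fixation_beyond_radius_breaks_run(self, screen):
        aois = self._aois(screen)
        far = self._annulus_pt(aois, frac=2.5, angle=math.pi)  # outside 1.5 L
        fixations = [
            fixation_at(*self._annulus_pt(aois, angle=1.0), 0.0, 150.0),
            fixation_at(*far, 200.0, 150.0),
            fixation_at(*self._annulus_pt(aois, angle=2.0), 400.0, 150.0),
        ]
        out, _ = gm.detect_search(fixations, aois)
        assert out["N_Search"] == 0.0  # two isolated marked fixations, no run


class TestGazeEntropy:
    def test_single_area_gives_zero_entropy(self, screen):
        part = gm.entropy_partition_for("prosaccade", screen)
        fixations = fixations_in_cells([2, 2, 2, 2], part, screen)
        sge, gte = gm.gaze_entropy(fixations, part)
        assert sge == 0.0 and gte == 0.0

    def test_hand_computed_half_quarter_quarter(self, screen):
        """p = (1/2, 1/4, 1/4) -> SGE = 1.5 bits, normalized by log2(6)."""
        part = gm.entropy_partition_for("prosaccade", screen)
        fixations = fixations_in_cells([0, 0, 1, 2], part, screen)
        sge, _ = gm.gaze_entropy(fixations, part)
        assert sge == pytest.approx(1.5 / math.log2(6))

    def test_deterministic_alternation_has_zero_gte(self, screen):
        part = gm.entropy_partition_for("prosaccade", screen)
        fixations = fixations_in_cells([0, 1, 0, 1, 0, 1], part, screen)
        sge, gte = gm.gaze_entropy(fixations, part)
        assert sge > 0
        assert gte == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_sequences(self, screen):
        """Normalized entropies equal a naive summation oracle to 1e-12."""
        rng = np.random.default_rng(99)
        for task in ("prosaccade", "antisaccade"):
            part = gm.entropy_partition_for(task, screen)
            for _ in range(500):
                cells = rng.integers(0, part.n_areas, rng.integers(1, 30)).tolist()
                fixations = fixations_in_cells(cells, part, screen)
                sge, gte = gm.gaze_entropy(fixations, part)
                o_sge, o_gte = naive_entropies(cells, part.n_areas)
                assert sge == pytest.approx(o_sge / part.h_max_bits, abs=1e-12)
                assert gte == pytest.approx(o_gte / part.h_max_bits, abs=1e-12)

    def test_entropy_bounds_and_uniform_maximum(self, screen):
        part = gm.entropy_partition_for("prosaccade", screen)
        rng = np.random.default_rng(5)
        for _ in range(200):
            cells = rng.integers(0, 6, rng.integers(1, 40)).tolist()
            sge, gte = gm.gaze_entropy(fixations_in_cells(cells, part, screen), part)
            assert -1e-12 <= sge <= 1 + 1e-12
            assert -1e-12 <= gte <= 1 + 1e-12
        sge, _ = gm.gaze_entropy(fixations_in_cells([0, 1, 2, 3, 4, 5], part, screen), part)
        assert sge == pytest.approx(1.0)

    def test_no_fixations_gives_missing(self, screen):
        part = gm.entropy_partition_for("prosaccade", screen)
        sge, gte = gm.gaze_entropy([], part)
        assert np.isnan(sge) and np.isnan(gte)


class TestTrialAssembly:
    def test_applicable_subset_per_task(self, screen):
        rng = np.random.default_rng(2)
        for task in ("prosaccade", "antisaccade", "delayed"):
            ecc = 15
            spec = gm.TrialSpec(task, ecc, "right")
            samples, _ = gm.generate_trial(gm.TD_PRESET, spec, screen, rng, 250)
            rec = gm.TrialRecord("p", 1, spec, samples)
            rec.fixations, rec.saccades = gm.detect_events(samples, screen)
            aois = gm.build_aois(spec, screen)
            out = gm.compute_trial_biomarkers(rec, aois)
            assert set(out) == {m.name for m in gm.applicable_metrics(task)}
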