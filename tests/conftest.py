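import numpy as np
import pandas as pd
import pytest

import gazemarkers as gm
from gazemarkers.pipeline import extract_trial_table, synthetic_feature_table


@pytest.fixture(scope="session")
def screen():
    return gm.ScreenConfig(sampling_rate_hz=250)


def make_trial_frame(samples: pd.DataFrame, spec: gm.TrialSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wrap one trial's relative-time samples as a (gaze, markers) pair."""
    g = samples.copy()
    g.insert(0, "trial_id", 1)
    g.insert(0, "participant_id", "p1")
    m = pd.DataFrame(
        [
            {
                "participant_id": "p1",
                "trial_id": 1,
                "task": spec.task,
                "eccentricity_deg": spec.eccentricity_deg,
                "side": spec.side,
                "order": spec.order,
                "onset_ms": 0.0,
            }
        ]
    )
    return g, m


@pytest.fixture(scope="session")
def cohort_50():
    """End-to-end extraction of the default presets at n=50 per group.

    Shared by the classifier-separation and parameter-recovery checks so
    the (expensive) generation + extraction happens once.
    """
    config = gm.CohortConfig(n_td=50, n_adhd=50, seed=20240501)
    table, trials = synthetic_feature_table(config, return_trials=True)
    return table, trials


def fixation_at(x, y, t_start=0.0, duration=100.0):
    return gm.FixationEvent(t_start=t_start, t_end=t_start + duration, x=x, y=y)
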