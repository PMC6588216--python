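import numpy as np
import pandas as pd
import pytest

from handselect import synthetic as syn
from handselect.geometry import FrameSpec, build_grid


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def frame_spec():
    return FrameSpec()


@pytest.fixture(scope="session")
def small_cohort_params():
    """A 6-subject cohort for fast end-to-end runs."""
    return syn.CohortParams(n_subjects=6)


@pytest.fixture(scope="session")
def small_study(small_cohort_params):
    return syn.simulate_study(small_cohort_params, seed=7)


@pytest.fixture(scope="session")
def default_study():
    """Full 27-subject study, no trajectories (shared across tests)."""
    return syn.simulate_study(seed=11, include_trajectories=False)


def step_policy_trials(grid, threshold, subject_id="S01", condition="NW",
                       n_rounds=1, block_label="NW1"):
    """Deterministic trials: right hand iff stimulus x > threshold."""
    rows = []
    idx = 0
    for _ in range(n_rounds):
        for row, col in grid.presentations():
            x = grid.x_of(col)
            rows.append(
                {
                    "subject_id": subject_id,
                    "block_label": block_label,
                    "condition": condition,
                    "trial_index": idx,
                    "row": row,
                    "column_index": col,
                    "stim_x_unity": x,
                    "stim_y_unity": grid.y_of(row),
                    "onset_s": float(idx),
                    "contact_s": float(idx) + 0.5,
                    "hand": "R" if x > threshold else "L",
                    "left_start_x_cm": -2.75,
                    "left_start_y_cm": 0.0,
                    "right_start_x_cm": 2.75,
                    "right_start_y_cm": 0.0,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


@pytest.fixture
def make_step_trials(grid):
    def _make(threshold, **kwargs):
        return step_policy_trials(grid, threshold, **kwargs)

    return _make
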