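"""Session structure: randomized trial sequences and the in-task speed score.

A session is one training round of 10 stimuli followed by four experimental
rounds of 48 stimuli each. The first two experimental rounds are performed
without the weighted glove (NW1, NW2), the last two with a 500 g weight on
the non-dominant left hand (W1, W2); block order is fixed, mirroring the
uncounterbalanced design. Within a round, the canonical presentation
multiset is shuffled uniformly. Each stimulus appears exactly 2 s after the
previous contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import StimulusGrid, build_grid

__all__ = ["TrialPlan", "make_session", "session_score", "BLOCKS", "EXPERIMENTAL_BLOCKS"]

#: Block labels in session order, with their weight condition.
BLOCKS = (
    ("TRAIN", "NW"),
    ("NW1", "NW"),
    ("NW2", "NW"),
    ("W1", "W"),
    ("W2", "W"),
)
EXPERIMENTAL_BLOCKS = ("NW1", "NW2", "W1", "W2")

#: Inter-stimulus interval: seconds between contact and the next onset.
DEFAULT_ITI_S = 2.0


@dataclass(frozen=True)
class TrialPlan:
    """Ordered presentations for one block."""

    block_label: str
    condition: str  # "NW" or "W"
    items: tuple[tuple[int, int], ...]  # (row, column_index) in order
    iti_seconds: float = DEFAULT_ITI_S
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.items)


def make_session(
    seed: int,
    grid: StimulusGrid | None = None,
    n_training: int = 10,
    iti_seconds: float = DEFAULT_ITI_S,
) -> list[TrialPlan]:
    """Build the five block plans (TRAIN, NW1, NW2, W1, W2) for one session.

    Each experimental block is an independent uniform shuffle of the
    canonical 48-presentation multiset; the training block draws
    ``n_training`` distinct cells without replacement. Sub-seeding is by
    (session seed, block index), so identical seeds give identical sessions.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    grid = grid or build_grid()
    canonical = grid.presentations()
    plans: list[TrialPlan] = []
    for block_index, (label, condition) in enumerate(BLOCKS):
        rng = np.random.default_rng([seed, block_index])
        if label == "TRAIN":
            cells = list(grid.cells())
            idx = rng.choice(len(cells), size=n_training, replace=False)
            items = tuple(cells[i] for i in idx)
        else:
            items = tuple(canonical[i] for i in rng.permutation(len(canonical)))
        plans.append(
            TrialPlan(label, condition, items, iti_seconds=iti_seconds, seed=seed)
        )
    return plans


def session_score(
    trials: pd.DataFrame,
    trajectories: pd.DataFrame,
) -> float:
    """The in-task score: summed centimetres-per-second across trials.

    For each trial the contacting hand's sampled trajectory gives a path
    length (summed Euclidean segment lengths, in cm) which is divided by the
    movement duration (span of the trajectory timestamps); the score is the
    sum of these speeds. Trials are matched on (subject_id, block_label,
    trial_index).

    Raises
    ------
    ValueError
        If any trial's movement duration is not positive; the offending
        trial identifiers are listed.
    """
    if len(trials) == 0:
        return 0.0
    key = ["subject_id", "block_label", "trial_index"]
    total = 0.0
    bad: list[tuple] = []
    grouped = trajectories.groupby(key, sort=False)
    for ident in trials[key].itertuples(index=False, name=None):
        samples = grouped.get_group(ident).sort_values("t_s")
        xyz = samples[["x_cm", "y_cm", "z_cm"]].to_numpy(float)
        t = samples["t_s"].to_numpy(float)
        duration = t[-1] - t[0]
        if duration <= 0:
            bad.append(ident)
            continue
        path = float(np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1)))
        total += path / duration
    if bad:
        raise ValueError(f"non-positive movement duration for trials: {bad[:10]}")
    return total
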