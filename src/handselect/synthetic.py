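"""Synthetic cohort simulator for the VR reaching paradigm.

No raw participant data is distributed with studies of this paradigm, so the
package ships a generative model of the whole experiment: a cohort of
simulated right-handers whose hand choices follow a logistic psychometric
function of the stimulus' horizontal position, with a lapse rate, whose
movements follow a minimum-jerk profile with Fitts-law movement times, and
whose covariates (Edinburgh Handedness Inventory items, grip strength) match
the group moments reported for the paradigm's validation cohort.

The logistic location parameter -- the *switch point* -- is the generative
counterpart of the reaching frequency midline (RFM) statistic estimated by
:mod:`handselect.rfm`: it is the horizontal position at which left- and
right-hand use balance. Group-level switch-point defaults are the published
Unity-unit RFM values per row and weight condition, and between-subject
spreads derive from the published standard errors (SEM x sqrt(27)).

A subject's six cell-wise switch points share a common subject component
(correlation ``subject_corr`` across cells, default 0.9): hand preference is
a stable trait, and the published within-subject condition-contrast SEMs are
an order of magnitude smaller than the between-subject cell SEMs, which is
only possible with strongly correlated cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .geometry import FrameSpec, StimulusGrid, build_grid, start_positions_visual2d
from .paradigm import make_session

__all__ = [
    "CohortParams",
    "SubjectParams",
    "SimulatedStudy",
    "choose_hand",
    "expected_midpoint",
    "sample_cohort",
    "simulate_rfm_midpoints",
    "simulate_study",
    "simulate_trial",
]

ROWS = (1, 2, 3)
CONDITIONS = ("NW", "W")

#: Published group-mean switch points, Unity units, keyed (row, condition).
#: Row 1 is the bottom row.
DEFAULT_SWITCH_MEANS = {
    (1, "NW"): -0.1240,
    (2, "NW"): -0.2257,
    (3, "NW"): -0.2125,
    (1, "W"): -0.2255,
    (2, "W"): -0.2568,
    (3, "W"): -0.2838,
}

#: Published SEMs of the cell means over 27 subjects, Unity units.
DEFAULT_SWITCH_SEMS = {
    (1, "NW"): 0.0307,
    (2, "NW"): 0.0362,
    (3, "NW"): 0.0514,
    (1, "W"): 0.0368,
    (2, "W"): 0.0462,
    (3, "W"): 0.0553,
}


def _default_switch_sds() -> dict[tuple[int, str], float]:
    return {k: v * math.sqrt(27) for k, v in DEFAULT_SWITCH_SEMS.items()}


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters for one simulated participant."""

    subject_id: str
    switch_point: dict[tuple[int, str], float]
    slope_sigma: float
    lapse: float
    rt_mean: float
    rt_sd: float
    speed_factor_weighted_left: float
    start_jitter_sd: float
    grip_left: float
    grip_right: float
    ehi_items: tuple[int, ...]  # 12 scored items, each in {-2,-1,1,2}
    ehi_broom: int = 2  # discarded before scoring

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.2:
            raise ValueError("lapse must lie in [0, 0.2]")
        if self.slope_sigma <= 0:
            raise ValueError("slope_sigma must be positive")
        if self.grip_left <= 0 or self.grip_right <= 0:
            raise ValueError("grip strengths must be positive")


@dataclass(frozen=True)
class CohortParams:
    """Group-level generative parameters.

    Switch-point means and between-subject SDs default to the published
    group RFM table (means) and its SEMs scaled by sqrt(27) (SDs). All
    other values are configuration choices, not published quantities.
    """

    n_subjects: int = 27
    switch_means: dict[tuple[int, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SWITCH_MEANS)
    )
    switch_sds: dict[tuple[int, str], float] = field(default_factory=_default_switch_sds)
    subject_corr: float = 0.9
    slope_sigma_mean: float = 0.5
    slope_sigma_sd: float = 0.1
    lapse_mean: float = 0.02
    lapse_sd: float = 0.02
    rt_mean_mean: float = 0.35
    rt_mean_sd: float = 0.05
    rt_sd: float = 0.05
    speed_factor_weighted_left_mean: float = 1.15
    speed_factor_weighted_left_sd: float = 0.05
    start_jitter_sd_cm: float = 0.25
    fitts_a_s: float = 0.2
    fitts_b_s_per_bit: float = 0.15
    grip_left_mean_kg: float = 39.6
    grip_left_sd_kg: float = 10.7
    grip_diff_mean_kg: float = -3.6  # left minus right
    grip_diff_sd_kg: float = 4.0
    ehi_mean: float = 92.02
    ehi_sd: float = 8.6
    ehi_min: float = 80.77
    ehi_max: float = 100.0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        sds = [*self.switch_sds.values(), self.slope_sigma_sd, self.lapse_sd,
               self.rt_mean_sd, self.grip_left_sd_kg, self.grip_diff_sd_kg,
               self.start_jitter_sd_cm, self.ehi_sd]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.subject_corr <= 1.0:
            raise ValueError("subject_corr must lie in [0, 1]")


def _sub_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-style sub-stream: independent of the order streams are drawn."""
    return np.random.default_rng([int(seed), *map(int, key)])


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# EHI item construction


_EHI_COMPOSITIONS: list[tuple[float, list[tuple[int, int, int, int]]]] | None = None


def _ehi_composition_table() -> list[tuple[float, list[tuple[int, int, int, int]]]]:
    """All achievable laterality indices for 12 items, with their compositions."""
    global _EHI_COMPOSITIONS
    if _EHI_COMPOSITIONS is None:
        by_li: dict[float, list[tuple[int, int, int, int]]] = {}
        for n_l2 in range(13):
            for n_l1 in range(13 - n_l2):
                for n_r1 in range(13 - n_l2 - n_l1):
                    n_r2 = 12 - n_l2 - n_l1 - n_r1
                    r = 2 * n_r2 + n_r1
                    l = 2 * n_l2 + n_l1
                    li = round(100.0 * (r - l) / (r + l), 9)
                    by_li.setdefault(li, []).append((n_l2, n_l1, n_r1, n_r2))
        _EHI_COMPOSITIONS = sorted(by_li.items())
    return _EHI_COMPOSITIONS


def _ehi_items_for_index(target: float, rng: np.random.Generator) -> tuple[int, ...]:
    """12 item responses in {-2,-1,1,2} whose laterality index best matches target.

    The laterality index is 100*(R - L)/(R + L) over the per-side tallies,
    where an item response of +2/+1 contributes 2/1 to R and -1/-2 likewise
    to L. The best-matching achievable index is found in a precomputed
    composition table; ties are broken at random.
    """
    table = _ehi_composition_table()
    best_li = min(table, key=lambda kv: abs(kv[0] - target))
    comps = best_li[1]
    n_l2, n_l1, n_r1, n_r2 = comps[rng.integers(len(comps))]
    items = [-2] * n_l2 + [-1] * n_l1 + [1] * n_r1 + [2] * n_r2
    rng.shuffle(items)
    return tuple(items)


def _truncated_normal(mean: float, sd: float, lo: float, hi: float,
                      rng: np.random.Generator) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


# ---------------------------------------------------------------------------
# Cohort sampling


def sample_cohort(params: CohortParams, seed: int) -> list[SubjectParams]:
    """Draw ``n_subjects`` parameter sets from the group-level distributions.

    Each subject's six switch points are ``mu_cell + sd_cell * (sqrt(rho) * u
    + sqrt(1 - rho) * e_cell)`` with a shared standard-normal ``u`` per
    subject, giving cell-wise variance ``sd_cell**2`` and between-cell
    correlation ``rho = subject_corr``. Simulated EHI indices are drawn from
    a normal truncated to the configured range, then realized as 12 item
    responses (plus a discarded broom item).
    """
    params.validate()
    cohort: list[SubjectParams] = []
    rho = params.subject_corr
    for i in range(params.n_subjects):
        rng = _sub_rng(seed, i, 0)
        u = rng.normal()
        switch = {
            cell: params.switch_means[cell]
            + params.switch_sds[cell]
            * (math.sqrt(rho) * u + math.sqrt(1.0 - rho) * rng.normal())
            for cell in params.switch_means
        }
        slope = max(0.05, rng.normal(params.slope_sigma_mean, params.slope_sigma_sd))
        lapse = float(np.clip(rng.normal(params.lapse_mean, params.lapse_sd), 0.0, 0.2))
        rt_mean = max(0.1, rng.normal(params.rt_mean_mean, params.rt_mean_sd))
        speed = max(1.0, rng.normal(params.speed_factor_weighted_left_mean,
                                    params.speed_factor_weighted_left_sd))
        grip_left = max(5.0, rng.normal(params.grip_left_mean_kg, params.grip_left_sd_kg))
        grip_diff = rng.normal(params.grip_diff_mean_kg, params.grip_diff_sd_kg)
        grip_right = max(5.0, grip_left - grip_diff)
        ehi_target = _truncated_normal(params.ehi_mean, params.ehi_sd,
                                       params.ehi_min, params.ehi_max, rng)
        items = _ehi_items_for_index(ehi_target, rng)
        cohort.append(
            SubjectParams(
                subject_id=f"S{i + 1:02d}",
                switch_point=switch,
                slope_sigma=float(slope),
                lapse=lapse,
                rt_mean=float(rt_mean),
                rt_sd=params.rt_sd,
                speed_factor_weighted_left=float(speed),
                start_jitter_sd=params.start_jitter_sd_cm,
                grip_left=float(grip_left),
                grip_right=float(grip_right),
                ehi_items=items,
                ehi_broom=int(rng.choice([1, 2])),
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Choice model


def p_right(stim_x_unity, switch_point, slope_sigma, lapse):
    """P(right hand) under the logistic-with-lapse choice model."""
    return lapse / 2.0 + (1.0 - lapse) * expit((stim_x_unity - switch_point) / slope_sigma)


def choose_hand(
    stim_x_unity: float,
    row: int,
    condition: str,
    subject: SubjectParams,
    rng: np.random.Generator,
) -> str:
    """Sample 'L' or 'R' for a stimulus at ``stim_x_unity`` (midline-relative)."""
    m = subject.switch_point[(row, condition)]
    p = p_right(stim_x_unity, m, subject.slope_sigma, subject.lapse)
    return "R" if rng.random() < p else "L"


def expected_midpoint(
    switch_point: float,
    slope_sigma: float,
    lapse: float = 0.0,
    grid: StimulusGrid | None = None,
) -> tuple[float, float, float]:
    """Large-sample expectation of the RFM midpoint under the choice model.

    Enumerates the canonical 16-presentation column multiset of one row and
    returns ``(midpoint, mean_left_x, mean_right_x)`` where the hand means
    are probability-weighted averages of the touched positions:
    ``E[x | R] = sum_c w_c x_c p_c / sum_c w_c p_c`` and analogously for the
    left hand. This is the limit the empirical midpoint converges to as
    trials per cell grow.
    """
    grid = grid or build_grid()
    x = np.array([grid.x_of(c) for c in range(grid.n_columns)], float)
    w = np.array(grid.repeats, float)
    p = p_right(x, switch_point, slope_sigma, lapse)
    mean_right = float(np.sum(w * x * p) / np.sum(w * p))
    mean_left = float(np.sum(w * x * (1.0 - p)) / np.sum(w * (1.0 - p)))
    return (mean_left + mean_right) / 2.0, mean_left, mean_right


# ---------------------------------------------------------------------------
# Trial-level simulation


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile 10*tau^3 - 15*tau^4 + 6*tau^5."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_trial(
    entry: tuple[int, int],
    subject: SubjectParams,
    condition: str,
    rng: np.random.Generator,
    spec: FrameSpec | None = None,
    grid: StimulusGrid | None = None,
    onset_s: float = 0.0,
    fitts_a_s: float = 0.2,
    fitts_b_s_per_bit: float = 0.15,
    with_trajectory: bool = True,
) -> tuple[dict, list[dict]]:
    """Simulate one reach: hand choice, timing, and a minimum-jerk trajectory.

    Movement time follows Fitts' law, ``MT = a + b * log2(2 D / W)`` with D
    the real-space distance from the chosen hand's (jittered) start to the
    stimulus centre and W the real-space cube width; the left hand is slowed
    by the subject's weighted-glove factor in weighted blocks. The
    contacting hand's path is a minimum-jerk segment sampled at 20 Hz from
    the start position to a uniformly drawn contact point inside the cube,
    in screen centimetres (x, y) with virtual depth on z.

    Returns the trial record (dict) and the list of trajectory samples.
    """
    spec = spec or FrameSpec()
    grid = grid or build_grid()
    row, col = entry
    stim_x = grid.x_of(col)
    stim_y = grid.y_of(row)

    starts = start_positions_visual2d(spec)
    half_sq = 2.3 / 2.0  # start squares are 2.3 cm on the screen
    jitter = {
        hand: (
            float(np.clip(rng.normal(0.0, subject.start_jitter_sd), -half_sq, half_sq)),
            float(np.clip(rng.normal(0.0, subject.start_jitter_sd), -half_sq, half_sq)),
        )
        for hand in ("L", "R")
    }
    start_cm = {
        hand: (starts[hand][0] + jitter[hand][0], starts[hand][1] + jitter[hand][1])
        for hand in ("L", "R")
    }

    hand = choose_hand(stim_x, row, condition, subject, rng)
    rt = max(0.05, rng.normal(subject.rt_mean, subject.rt_sd))

    # Real-space reach distance from the chosen hand's actual start position.
    gain = spec.real_gain
    sx_cm = stim_x * spec.screen_cm_per_unit
    sy_cm = spec.bottom_row_y_cm + stim_y * spec.screen_cm_per_unit
    hx, hy = start_cm[hand]
    d_real = gain * math.sqrt((sx_cm - hx) ** 2 + (sy_cm - hy) ** 2 + spec.depth_cm**2)
    w_real = grid.cube_edge * spec.real_cm_per_unit
    mt = fitts_a_s + fitts_b_s_per_bit * math.log2(2.0 * d_real / w_real)
    if hand == "L" and condition == "W":
        mt *= subject.speed_factor_weighted_left
    contact_s = onset_s + rt + mt

    record = {
        "subject_id": subject.subject_id,
        "condition": condition,
        "row": row,
        "column_index": col,
        "stim_x_unity": stim_x,
        "stim_y_unity": stim_y,
        "onset_s": onset_s,
        "contact_s": contact_s,
        "hand": hand,
        "left_start_x_cm": start_cm["L"][0],
        "left_start_y_cm": start_cm["L"][1],
        "right_start_x_cm": start_cm["R"][0],
        "right_start_y_cm": start_cm["R"][1],
    }

    samples: list[dict] = []
    if with_trajectory:
        # Contact point uniform inside the cube's closed extent, screen cm.
        half_cm = grid.cube_edge / 2.0 * spec.screen_cm_per_unit
        ex = sx_cm + rng.uniform(-half_cm, half_cm)
        ey = sy_cm + rng.uniform(-half_cm, half_cm)
        t0 = onset_s + rt
        t = np.arange(t0, contact_s, 0.05)
        if t[-1] < contact_s:
            t = np.append(t, contact_s)
        tau = (t - t0) / mt
        prof = _minimum_jerk(tau)
        xs = hx + (ex - hx) * prof
        ys = hy + (ey - hy) * prof
        zs = spec.depth_cm * prof
        samples = [
            {"t_s": float(ti), "x_cm": float(xi), "y_cm": float(yi), "z_cm": float(zi)}
            for ti, xi, yi, zi in zip(t, xs, ys, zs)
        ]
    return record, samples


class SimulatedStudy(NamedTuple):
    """Bundle of simulator outputs: long-format trial, covariate, trajectory tables."""

    trials: pd.DataFrame
    covariates: pd.DataFrame
    trajectories: pd.DataFrame


def simulate_study(
    params: CohortParams | None = None,
    seed: int = 0,
    include_trajectories: bool = True,
    spec: FrameSpec | None = None,
    grid: StimulusGrid | None = None,
) -> SimulatedStudy:
    """Simulate the full experiment for a cohort.

    Every subject runs a training block of 10 and four experimental blocks
    of 48 trials in fixed NW1, NW2, W1, W2 order; stimulus onsets chain at
    exactly 2 s after the previous contact. Per-subject and per-block random
    streams are derived from the master seed by counter-based splitting, so
    results do not depend on simulation order.
    """
    params = params or CohortParams()
    spec = spec or FrameSpec()
    grid = grid or build_grid()
    cohort = sample_cohort(params, seed)

    trial_rows: list[dict] = []
    traj_rows: list[dict] = []
    cov_rows: list[dict] = []
    for i, subject in enumerate(cohort):
        session = make_session(_sub_seed(seed, i, 90), grid=grid)
        for block_index, plan in enumerate(session):
            rng = _sub_rng(seed, i, 1 + block_index)
            clock = 0.0
            for trial_index, entry in enumerate(plan.items):
                record, samples = simulate_trial(
                    entry,
                    subject,
                    plan.condition,
                    rng,
                    spec=spec,
                    grid=grid,
                    onset_s=clock,
                    fitts_a_s=params.fitts_a_s,
                    fitts_b_s_per_bit=params.fitts_b_s_per_bit,
                    with_trajectory=include_trajectories,
                )
                record["block_label"] = plan.block_label
                record["trial_index"] = trial_index
                trial_rows.append(record)
                for s in samples:
                    traj_rows.append(
                        {
                            "subject_id": subject.subject_id,
                            "block_label": plan.block_label,
                            "trial_index": trial_index,
                            **s,
                        }
                    )
                clock = record["contact_s"] + plan.iti_seconds
        cov_rows.append(
            {
                "subject_id": subject.subject_id,
                **{f"ehi_{j + 1:02d}": v for j, v in enumerate(subject.ehi_items)},
                "ehi_13": subject.ehi_broom,
                "grip_left_kg": subject.grip_left,
                "grip_right_kg": subject.grip_right,
            }
        )

    columns = [
        "subject_id", "block_label", "condition", "trial_index", "row",
        "column_index", "stim_x_unity", "stim_y_unity", "onset_s", "contact_s",
        "hand", "left_start_x_cm", "left_start_y_cm", "right_start_x_cm",
        "right_start_y_cm",
    ]
    trials = pd.DataFrame(trial_rows)[columns]
    trajectories = pd.DataFrame(
        traj_rows,
        columns=["subject_id", "block_label", "trial_index", "t_s", "x_cm", "y_cm", "z_cm"],
    )
    covariates = pd.DataFrame(cov_rows)
    return SimulatedStudy(trials, covariates, trajectories)


# ---------------------------------------------------------------------------
# Vectorized choice-only path for calibration studies


def simulate_rfm_midpoints(
    params: CohortParams | None = None,
    seed: int = 0,
    n_reps: int = 1,
    grid: StimulusGrid | None = None,
    degenerate: str = "impute",
) -> np.ndarray:
    """Cell-wise RFM midpoints for ``n_reps`` simulated cohorts, vectorized.

    Simulates only the hand choices (32 Bernoulli trials per subject, row and
    condition: the 16-presentation column multiset over two blocks) and
    computes the per-cell midpoint estimator directly. This is the fast path
    used by type-I-error and power calibration, where trajectories and
    timing are irrelevant.

    Returns an array of shape ``(n_reps, n_subjects, 3, 2)`` (rows ordered
    bottom to top, conditions NW then W). Cells where one hand was never
    chosen are imputed at that hand's outermost column (+/-3) when
    ``degenerate="impute"``, else left NaN.
    """
    params = params or CohortParams()
    params.validate()
    grid = grid or build_grid()
    rng = np.random.default_rng([int(seed), 424243])

    x_cols = np.array([grid.x_of(c) for c in range(grid.n_columns)], float)
    x_round = np.repeat(x_cols, grid.repeats)  # 16 presentations per row
    x_trials = np.tile(x_round, 2)  # two blocks per condition -> 32
    n_t = x_trials.size

    n, r = params.n_subjects, n_reps
    mu = np.array(
        [[params.switch_means[(row, cond)] for cond in CONDITIONS] for row in ROWS]
    )  # (3, 2)
    sd = np.array(
        [[params.switch_sds[(row, cond)] for cond in CONDITIONS] for row in ROWS]
    )
    rho = params.subject_corr
    u = rng.standard_normal((r, n, 1, 1))
    e = rng.standard_normal((r, n, 3, 2))
    m = mu + sd * (math.sqrt(rho) * u + math.sqrt(1.0 - rho) * e)

    slope = np.maximum(
        0.05, rng.normal(params.slope_sigma_mean, params.slope_sigma_sd, (r, n, 1, 1))
    )
    lapse = np.clip(rng.normal(params.lapse_mean, params.lapse_sd, (r, n, 1, 1)), 0.0, 0.2)

    p = lapse[..., None] / 2.0 + (1.0 - lapse[..., None]) * expit(
        (x_trials - m[..., None]) / slope[..., None]
    )  # (r, n, 3, 2, 32)
    right = rng.random(p.shape) < p

    n_right = right.sum(axis=-1)
    n_left = n_t - n_right
    sum_x_right = np.sum(np.where(right, x_trials, 0.0), axis=-1)
    sum_x_left = x_trials.sum() - sum_x_right
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_right = sum_x_right / n_right
        mean_left = sum_x_left / n_left
    if degenerate == "impute":
        mean_right = np.where(n_right == 0, x_cols[-1], mean_right)
        mean_left = np.where(n_left == 0, x_cols[0], mean_left)
    return (mean_left + mean_right) / 2.0
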