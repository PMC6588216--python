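"""Reaching-frequency-midline estimation and descriptive choice analyses.

The reaching frequency midline (RFM) is the horizontal position at which a
participant's left- and right-hand use balances. Within each stimulus row,
weight condition and participant, the touched stimulus positions (midline-
relative Unity units) are averaged separately for each hand; the midpoint of
the two hand means estimates the RFM. Dividing the midpoint by the grid's
horizontal range and multiplying by 100 yields the literal percent-of-range
variant; both are reported, and conversions to screen and real-space
centimetres follow the geometry module's scales exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import FrameSpec, StimulusGrid, build_grid
from .paradigm import EXPERIMENTAL_BLOCKS

__all__ = [
    "compute_rfm",
    "crossover_counts",
    "percent_change",
    "ipsilateral_use",
    "start_position_histogram",
    "blockwise_rfm",
    "CrossoverResult",
    "StartHistogram",
]

_HANDS = ("L", "R")


def _experimental(trials: pd.DataFrame) -> pd.DataFrame:
    """Restrict to experimental blocks (the training round is never analysed)."""
    if "block_label" in trials.columns:
        return trials[trials["block_label"].isin(EXPERIMENTAL_BLOCKS)]
    return trials


def compute_rfm(
    trials: pd.DataFrame,
    grid: StimulusGrid | None = None,
    spec: FrameSpec | None = None,
    range_units: float | None = None,
    degenerate_policy: str = "drop",
) -> pd.DataFrame:
    """Per (subject, row, condition) RFM table.

    Parameters
    ----------
    trials : DataFrame
        Trial-level records with ``subject_id``, ``row``, ``condition``,
        ``hand`` and ``stim_x_unity`` (midline-relative). Training-block
        rows are ignored.
    range_units : float, optional
        Horizontal stimulus range used for the percent-of-range variant;
        defaults to the grid's centre-to-centre span (6 Unity units).
    degenerate_policy : {"drop", "impute"}
        Handling of cells where one hand was never used: ``drop`` leaves the
        midpoint missing; ``impute`` substitutes the unused hand's mean at
        that hand's outermost column. Either way the cell is flagged.

    Returns
    -------
    DataFrame with columns ``subject_id, row, condition, n_left, n_right,
    mean_left_x, mean_right_x, midpoint, percent_of_range,
    midpoint_visual2d_cm, midpoint_real3d_cm, degenerate``.
    """
    grid = grid or build_grid()
    spec = spec or FrameSpec()
    range_units = range_units if range_units is not None else grid.horizontal_range
    if degenerate_policy not in ("drop", "impute"):
        raise ValueError(f"unknown degenerate_policy {degenerate_policy!r}")

    trials = _experimental(trials)
    cols = [
        "subject_id", "row", "condition", "n_left", "n_right", "mean_left_x",
        "mean_right_x", "midpoint", "percent_of_range", "midpoint_visual2d_cm",
        "midpoint_real3d_cm", "degenerate",
    ]
    if len(trials) == 0:
        return pd.DataFrame(columns=cols)
    bad = set(trials["hand"]) - set(_HANDS)
    if bad:
        raise ValueError(f"unknown hand labels: {sorted(bad)}")

    rows: list[dict] = []
    for (subject, row, condition), g in trials.groupby(
        ["subject_id", "row", "condition"], sort=True
    ):
        x = g["stim_x_unity"].to_numpy(float)
        is_right = (g["hand"] == "R").to_numpy()
        n_right = int(is_right.sum())
        n_left = int(len(g) - n_right)
        mean_right = float(x[is_right].mean()) if n_right else np.nan
        mean_left = float(x[~is_right].mean()) if n_left else np.nan
        degenerate = n_left == 0 or n_right == 0
        if degenerate and degenerate_policy == "impute":
            if n_left == 0:
                mean_left = grid.column_offsets[0]
            if n_right == 0:
                mean_right = grid.column_offsets[-1]
        midpoint = (mean_left + mean_right) / 2.0
        rows.append(
            {
                "subject_id": subject,
                "row": int(row),
                "condition": condition,
                "n_left": n_left,
                "n_right": n_right,
                "mean_left_x": mean_left,
                "mean_right_x": mean_right,
                "midpoint": midpoint,
                "percent_of_range": midpoint / range_units * 100.0,
                "midpoint_visual2d_cm": midpoint * spec.screen_cm_per_unit,
                "midpoint_real3d_cm": midpoint * spec.real_cm_per_unit,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def group_rfm(rfm_table: pd.DataFrame, include_degenerate: bool = False) -> pd.DataFrame:
    """Group mean and SEM of subject midpoints per (row, condition).

    Degenerate cells are excluded from group averaging by default. The
    group statistic is the mean of subject midpoints (not a pooled-trial
    estimate), consistent with SEMs over subjects.
    """
    t = rfm_table if include_degenerate else rfm_table[~rfm_table["degenerate"]]
    t = t.dropna(subset=["midpoint"])
    out = (
        t.groupby(["row", "condition"])["midpoint"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "midpoint_mean", "sem": "midpoint_sem", "count": "n_subjects"})
    )
    return out


@dataclass(frozen=True)
class CrossoverResult:
    """Right-hand reaches into left hemispace, per position and in total."""

    by_position: pd.DataFrame  # columns: stim_x_unity, row, count
    total: int
    condition: str | None = None


def crossover_counts(trials: pd.DataFrame, condition: str | None = None) -> CrossoverResult:
    """Count right-hand contacts to stimuli left of the midline.

    The x = 0 column belongs to neither hemispace and never counts as a
    crossover. Counts are reported per horizontal position and row, plus
    the grand total.
    """
    t = _experimental(trials)
    if condition is not None:
        t = t[t["condition"] == condition]
    cross = t[(t["hand"] == "R") & (t["stim_x_unity"] < 0)]
    by_pos = (
        cross.groupby(["stim_x_unity", "row"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["stim_x_unity", "row"])
        .reset_index(drop=True)
    )
    return CrossoverResult(by_position=by_pos, total=int(len(cross)), condition=condition)


def percent_change(old: float, new: float) -> float:
    """Percent change (new - old)/old * 100, rounded to one decimal."""
    return round((new - old) / old * 100.0, 1)


def choice_map(trials: pd.DataFrame) -> pd.DataFrame:
    """Fraction of right-hand contacts per (row, column, condition).

    Returns per-subject fractions and the group mean in long format with
    columns ``row, column_index, stim_x_unity, condition, subject_id,
    n_trials, frac_right`` plus group rows where ``subject_id`` is ``__group__``.
    """
    t = _experimental(trials)
    keys = ["row", "column_index", "stim_x_unity", "condition"]
    per_subj = (
        t.assign(is_right=(t["hand"] == "R").astype(float))
        .groupby(keys + ["subject_id"])
        .agg(n_trials=("is_right", "size"), frac_right=("is_right", "mean"))
        .reset_index()
    )
    group = (
        per_subj.groupby(keys)
        .agg(n_trials=("n_trials", "sum"), frac_right=("frac_right", "mean"))
        .reset_index()
        .assign(subject_id="__group__")
    )
    return pd.concat([per_subj, group], ignore_index=True)[
        keys + ["subject_id", "n_trials", "frac_right"]
    ]


def ipsilateral_use(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fraction of ipsilateral hand use in each hemispace, per subject and group.

    Right-hand ipsilateral use is the fraction of right-hand contacts among
    stimuli with x > 0; left-hand likewise among x < 0. The x = 0 column is
    excluded from both hemispaces. Subjects with no trials in a hemispace
    are flagged and excluded from that side's group mean.
    """
    t = _experimental(trials)
    rows = []
    for subject, g in t.groupby("subject_id"):
        right_side = g[g["stim_x_unity"] > 0]
        left_side = g[g["stim_x_unity"] < 0]
        rows.append(
            {
                "subject_id": subject,
                "right_ipsilateral": (right_side["hand"] == "R").mean()
                if len(right_side)
                else np.nan,
                "left_ipsilateral": (left_side["hand"] == "L").mean()
                if len(left_side)
                else np.nan,
                "missing_right_hemispace": len(right_side) == 0,
                "missing_left_hemispace": len(left_side) == 0,
            }
        )
    per_subject = pd.DataFrame(rows)
    group = {
        "right_ipsilateral": float(per_subject["right_ipsilateral"].mean()),
        "left_ipsilateral": float(per_subject["left_ipsilateral"].mean()),
    }
    return per_subject, group


@dataclass(frozen=True)
class StartHistogram:
    """Group-mean 2D probability maps of hand positions at trial onset."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    maps: dict[str, np.ndarray]  # hand -> (nx, ny) probabilities, mean over subjects
    n_excluded: int  # trials lacking start coordinates


def start_position_histogram(trials: pd.DataFrame, bin_cm: float = 0.25) -> StartHistogram:
    """2D histograms of start positions (visual2D cm), averaged over subjects.

    Each subject contributes a per-hand histogram normalized to sum to 1;
    the group map is the unweighted mean of subject maps (and therefore also
    sums to 1 per hand). Bins are half-open ``[lo, hi)`` of width
    ``bin_cm``; edges are aligned to multiples of the bin width and shared
    across hands and subjects.
    """
    t = _experimental(trials)
    coord_cols = {
        "L": ("left_start_x_cm", "left_start_y_cm"),
        "R": ("right_start_x_cm", "right_start_y_cm"),
    }
    all_cols = [c for pair in coord_cols.values() for c in pair]
    complete = t.dropna(subset=all_cols)
    n_excluded = len(t) - len(complete)

    def edges(vals: np.ndarray) -> np.ndarray:
        lo = np.floor(vals.min() / bin_cm) * bin_cm
        hi = np.ceil(vals.max() / bin_cm) * bin_cm + bin_cm / 2.0
        return np.arange(lo, hi + bin_cm, bin_cm)

    xs = complete[[coord_cols["L"][0], coord_cols["R"][0]]].to_numpy(float).ravel()
    ys = complete[[coord_cols["L"][1], coord_cols["R"][1]]].to_numpy(float).ravel()
    x_edges, y_edges = edges(xs), edges(ys)

    maps: dict[str, np.ndarray] = {}
    for hand, (cx, cy) in coord_cols.items():
        subj_maps = []
        for _, g in complete.groupby("subject_id"):
            h, _, _ = np.histogram2d(
                g[cx].to_numpy(float), g[cy].to_numpy(float), bins=(x_edges, y_edges)
            )
            total = h.sum()
            if total > 0:
                subj_maps.append(h / total)
        maps[hand] = (
            np.mean(subj_maps, axis=0)
            if subj_maps
            else np.zeros((len(x_edges) - 1, len(y_edges) - 1))
        )
    return StartHistogram(x_edges=x_edges, y_edges=y_edges, maps=maps, n_excluded=n_excluded)


def blockwise_rfm(
    trials: pd.DataFrame,
    grid: StimulusGrid | None = None,
    spec: FrameSpec | None = None,
) -> pd.DataFrame:
    """Group-mean RFM midpoint per experimental block in session order.

    Midpoints are computed per subject, row and block, averaged across rows
    within a subject, then averaged across subjects. Used to check that the
    condition effect appears at the NW-to-W block transition rather than
    drifting over time.
    """
    t = _experimental(trials).copy()
    out_rows = []
    for label in EXPERIMENTAL_BLOCKS:
        block = t[t["block_label"] == label]
        if len(block) == 0:
            out_rows.append({"block_label": label, "midpoint_mean": np.nan,
                             "midpoint_sem": np.nan, "n_subjects": 0})
            continue
        table = compute_rfm(block, grid=grid, spec=spec)
        per_subject = (
            table.dropna(subset=["midpoint"]).groupby("subject_id")["midpoint"].mean()
        )
        out_rows.append(
            {
                "block_label": label,
                "midpoint_mean": float(per_subject.mean()),
                "midpoint_sem": float(per_subject.sem()) if len(per_subject) > 1 else np.nan,
                "n_subjects": int(len(per_subject)),
            }
        )
    return pd.DataFrame(out_rows)
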