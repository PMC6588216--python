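"""File formats, configuration and report assembly.

Data files are UTF-8 CSV with comma delimiters and "." decimals. Hand
positions are stored in midline-relative screen centimetres (visual2D) and
stimulus identity in Unity units; all frame conversions happen in
:mod:`handselect.geometry`. Values are written at full precision in data
files and rounded only in the human-readable report (Unity to 4 decimals,
centimetres to 2).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .geometry import FrameSpec, StimulusGrid, build_grid

__all__ = [
    "TRIAL_COLUMNS",
    "TRAJECTORY_COLUMNS",
    "RunConfig",
    "SchemaError",
    "read_trials",
    "read_covariates",
    "write_report",
]

log = logging.getLogger("handselect")

TRIAL_COLUMNS: dict[str, type] = {
    "subject_id": str,
    "block_label": str,
    "condition": str,
    "trial_index": int,
    "row": int,
    "column_index": int,
    "stim_x_unity": float,
    "stim_y_unity": float,
    "onset_s": float,
    "contact_s": float,
    "hand": str,
    "left_start_x_cm": float,
    "left_start_y_cm": float,
    "right_start_x_cm": float,
    "right_start_y_cm": float,
}

TRAJECTORY_COLUMNS = ("subject_id", "block_label", "trial_index", "t_s", "x_cm", "y_cm", "z_cm")

VALID_HANDS = {"L", "R"}
VALID_CONDITIONS = {"NW", "W"}


class SchemaError(ValueError):
    """A data file does not match its declared schema."""


class FramesConfig(BaseModel):
    """JSON counterpart of :class:`handselect.geometry.FrameSpec`."""

    model_config = ConfigDict(extra="forbid")

    screen_cm_per_unit: float = 2.4
    hand_separation_real_cm: float = 22.1
    hand_separation_virtual_cm: float = 5.53
    hand_separation_screen_cm: float = 5.5
    depth_cm: float = 5.37

    def to_spec(self) -> FrameSpec:
        return FrameSpec(
            screen_cm_per_unit=self.screen_cm_per_unit,
            hand_separation_real_cm=self.hand_separation_real_cm,
            hand_separation_virtual_cm=self.hand_separation_virtual_cm,
            hand_separation_screen_cm=self.hand_separation_screen_cm,
            depth_cm=self.depth_cm,
        )


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    range_units: float | None = None  # None -> grid's horizontal span
    degenerate_policy: str = "drop"
    histogram_bin_cm: float = 0.25


class CohortConfig(BaseModel):
    """Overrides for the synthetic cohort; unset fields keep library defaults."""

    model_config = ConfigDict(extra="forbid")

    n_subjects: int = 27
    subject_corr: float = 0.9
    slope_sigma_mean: float = 0.5
    lapse_mean: float = 0.02
    start_jitter_sd_cm: float = 0.25
    fitts_a_s: float = 0.2
    fitts_b_s_per_bit: float = 0.15


class RunConfig(BaseModel):
    """Validated JSON run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    frames: FramesConfig = Field(default_factory=FramesConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    iti_seconds: float = 2.0
    n_training: int = 10
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        cfg = cls.model_validate_json(text)
        log.info("config %s loaded (sha256 %s)", path,
                 hashlib.sha256(text.encode()).hexdigest()[:12])
        return cfg


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col, typ in TRIAL_COLUMNS.items():
        if typ is float:
            out[col] = pd.to_numeric(out[col], errors="coerce")
        elif typ is int:
            out[col] = pd.to_numeric(out[col], errors="coerce")
        else:
            out[col] = out[col].astype(str)
    return out


def read_trials(
    path: str | Path,
    grid: StimulusGrid | None = None,
    recentre: bool = True,
) -> pd.DataFrame:
    """Read and validate a trials.csv file.

    Checks the exact column set, hand and condition labels, trial timing
    (contact after onset) and grid membership of stimulus coordinates.
    Stimulus x recorded in absolute scene coordinates (centred on the
    scene's ``center_x``) is re-centred to midline-relative units when
    ``recentre`` is set and the coordinates are off-grid but on-grid after
    subtracting the centre. Malformed rows are collected and reported with
    their line numbers (first 10 listed).
    """
    grid = grid or build_grid()
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    extra = set(df.columns) - set(TRIAL_COLUMNS)
    if missing or extra:
        raise SchemaError(
            f"{path}: column mismatch (missing {sorted(missing)}, unexpected {sorted(extra)})"
        )
    df = _coerce(df)

    offsets = np.asarray(grid.column_offsets)
    if recentre:
        x = df["stim_x_unity"].to_numpy(float)
        on_grid = np.isclose(x[:, None], offsets, atol=1e-6).any(axis=1)
        shifted = np.isclose((x - grid.center_x)[:, None], offsets, atol=1e-6).any(axis=1)
        # a file is either midline-relative or scene-centred as a whole
        if not on_grid.all() and shifted.all():
            df["stim_x_unity"] -= grid.center_x
            log.info("re-centred %d scene-coordinate stimulus rows", len(df))

    problems: list[tuple[int, str]] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        if rec.hand not in VALID_HANDS:
            problems.append((line, f"invalid hand {rec.hand!r}"))
        elif rec.condition not in VALID_CONDITIONS:
            problems.append((line, f"invalid condition {rec.condition!r}"))
        elif not (1 <= rec.row <= grid.n_rows) or not (0 <= rec.column_index < grid.n_columns):
            problems.append((line, f"invalid cell ({rec.row}, {rec.column_index})"))
        elif not np.isclose(rec.stim_x_unity, grid.x_of(int(rec.column_index)), atol=1e-6):
            problems.append((line, f"stim_x_unity {rec.stim_x_unity} off-grid for column "
                                   f"{rec.column_index}"))
        elif not rec.contact_s > rec.onset_s:
            problems.append((line, "contact_s must exceed onset_s"))
    if problems:
        shown = "; ".join(f"line {ln}: {msg}" for ln, msg in problems[:10])
        raise SchemaError(f"{path}: {len(problems)} malformed rows ({shown})")
    df["row"] = df["row"].astype(int)
    df["column_index"] = df["column_index"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    log.info("read %d trials, %d subjects from %s", len(df), df["subject_id"].nunique(), path)
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"subject_id", "grip_left_kg", "grip_right_kg"} | {
        f"ehi_{i + 1:02d}" for i in range(13)
    }
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing covariate columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Report assembly


def _round_cols(df: pd.DataFrame, rules: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, nd in rules.items():
        if col in out.columns:
            out[col] = out[col].round(nd)
    return out


def table1_analogue(rfm_table: pd.DataFrame, spec: FrameSpec | None = None) -> pd.DataFrame:
    """Group RFM table: rows (and their mean) x condition x three frames.

    Means and SEMs of subject midpoints, reported in Unity units (4
    decimals) and screen/real centimetres (2 decimals).
    """
    spec = spec or FrameSpec()
    t = rfm_table[~rfm_table["degenerate"]].dropna(subset=["midpoint"])
    per_subj_rows = t.groupby(["subject_id", "row", "condition"])["midpoint"].mean().reset_index()
    per_subj_mean = (
        t.groupby(["subject_id", "condition"])["midpoint"].mean().reset_index().assign(row="mean")
    )
    combined = pd.concat([per_subj_rows, per_subj_mean], ignore_index=True)
    out = []
    for (row, cond), g in combined.groupby(["row", "condition"]):
        mean_u = g["midpoint"].mean()
        sem_u = g["midpoint"].sem()
        out.append(
            {
                "row": row,
                "condition": cond,
                "unity_mean": round(mean_u, 4),
                "unity_sem": round(sem_u, 4),
                "visual2d_cm_mean": round(mean_u * spec.screen_cm_per_unit, 2),
                "visual2d_cm_sem": round(sem_u * spec.screen_cm_per_unit, 3),
                "real3d_cm_mean": round(mean_u * spec.real_cm_per_unit, 2),
                "real3d_cm_sem": round(sem_u * spec.real_cm_per_unit, 3),
                "n_subjects": int(len(g)),
            }
        )
    return pd.DataFrame(out)


def write_report(results: Any, out_dir: str | Path) -> dict[str, Path]:
    """Write the analysis bundle for a fitted :class:`HandSelectionResults`.

    Emits a group RFM table, correlation listing, crossover and choice-map
    CSVs, per-block midpoints, exclusions, and ``summary.json`` with the
    rANOVA and headline descriptives. Missing analyses are marked missing
    in the summary rather than silently omitted.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame | None) -> None:
        if df is None:
            return
        p = out / name
        df.to_csv(p, index=False)
        written[name] = p

    emit("rfm_table.csv", results.rfm_table)
    emit("table1.csv", results.group_table)
    emit("choice_map.csv", results.choice_map)
    emit("blockwise.csv", results.blockwise)
    emit("ipsilateral.csv", results.ipsilateral_per_subject)
    emit("contrasts.csv", _round_cols(
        pd.concat([results.contrasts_height, results.contrasts_weight], ignore_index=True),
        {"mean_diff": 4, "sem": 4, "t": 4, "p": 4, "bonferroni_threshold": 4},
    ))
    if results.correlations is not None:
        emit("correlations.csv", _round_cols(results.correlations, {"r": 2}))
    if results.exclusions is not None:
        emit("exclusions.csv", results.exclusions)

    crossovers = pd.concat(
        [
            r.by_position.assign(condition=cond)
            for cond, r in results.crossovers.items()
        ],
        ignore_index=True,
    )
    emit("crossovers.csv", crossovers)

    summary: dict[str, Any] = {
        "n_subjects": results.anova.n_subjects if results.anova else None,
        "anova": {
            name: {
                "ss": e.ss, "df": e.df, "ss_error": e.ss_error, "df_error": e.df_error,
                "F": round(e.F, 4), "p": round(e.p, 4),
                "mauchly_p": None if e.mauchly_p is None else round(e.mauchly_p, 4),
                "gg_epsilon": None if e.gg_epsilon is None else round(e.gg_epsilon, 4),
                "gg_applied": e.gg_applied,
                "p_reported": round(e.p_reported, 4),
            }
            for name, e in results.anova.effects.items()
        }
        if results.anova
        else "missing",
        "crossovers": {cond: r.total for cond, r in results.crossovers.items()},
        "crossover_percent_change": results.crossover_change,
        "ipsilateral_group": results.ipsilateral_group,
        "correlation_bonferroni_threshold": results.correlation_threshold
        if results.correlations is not None
        else "missing",
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    written["summary.json"] = out / "summary.json"
    log.info("report written to %s (%d files)", out, len(written))
    return written
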