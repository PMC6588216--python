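"""Model/results interface over the hand-selection analysis pipeline.

`HandSelectionModel` is constructed from trial-level reaching data (plus
optional participant covariates); `fit()` runs the full analysis -- RFM
estimation, the 3 x 2 repeated-measures ANOVA with sphericity handling,
paired contrasts, crossover / ipsilateral / start-position descriptives and
the exploratory correlation matrix -- and returns a `HandSelectionResults`
carrying the estimates, their uncertainties and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as hio
from . import rfm as hrfm
from . import stats as hstats
from .geometry import FrameSpec, StimulusGrid, build_grid

__all__ = ["HandSelectionModel", "HandSelectionResults"]


class HandSelectionModel:
    """Hand-selection analysis of a VR reaching dataset.

    Parameters
    ----------
    trials : DataFrame
        Trial-level records following the trials.csv schema (one row per
        stimulus presentation, midline-relative Unity stimulus coordinates,
        hand label, start positions in screen cm).
    covariates : DataFrame, optional
        Per-subject EHI item responses and grip strengths; enables EHI
        scoring, exclusions and the 13-variable correlation matrix.
    manual_exclusions : dict, optional
        subject_id -> reason strings for self-report-based exclusions.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        grid: StimulusGrid | None = None,
        frame_spec: FrameSpec | None = None,
        range_units: float | None = None,
        degenerate_policy: str = "drop",
        histogram_bin_cm: float = 0.25,
        manual_exclusions: dict[str, str] | None = None,
    ) -> None:
        self.trials = trials
        self.covariates = covariates
        self.grid = grid or build_grid()
        self.frame_spec = frame_spec or FrameSpec()
        self.range_units = range_units
        self.degenerate_policy = degenerate_policy
        self.histogram_bin_cm = histogram_bin_cm
        self.manual_exclusions = manual_exclusions or {}

    @classmethod
    def from_csv(
        cls,
        trials_path: str | Path,
        covariates_path: str | Path | None = None,
        **kwargs: Any,
    ) -> "HandSelectionModel":
        """Build the model from validated trials.csv / covariates.csv files."""
        trials = hio.read_trials(trials_path)
        cov = hio.read_covariates(covariates_path) if covariates_path else None
        return cls(trials, covariates=cov, **kwargs)

    def fit(self) -> "HandSelectionResults":
        """Run the full analysis and return the results object."""
        trials = self.trials
        profiles = exclusions = None
        if self.covariates is not None:
            profiles = hstats.score_profiles(self.covariates)
            included, exclusions = hstats.apply_exclusions(profiles, self.manual_exclusions)
            trials = trials[trials["subject_id"].isin(included)]
            profiles = profiles[profiles["subject_id"].isin(included)]

        rfm_table = hrfm.compute_rfm(
            trials,
            grid=self.grid,
            spec=self.frame_spec,
            range_units=self.range_units,
            degenerate_policy=self.degenerate_policy,
        )
        anova = hstats.rm_anova_3x2(rfm_table)
        contrasts_height = hstats.paired_contrasts(rfm_table, "height")
        contrasts_weight = hstats.paired_contrasts(rfm_table, "weight")

        crossovers = {
            cond: hrfm.crossover_counts(trials, cond) for cond in ("NW", "W")
        }
        change = (
            hrfm.percent_change(crossovers["NW"].total, crossovers["W"].total)
            if crossovers["NW"].total > 0
            else float("nan")
        )
        ipsi_subj, ipsi_group = hrfm.ipsilateral_use(trials)
        start_hist = hrfm.start_position_histogram(trials, bin_cm=self.histogram_bin_cm)
        blockwise = hrfm.blockwise_rfm(trials, grid=self.grid, spec=self.frame_spec)
        cmap = hrfm.choice_map(trials)

        correlations = corr_threshold = None
        if profiles is not None:
            variables = hstats.build_correlation_variables(rfm_table, profiles)
            correlations, corr_threshold = hstats.correlation_matrix(variables)

        return HandSelectionResults(
            model=self,
            rfm_table=rfm_table,
            group_table=hio.table1_analogue(rfm_table, self.frame_spec),
            anova=anova,
            contrasts_height=contrasts_height,
            contrasts_weight=contrasts_weight,
            crossovers=crossovers,
            crossover_change=change,
            ipsilateral_per_subject=ipsi_subj,
            ipsilateral_group=ipsi_group,
            start_histogram=start_hist,
            blockwise=blockwise,
            choice_map=cmap,
            profiles=profiles,
            exclusions=exclusions,
            correlations=correlations,
            correlation_threshold=corr_threshold,
        )


@dataclass
class HandSelectionResults:
    """Fitted hand-selection analysis.

    Attributes hold the per-subject RFM table, the group table in all three
    reporting frames, the rANOVA decomposition, paired contrasts, and the
    descriptive analyses; ``summary()`` renders the headline results.
    """

    model: HandSelectionModel
    rfm_table: pd.DataFrame
    group_table: pd.DataFrame
    anova: hstats.RmAnovaResult
    contrasts_height: pd.DataFrame
    contrasts_weight: pd.DataFrame
    crossovers: dict[str, hrfm.CrossoverResult]
    crossover_change: float
    ipsilateral_per_subject: pd.DataFrame
    ipsilateral_group: dict[str, float]
    start_histogram: hrfm.StartHistogram
    blockwise: pd.DataFrame
    choice_map: pd.DataFrame
    profiles: pd.DataFrame | None = None
    exclusions: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    correlation_threshold: float | None = None

    def condition_shift_cm(self, frame: str = "real3D") -> float:
        """Group mean RFM shift, weighted minus non-weighted, in cm."""
        spec = self.model.frame_spec
        t = self.rfm_table[~self.rfm_table["degenerate"]].dropna(subset=["midpoint"])
        per = t.groupby(["subject_id", "condition"])["midpoint"].mean().unstack()
        shift_unity = float((per["W"] - per["NW"]).mean())
        scale = {"unity3D": 1.0, "visual2D": spec.screen_cm_per_unit,
                 "real3D": spec.real_cm_per_unit}[frame]
        return shift_unity * scale

    def summary(self) -> str:
        """Human-readable headline table of the fitted analysis."""
        lines = [
            "Hand-selection analysis (reaching frequency midline)",
            "=" * 56,
            f"subjects analysed: {self.anova.n_subjects}"
            + (f" (dropped: {', '.join(self.anova.dropped_subjects)})"
               if self.anova.dropped_subjects else ""),
            "",
            "Group RFM midpoints (mean over subjects):",
        ]
        row_names = {1: "bottom", 2: "middle", 3: "top", "mean": "mean"}
        for _, r in self.group_table.iterrows():
            lines.append(
                f"  {row_names.get(r['row'], r['row']):>6} {r['condition']:>2}: "
                f"{r['unity_mean']:+.4f} unity  "
                f"{r['visual2d_cm_mean']:+.2f} cm screen  "
                f"{r['real3d_cm_mean']:+.2f} cm real"
            )
        lines.append("")
        lines.append("Repeated-measures ANOVA (3 height x 2 weight):")
        for name, e in self.anova.effects.items():
            gg = " [GG]" if e.gg_applied else ""
            lines.append(
                f"  {name:>11}: F({e.df:g},{e.df_error:g}) = {e.F:.4f}, "
                f"p = {e.p_reported:.4f}{gg}"
            )
        lines.append("")
        lines.append(
            f"Condition shift (W - NW): {self.condition_shift_cm('real3D'):+.2f} cm real3D"
        )
        lines.append(
            f"Crossovers: NW {self.crossovers['NW'].total}, W {self.crossovers['W'].total} "
            f"({self.crossover_change:+.1f}%)"
        )
        lines.append(
            "Ipsilateral use: right "
            f"{100 * self.ipsilateral_group['right_ipsilateral']:.0f}%, left "
            f"{100 * self.ipsilateral_group['left_ipsilateral']:.0f}%"
        )
        if self.correlations is not None:
            n_sig = int(self.correlations["sig_bonferroni"].sum())
            lines.append(
                f"Correlations: {len(self.correlations)} pairs, "
                f"{n_sig} significant at Bonferroni threshold "
                f"{self.correlation_threshold:.3g}"
            )
        return "\n".join(lines)

    def save_report(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the CSV/JSON report bundle (see :func:`handselect.io.write_report`)."""
        return hio.write_report(self, out_dir)

    # ------------------------------------------------------------------
    # Plotting

    def plot_choice_map(self, condition: str = "NW", ax=None):
        """Colour-coded group fraction of right-hand use per grid cell."""
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        g = self.choice_map
        g = g[(g["subject_id"] == "__group__") & (g["condition"] == condition)]
        sc = ax.scatter(
            g["stim_x_unity"], g["row"], c=g["frac_right"], cmap="coolwarm",
            vmin=0, vmax=1, s=120, marker="s",
        )
        ax.set_xlabel("stimulus x (Unity units, midline-relative)")
        ax.set_ylabel("row (1 = bottom)")
        ax.set_title(f"Right-hand use, {condition} condition")
        plt.colorbar(sc, ax=ax, label="fraction right hand")
        return ax

    def plot_crossovers(self, ax=None):
        """Per-position crossover counts for both conditions."""
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        width = 0.08
        for offset, (cond, res) in zip((-width / 2, width / 2), self.crossovers.items()):
            agg = res.by_position.groupby("stim_x_unity")["count"].sum()
            ax.bar(agg.index + offset, agg.values, width=width, label=cond)
        ax.set_xlabel("stimulus x (Unity units)")
        ax.set_ylabel("right-hand crossovers")
        ax.legend()
        return ax
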