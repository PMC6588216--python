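"""Inferential procedures for the hand-selection analysis.

The primary inference is a 3 (height) x 2 (weight) factorial repeated-
measures ANOVA on per-subject RFM midpoints, with Mauchly sphericity tests
and Greenhouse-Geisser correction where sphericity is violated, followed by
Bonferroni-corrected paired contrasts. The sums of squares are computed by
explicit within-subject decomposition rather than delegated to a fitting
library, so the arithmetic can be verified against an independent
design-matrix oracle. An exploratory 13-variable Pearson correlation matrix
and Edinburgh Handedness Inventory scoring/exclusion round out the study's
statistical procedure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "RmAnovaResult",
    "rm_anova_3x2",
    "paired_contrasts",
    "correlation_matrix",
    "build_correlation_variables",
    "score_ehi",
    "score_profiles",
    "apply_exclusions",
    "EHI_CUTOFF",
]

#: Right-handedness inclusion cutoff on the EHI laterality index
#: (the 4th right decile).
EHI_CUTOFF = 74.0

ROWS = (1, 2, 3)
CONDITIONS = ("NW", "W")


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


@dataclass(frozen=True)
class EffectResult:
    """One within-subject effect from the factorial rANOVA."""

    ss: float
    df: float
    ss_error: float
    df_error: float
    F: float
    p: float
    mauchly_w: float | None = None
    mauchly_chi2: float | None = None
    mauchly_p: float | None = None
    gg_epsilon: float | None = None
    df_corrected: float | None = None
    df_error_corrected: float | None = None
    p_corrected: float | None = None
    gg_applied: bool = False

    @property
    def p_reported(self) -> float:
        """Greenhouse-Geisser-corrected p where the correction was applied."""
        return self.p_corrected if self.gg_applied else self.p


@dataclass(frozen=True)
class RmAnovaResult:
    """3 x 2 repeated-measures ANOVA decomposition."""

    effects: dict[str, EffectResult]
    ss_subject: float
    ss_total: float
    n_subjects: int
    dropped_subjects: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append(
                {
                    "effect": name,
                    "ss": e.ss,
                    "df": e.df,
                    "ss_error": e.ss_error,
                    "df_error": e.df_error,
                    "F": e.F,
                    "p": e.p,
                    "mauchly_w": e.mauchly_w,
                    "mauchly_p": e.mauchly_p,
                    "gg_epsilon": e.gg_epsilon,
                    "gg_applied": e.gg_applied,
                    "p_reported": e.p_reported,
                }
            )
        return pd.DataFrame(rows)


def _pivot_midpoints(rfm_table: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Subjects x 3 x 2 midpoint array; returns (Y, kept_ids, dropped_ids)."""
    wide = rfm_table.pivot_table(
        index="subject_id", columns=["row", "condition"], values="midpoint", aggfunc="first"
    )
    needed = [(r, c) for r in ROWS for c in CONDITIONS]
    for cell in needed:
        if cell not in wide.columns:
            wide[cell] = np.nan
    wide = wide[needed]
    complete = wide.dropna()
    dropped = [s for s in wide.index if s not in complete.index]
    y = complete.to_numpy(float).reshape(len(complete), len(ROWS), len(CONDITIONS))
    return y, list(complete.index), dropped


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (normalized Helmert rows)."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1.0)
        h[i] /= np.linalg.norm(h[i])
    return h


def _f_ratio(ss: float, df: float, ss_err: float, df_err: float,
             scale: float = 1.0) -> tuple[float, float]:
    """F and p with guards for numerically zero strata.

    ``scale`` is a reference sum of squares (the total SS) against which a
    stratum is judged to be zero; a zero effect over a zero error stratum
    reports F = 0, p = 1.
    """
    tiny = 1e-12 * max(scale, 1e-30)
    if ss_err <= tiny:
        if ss <= tiny:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss / df) / (ss_err / df_err)
    return float(f), float(sps.f.sf(f, df, df_err))


def _mauchly(t_mat: np.ndarray, n: int, scale: float = 1.0) -> tuple[float, float, float]:
    """Mauchly's sphericity test on a contrast covariance matrix.

    ``t_mat`` is C S C' for orthonormal contrasts C and sample covariance S
    over n subjects; ``scale`` is a reference variance (e.g. trace of S) used
    to detect a numerically zero stratum, which carries no evidence against
    sphericity and returns (1, 0, 1). Otherwise returns (W, chi2, p) using
    the standard chi-square approximation.
    """
    p = t_mat.shape[0]
    if np.trace(t_mat) <= 1e-12 * max(scale, 1e-30):
        return 1.0, 0.0, 1.0
    eig = np.linalg.eigvalsh(t_mat)
    eig = np.clip(eig, 1e-300, None)
    w = float(np.prod(eig) / (np.mean(eig) ** p))
    if w <= 0 or not math.isfinite(w):
        return 1.0, 0.0, 1.0
    d = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * (n - 1))
    chi2 = -(n - 1) * d * math.log(w)
    df = p * (p + 1) / 2.0 - 1.0
    pval = float(sps.chi2.sf(chi2, df))
    return w, float(chi2), pval


def _gg_epsilon(t_mat: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the contrast covariance matrix."""
    p = t_mat.shape[0]
    denom = p * np.trace(t_mat @ t_mat)
    if denom <= 1e-300:
        return 1.0
    return float(np.trace(t_mat) ** 2 / denom)


def _sphericity_block(
    scores: np.ndarray, ss: float, df: float, ss_err: float, df_err: float,
    alpha: float = 0.05, scale_ss: float = 1.0,
) -> EffectResult:
    """Assemble an EffectResult with Mauchly/GG handling for a >=2 df effect.

    ``scores`` is the n x k matrix of per-subject level scores whose
    orthonormal contrasts span the effect stratum.
    """
    n, k = scores.shape
    f, p = _f_ratio(ss, df, ss_err, df_err, scale=scale_ss)
    c = _orthonormal_contrasts(k)
    s = np.cov(scores, rowvar=False, ddof=1)
    t_mat = c @ s @ c.T
    w, chi2, mauchly_p = _mauchly(t_mat, n, scale=float(np.trace(s)))
    eps = _gg_epsilon(t_mat)
    applied = mauchly_p < alpha
    df_c, df_ec = eps * df, eps * df_err
    p_c = float(sps.f.sf(f, df_c, df_ec)) if np.isfinite(f) and f > 0 else p
    return EffectResult(
        ss=ss, df=df, ss_error=ss_err, df_error=df_err, F=float(f), p=p,
        mauchly_w=w, mauchly_chi2=chi2, mauchly_p=mauchly_p, gg_epsilon=eps,
        df_corrected=df_c, df_error_corrected=df_ec, p_corrected=p_c,
        gg_applied=bool(applied),
    )


def rm_anova_3x2(rfm_table: pd.DataFrame, alpha_sphericity: float = 0.05) -> RmAnovaResult:
    """3 (height) x 2 (weight) repeated-measures ANOVA on RFM midpoints.

    Subjects missing any of the six cells are dropped (and listed in the
    result). Each within-subject effect is tested against its own
    effect-by-subject error stratum. Mauchly's test is run for the height
    main effect and the interaction (the 1-df weight effect cannot violate
    sphericity); the Greenhouse-Geisser correction is applied per effect
    when the corresponding Mauchly p falls below ``alpha_sphericity``.
    """
    y, kept, dropped = _pivot_midpoints(rfm_table)
    n = len(kept)
    if n < 2:
        raise ValueError(
            f"need at least 2 complete subjects, got {n}; dropped: {dropped}"
        )
    a, b = len(ROWS), len(CONDITIONS)
    gm = y.mean()
    a_means = y.mean(axis=(0, 2))
    b_means = y.mean(axis=(0, 1))
    ab_means = y.mean(axis=0)
    s_means = y.mean(axis=(1, 2))
    as_means = y.mean(axis=2)
    bs_means = y.mean(axis=1)

    ss_a = n * b * float(np.sum((a_means - gm) ** 2))
    ss_b = n * a * float(np.sum((b_means - gm) ** 2))
    ss_ab = n * float(np.sum((ab_means - a_means[:, None] - b_means[None, :] + gm) ** 2))
    ss_s = a * b * float(np.sum((s_means - gm) ** 2))
    ss_as = b * float(
        np.sum((as_means - a_means[None, :] - s_means[:, None] + gm) ** 2)
    )
    ss_bs = a * float(
        np.sum((bs_means - b_means[None, :] - s_means[:, None] + gm) ** 2)
    )
    ss_total = float(np.sum((y - gm) ** 2))
    ss_abs = ss_total - (ss_a + ss_b + ss_ab + ss_s + ss_as + ss_bs)

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_as, df_bs, df_abs = df_a * (n - 1), df_b * (n - 1), df_ab * (n - 1)

    height = _sphericity_block(as_means, ss_a, df_a, ss_as, df_as,
                               alpha_sphericity, scale_ss=ss_total)

    f_b, p_b = _f_ratio(ss_b, df_b, ss_bs, df_bs, scale=ss_total)
    weight = EffectResult(
        ss=ss_b, df=df_b, ss_error=ss_bs, df_error=df_bs, F=f_b, p=p_b,
    )

    # Interaction stratum: per-subject interaction scores via the double-
    # centred cell matrix; its orthonormal contrasts give the Mauchly input.
    inter_scores = (y - as_means[..., None] - bs_means[:, None, :] + s_means[:, None, None])
    inter_flat = inter_scores.reshape(n, a * b)
    c_ab = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
    s_full = np.cov(y.reshape(n, a * b), rowvar=False, ddof=1)
    t_int = c_ab @ s_full @ c_ab.T
    f_ab, p_ab = _f_ratio(ss_ab, df_ab, ss_abs, df_abs, scale=ss_total)
    w_i, chi2_i, mp_i = _mauchly(t_int, n, scale=float(np.trace(s_full)))
    eps_i = _gg_epsilon(t_int)
    applied_i = mp_i < alpha_sphericity
    p_ab_c = (
        float(sps.f.sf(f_ab, eps_i * df_ab, eps_i * df_abs))
        if np.isfinite(f_ab) and f_ab > 0
        else p_ab
    )
    interaction = EffectResult(
        ss=ss_ab, df=df_ab, ss_error=ss_abs, df_error=df_abs, F=f_ab, p=p_ab,
        mauchly_w=w_i, mauchly_chi2=chi2_i, mauchly_p=mp_i, gg_epsilon=eps_i,
        df_corrected=eps_i * df_ab, df_error_corrected=eps_i * df_abs,
        p_corrected=p_ab_c,
        gg_applied=bool(applied_i),
    )
    _ = inter_flat  # retained for clarity of the stratum definition

    return RmAnovaResult(
        effects={"height": height, "weight": weight, "interaction": interaction},
        ss_subject=ss_s,
        ss_total=ss_total,
        n_subjects=n,
        dropped_subjects=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# Paired contrasts


def paired_contrasts(rfm_table: pd.DataFrame, factor: str = "height") -> pd.DataFrame:
    """Pairwise paired t-tests across the levels of one factor.

    Per subject, level scores are midpoints averaged over the other factor.
    Each pair reports the mean within-subject difference, its SEM, the
    two-sided t and p, and whether p clears the Bonferroni threshold
    0.05/m for the m pairs tested. Zero-variance differences give an
    undefined t (NaN).
    """
    y, kept, _ = _pivot_midpoints(rfm_table)
    n = len(kept)
    if n < 2:
        raise ValueError("need at least 2 complete subjects for paired contrasts")
    if factor == "height":
        scores = {row: y[:, i, :].mean(axis=1) for i, row in enumerate(ROWS)}
    elif factor == "weight":
        scores = {cond: y[:, :, j].mean(axis=1) for j, cond in enumerate(CONDITIONS)}
    else:
        raise ValueError(f"unknown factor {factor!r}")

    pairs = list(itertools.combinations(scores, 2))
    threshold = 0.05 / len(pairs)
    rows = []
    for a_lvl, b_lvl in pairs:
        d = scores[a_lvl] - scores[b_lvl]
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        sem = sd / math.sqrt(n)
        if sd == 0:
            t = p = np.nan
        else:
            t = mean / sem
            p = float(2.0 * sps.t.sf(abs(t), n - 1))
        rows.append(
            {
                "factor": factor,
                "level_a": a_lvl,
                "level_b": b_lvl,
                "mean_diff": mean,
                "sem": sem,
                "t": t,
                "df": n - 1,
                "p": p,
                "bonferroni_threshold": threshold,
                "significant_bonferroni": bool(p < threshold) if not np.isnan(p) else False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exploratory correlations


def correlation_matrix(variables: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pearson correlations over all unordered variable pairs.

    For k variables this yields k(k-1)/2 coefficients (78 for the canonical
    13). p-values use the t transform of r with n - 2 degrees of freedom.
    Pairs involving a constant variable are reported with missing r and p.
    Returns the long-format table and the Bonferroni threshold 0.05/m.
    """
    cols = list(variables.columns)
    if len(variables) < 3:
        raise ValueError("need at least 3 complete subjects for correlations")
    pairs = list(itertools.combinations(cols, 2))
    threshold = 0.05 / len(pairs)
    rows = []
    for va, vb in pairs:
        sub = variables[[va, vb]].dropna()
        x = sub[va].to_numpy(float)
        z = sub[vb].to_numpy(float)
        n = len(sub)
        if n < 3 or x.std(ddof=1) == 0 or z.std(ddof=1) == 0:
            r = p = np.nan
        else:
            r = float(np.corrcoef(x, z)[0, 1])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * math.sqrt((n - 2) / (1.0 - r**2))
                p = float(2.0 * sps.t.sf(abs(t), n - 2))
        rows.append(
            {
                "var_a": va,
                "var_b": vb,
                "n": n,
                "r": r,
                "p": p,
                "sig_uncorrected": bool(p < 0.05) if not np.isnan(p) else False,
                "sig_bonferroni": bool(p < threshold) if not np.isnan(p) else False,
            }
        )
    return pd.DataFrame(rows), threshold


def build_correlation_variables(
    rfm_table: pd.DataFrame, profiles: pd.DataFrame
) -> pd.DataFrame:
    """The canonical 13-variable set for the exploratory correlation matrix.

    EHI laterality index; grip left, right and difference (left - right);
    the six RFM cells (row x condition); and the three per-row condition
    differences (weighted minus non-weighted). Indexed by subject.
    """
    wide = rfm_table.pivot_table(
        index="subject_id", columns=["row", "condition"], values="midpoint", aggfunc="first"
    )
    names = {1: "low", 2: "mid", 3: "high"}
    out = pd.DataFrame(index=wide.index)
    for row in ROWS:
        for cond in CONDITIONS:
            out[f"rfm_{cond.lower()}_{names[row]}"] = wide.get((row, cond))
    for row in ROWS:
        out[f"rfm_d_{names[row]}"] = wide.get((row, "W")) - wide.get((row, "NW"))
    prof = profiles.set_index("subject_id")
    out.insert(0, "ehi", prof["laterality_index"])
    out.insert(1, "grip_left", prof["grip_left_kg"])
    out.insert(2, "grip_right", prof["grip_right_kg"])
    out.insert(3, "grip_diff", prof["grip_diff_kg"])
    return out


# ---------------------------------------------------------------------------
# Edinburgh Handedness Inventory


def score_ehi(
    item_responses, broom_index: int = 12, cutoff: float = EHI_CUTOFF
) -> tuple[float, bool]:
    """Laterality index from the 13-item augmented EHI.

    The broom item (``broom_index``, default last) is discarded before
    scoring because of unreliable responses; the remaining 12 items
    contribute per-side tallies (response +2/+1 adds 2/1 to the right
    tally, -1/-2 likewise to the left). The index is
    ``100 * (R - L) / (R + L)``; inclusion requires it to exceed the cutoff
    (4th right decile, > 74). All-zero tallies give a NaN index and
    exclusion.
    """
    items = list(item_responses)
    if len(items) != 13:
        raise ValueError(f"expected 13 item responses, got {len(items)}")
    kept = [v for i, v in enumerate(items) if i != broom_index]
    right = sum(v for v in kept if v > 0)
    left = sum(-v for v in kept if v < 0)
    if right + left == 0:
        return float("nan"), False
    index = 100.0 * (right - left) / (right + left)
    return index, bool(index > cutoff)


def score_profiles(covariates: pd.DataFrame, broom_index: int = 12,
                   cutoff: float = EHI_CUTOFF) -> pd.DataFrame:
    """Handedness profiles for a covariate table.

    Expects columns ``subject_id``, ``ehi_01`` .. ``ehi_13``,
    ``grip_left_kg``, ``grip_right_kg``; returns per-subject laterality
    index, inclusion flag and grip measures (difference is left - right).
    """
    item_cols = [f"ehi_{i + 1:02d}" for i in range(13)]
    rows = []
    for _, rec in covariates.iterrows():
        li, inc = score_ehi([rec[c] for c in item_cols], broom_index=broom_index,
                            cutoff=cutoff)
        rows.append(
            {
                "subject_id": rec["subject_id"],
                "laterality_index": li,
                "included": inc,
                "grip_left_kg": float(rec["grip_left_kg"]),
                "grip_right_kg": float(rec["grip_right_kg"]),
                "grip_diff_kg": float(rec["grip_left_kg"] - rec["grip_right_kg"]),
            }
        )
    return pd.DataFrame(rows)


def apply_exclusions(
    profiles: pd.DataFrame, manual_flags: dict[str, str] | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Final inclusion list after EHI cutoff and manual exclusions.

    ``manual_flags`` maps subject ids to self-report exclusion reasons
    (e.g. deliberate strategy changes). Returns the included subject ids
    and a table of excluded subjects with reasons.
    """
    manual_flags = manual_flags or {}
    included: list[str] = []
    reasons: list[dict] = []
    for _, rec in profiles.iterrows():
        sid = rec["subject_id"]
        if sid in manual_flags:
            reasons.append({"subject_id": sid, "reason": manual_flags[sid]})
        elif not rec["included"]:
            reasons.append(
                {"subject_id": sid,
                 "reason": f"EHI laterality index {rec['laterality_index']:.2f} "
                           f"not above cutoff"}
            )
        else:
            included.append(sid)
    return included, pd.DataFrame(reasons, columns=["subject_id", "reason"])
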