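"""Inference checks: rANOVA oracle equivalence, contrasts, correlations, EHI."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from handselect import stats as hst


def wide_to_rfm_table(y):
    """Subjects x 3 x 2 array -> the long-format midpoint table."""
    rows = []
    for i in range(y.shape[0]):
        for ri, row in enumerate((1, 2, 3)):
            for ci, cond in enumerate(("NW", "W")):
                rows.append(
                    {"subject_id": f"S{i:03d}", "row": row, "condition": cond,
                     "midpoint": y[i, ri, ci]}
                )
    return pd.DataFrame(rows)


def design_matrix_anova(y):
    """Independent oracle: within-subject effects from explicit contrast matrices.

    For each effect, an orthonormal contrast matrix K over the 6 cell means
    projects each subject's cell vector to effect scores Z = Y K'; then
    SS_effect = n * ||mean(Z)||^2 and SS_error = sum ||Z_i - mean(Z)||^2,
    with F formed from the matching degrees of freedom.
    """
    n = y.shape[0]
    flat = y.reshape(n, 6)  # cell order (row, condition), row-major

    def helmert(k):
        h = np.zeros((k - 1, k))
        for i in range(k - 1):
            h[i, : i + 1] = 1.0
            h[i, i + 1] = -(i + 1.0)
            h[i] /= np.linalg.norm(h[i])
        return h

    c3, c2 = helmert(3), helmert(2)
    j3, j2 = np.ones((1, 3)) / math.sqrt(3), np.ones((1, 2)) / math.sqrt(2)
    effects = {
        "height": (np.kron(c3, j2), 2),
        "weight": (np.kron(j3, c2), 1),
        "interaction": (np.kron(c3, c2), 2),
    }
    out = {}
    for name, (k_mat, df) in effects.items():
        z = flat @ k_mat.T
        zbar = z.mean(axis=0)
        ss = n * float(zbar @ zbar)
        ss_err = float(((z - zbar) ** 2).sum())
        df_err = df * (n - 1)
        f = (ss / df) / (ss_err / df_err)
        p = float(sps.f.sf(f, df, df_err))
        out[name] = (ss, ss_err, f, p)
    return out


class TestRmAnova:
    def test_matches_design_matrix_oracle_on_random_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            y = rng.normal(size=(27, 3, 2))
            res = hst.rm_anova_3x2(wide_to_rfm_table(y))
            oracle = design_matrix_anova(y)
            for name in ("height", "weight", "interaction"):
                ss, ss_err, f, p = oracle[name]
                e = res.effects[name]
                assert e.ss == pytest.approx(ss, rel=1e-8)
                assert e.ss_error == pytest.approx(ss_err, rel=1e-8)
                assert e.F == pytest.approx(f, rel=1e-8)
                assert e.p == pytest.approx(p, rel=1e-8)

    def test_total_ss_decomposes(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(12, 3, 2))
        res = hst.rm_anova_3x2(wide_to_rfm_table(y))
        parts = res.ss_subject + sum(
            e.ss + e.ss_error for e in res.effects.values()
        )
        assert parts == pytest.approx(res.ss_total, rel=1e-8)

    def test_weight_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(20, 3, 2))
        res = hst.rm_anova_3x2(wide_to_rfm_table(y))
        nw = y[:, :, 0].mean(axis=1)
        w = y[:, :, 1].mean(axis=1)
        t, p = sps.ttest_rel(nw, w)
        assert res.effects["weight"].F == pytest.approx(t**2, rel=1e-10)
        assert res.effects["weight"].p == pytest.approx(p, rel=1e-10)

    def test_constant_cells_give_zero_f(self):
        rng = np.random.default_rng(2)
        y = np.repeat(rng.normal(size=(8, 1, 1)), 6, axis=1).reshape(8, 3, 2)
        res = hst.rm_anova_3x2(wide_to_rfm_table(y))
        for e in res.effects.values():
            assert e.F == 0.0
            assert e.p == 1.0

    def test_sphericity_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        base = rng.normal(size=(24, 3))
        # induce heteroscedastic levels so sphericity is genuinely violated
        height_scores = base * np.array([0.3, 1.0, 2.5])
        y = np.stack([height_scores, height_scores + rng.normal(size=(24, 3)) * 0.1], axis=2)
        res = hst.rm_anova_3x2(wide_to_rfm_table(y))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(24), 3),
                "height": np.tile([1, 2, 3], 24),
                "score": y.mean(axis=2).ravel(),
            }
        )
        sph = pingouin.sphericity(long, dv="score", within="height", subject="subject")
        eps = pingouin.epsilon(long, dv="score", within="height", subject="subject",
                               correction="gg")
        e = res.effects["height"]
        assert e.mauchly_w == pytest.approx(float(sph.W), rel=1e-6)
        assert e.mauchly_p == pytest.approx(float(sph.pval), rel=1e-6)
        assert e.gg_epsilon == pytest.approx(float(eps), rel=1e-6)
        assert e.gg_applied == (sph.pval < 0.05)
        assert 0.5 <= e.gg_epsilon <= 1.0  # bounded by 1/(k-1) and 1

    def test_two_level_rm_anova_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        y = rng.normal(size=(15, 3, 2)) + np.array([0.0, 0.4])
        res = hst.rm_anova_3x2(wide_to_rfm_table(y))
        long = wide_to_rfm_table(y)
        pg = pingouin.rm_anova(
            data=long, dv="midpoint", within=["row", "condition"],
            subject="subject_id", detailed=True,
        )
        by_src = {s: g for s, g in pg.groupby("Source")}
        assert res.effects["weight"].F == pytest.approx(
            float(by_src["condition"]["F"].iloc[0]), rel=1e-6
        )
        assert res.effects["height"].F == pytest.approx(
            float(by_src["row"]["F"].iloc[0]), rel=1e-6
        )
        assert res.effects["interaction"].F == pytest.approx(
            float(by_src["row * condition"]["F"].iloc[0]), rel=1e-6
        )

    def test_incomplete_subjects_dropped_and_listed(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(6, 3, 2))
        table = wide_to_rfm_table(y)
        table.loc[(table["subject_id"] == "S002") & (table["row"] == 2), "midpoint"] = np.nan
        res = hst.rm_anova_3x2(table)
        assert res.n_subjects == 5
        assert res.dropped_subjects == ("S002",)

    def test_too_few_subjects_rejected(self):
        y = np.zeros((1, 3, 2))
        with pytest.raises(ValueError, match="at least 2"):
            hst.rm_anova_3x2(wide_to_rfm_table(y))


class TestPowerCalibration:
    @staticmethod
    def _rejection_rate(params, seed, n_reps):
        from handselect import synthetic as syn

        mids = syn.simulate_rfm_midpoints(params, seed=seed, n_reps=n_reps)
        base = wide_to_rfm_table(np.zeros((params.n_subjects, 3, 2)))
        rej = 0
        for rep in mids:
            base["midpoint"] = rep.reshape(-1)
            rej += hst.rm_anova_3x2(base).effects["weight"].p < 0.05
        return rej / n_reps

    def test_weight_effect_detectable_above_null_rate(self):
        """Under the defaults cohort the weight effect rejects far more often
        than under a matched null; the observed rate is reported, not fixed.
        (Boundary-column choice noise caps the absolute power of the
        midpoint estimator; see the methods note.)"""
        from handselect import synthetic as syn

        params = syn.CohortParams()
        null = syn.CohortParams(
            switch_means={(r, c): params.switch_means[(r, "NW")]
                          for r in (1, 2, 3) for c in ("NW", "W")},
            switch_sds={(r, c): params.switch_sds[(r, "NW")]
                        for r in (1, 2, 3) for c in ("NW", "W")},
        )
        power = self._rejection_rate(params, seed=31, n_reps=500)
        null_rate = self._rejection_rate(null, seed=32, n_reps=500)
        print(f"weight-effect rejection rate: {power:.3f} (null {null_rate:.3f})")
        # 500-replicate binomial SEs are ~0.02; demand clear separation
        assert power > null_rate + 6 * 0.02
        assert null_rate < 0.10


class TestPairedContrasts:
    def test_three_height_pairs_and_threshold(self):
        rng = np.random.default_rng(5)
        table = wide_to_rfm_table(rng.normal(size=(10, 3, 2)))
        out = hst.paired_contrasts(table, "height")
        assert len(out) == 3
        assert round(out["bonferroni_threshold"].iloc[0], 4) == 0.0167

    def test_identical_levels_give_zero_difference(self):
        y = np.tile(np.random.default_rng(1).normal(size=(8, 1, 2)), (1, 3, 1))
        out = hst.paired_contrasts(wide_to_rfm_table(y), "height")
        assert np.allclose(out["mean_diff"], 0.0)
        assert out["t"].isna().all()  # zero-variance differences: t undefined

    def test_matches_textbook_formula_and_scipy(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(14, 3, 2))
        out = hst.paired_contrasts(wide_to_rfm_table(y), "weight")
        nw = y[:, :, 0].mean(axis=1)
        w = y[:, :, 1].mean(axis=1)
        d = nw - w
        t_manual = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        t_scipy, p_scipy = sps.ttest_rel(nw, w)
        rec = out.iloc[0]
        assert rec["mean_diff"] == pytest.approx(d.mean(), rel=1e-12)
        assert rec["t"] == pytest.approx(t_manual, rel=1e-12)
        assert rec["t"] == pytest.approx(t_scipy, rel=1e-10)
        assert rec["p"] == pytest.approx(p_scipy, rel=1e-10)


class TestCorrelations:
    def test_13_variables_give_78_pairs_and_threshold(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(27, 13)), columns=[f"v{i}" for i in range(13)])
        out, threshold = hst.correlation_matrix(df)
        assert len(out) == 78
        assert threshold == pytest.approx(0.05 / 78)
        assert float(f"{threshold:.3g}") == 0.000641
        # diagonal excluded: no self-pairs
        assert (out["var_a"] != out["var_b"]).all()

    def test_constant_variable_reported_missing(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        out, _ = hst.correlation_matrix(df)
        assert np.isnan(out["r"].iloc[0])

    def test_p_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(27, 3)), columns=list("abc"))
        out, _ = hst.correlation_matrix(df)
        for _, rec in out.iterrows():
            r, p = sps.pearsonr(df[rec["var_a"]], df[rec["var_b"]])
            assert rec["r"] == pytest.approx(r, rel=1e-10)
            assert rec["p"] == pytest.approx(p, rel=1e-8)

    def test_monte_carlo_recovery_of_true_correlation(self):
        """Bivariate normal rho = 0.9, n = 27: the mean estimate over 2,000
        replicates matches the finite-n expectation of Pearson's r,
        E[r] ~ rho - rho (1 - rho^2)/(2 (n-1)), within 3 standard errors."""
        rho, n, reps = 0.9, 27, 2000
        rng = np.random.default_rng(1234)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        chol = np.linalg.cholesky(cov)
        rs = []
        for _ in range(reps):
            xy = rng.standard_normal((n, 2)) @ chol.T
            df = pd.DataFrame(xy, columns=["x", "y"])
            out, _ = hst.correlation_matrix(df)
            rs.append(out["r"].iloc[0])
        rs = np.array(rs)
        expected = rho - rho * (1 - rho**2) / (2 * (n - 1))
        se = rs.std(ddof=1) / math.sqrt(reps)
        assert abs(rs.mean() - expected) < 3 * se

    def test_canonical_variable_set_composition(self, default_study):
        from handselect.rfm import compute_rfm

        table = compute_rfm(default_study.trials)
        profiles = hst.score_profiles(default_study.covariates)
        variables = hst.build_correlation_variables(table, profiles)
        assert variables.shape[1] == 13
        assert list(variables.columns[:4]) == ["ehi", "grip_left", "grip_right", "grip_diff"]
        # condition differences are weighted minus non-weighted
        assert np.allclose(
            variables["rfm_d_low"], variables["rfm_w_low"] - variables["rfm_nw_low"],
            equal_nan=True,
        )


class TestEhi:
    def test_all_right_items_score_100(self):
        li, included = hst.score_ehi([2] * 13)
        assert li == 100.0
        assert included

    def test_balanced_items_score_zero_and_exclude(self):
        li, included = hst.score_ehi([2] * 6 + [-2] * 6 + [2])
        assert li == 0.0
        assert not included

    def test_tally_formula(self):
        # 11 items right-2, one left-2 (+ broom): R=22, L=2 -> 100*20/24
        li, included = hst.score_ehi([2] * 11 + [-2] + [1])
        assert li == pytest.approx(83.33, abs=0.005)
        assert included

    def test_broom_item_is_discarded(self):
        with_broom_left = hst.score_ehi([2] * 12 + [-2], broom_index=12)
        with_broom_right = hst.score_ehi([2] * 12 + [2], broom_index=12)
        assert with_broom_left == with_broom_right

    def test_all_zero_tallies_flagged(self):
        li, included = hst.score_ehi([0] * 13)
        assert math.isnan(li)
        assert not included

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="13"):
            hst.score_ehi([2] * 12)


class TestExclusions:
    @staticmethod
    def _profiles(n=30, fail=("S01",)):
        rows = []
        for i in range(n):
            sid = f"S{i + 1:02d}"
            li = 50.0 if sid in fail else 95.0
            rows.append(
                {"subject_id": sid, "laterality_index": li, "included": li > 74,
                 "grip_left_kg": 40.0, "grip_right_kg": 44.0, "grip_diff_kg": -4.0}
            )
        return pd.DataFrame(rows)

    def test_cutoff_and_manual_flags_remove_three_of_thirty(self):
        profiles = self._profiles()
        manual = {"S02": "deliberately trained the weighted hand",
                  "S03": "ambidextrous tool use at work"}
        included, reasons = hst.apply_exclusions(profiles, manual)
        assert len(included) == 27
        assert set(reasons["subject_id"]) == {"S01", "S02", "S03"}

    def test_no_failures_is_identity(self):
        profiles = self._profiles(fail=())
        included, reasons = hst.apply_exclusions(profiles)
        assert len(included) == 30
        assert len(reasons) == 0

    def test_impossible_cutoff_excludes_all(self):
        profiles = self._profiles(fail=())
        profiles["included"] = profiles["laterality_index"] > 101
        included, reasons = hst.apply_exclusions(profiles)
        assert included == []
        assert len(reasons) == 30
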