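import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ivimprefmap.dwi_io import BiomarkerTable
from ivimprefmap.repeatability_stats import (
    delegated_test,
    rm_anova,
    rm_correlation,
    wcv,
    wcv_from_values,
)


def ancova_rmcorr_oracle(subjects, x, y):
    """Repeated-measures correlation via explicit subject-indicator
    regression (independent ANCOVA oracle)."""
    subjects = np.asarray(subjects)
    x, y = np.asarray(x, float), np.asarray(y, float)
    uniq = np.unique(subjects)
    n, k = len(x), len(uniq)
    # design: subject dummies + common slope for x
    X = np.column_stack(
        [(subjects == s).astype(float) for s in uniq] + [x]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_full = y - X @ beta
    X0 = X[:, :-1]
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    resid_red = y - X0 @ beta0
    ss_full = resid_full @ resid_full
    ss_red = resid_red @ resid_red
    r2 = (ss_red - ss_full) / ss_red
    r = np.sign(beta[-1]) * np.sqrt(r2)
    return float(r), n - k - 1


def rm_anova_ss_oracle(wide):
    """From-scratch sums-of-squares enumeration for one-way rm-ANOVA."""
    s, t = wide.shape
    grand = wide.mean()
    ss_sub = sum(t * (wide[i].mean() - grand) ** 2 for i in range(s))
    ss_time = sum(s * (wide[:, j].mean() - grand) ** 2 for j in range(t))
    ss_tot = sum((wide[i, j] - grand) ** 2
                 for i in range(s) for j in range(t))
    ss_err = ss_tot - ss_sub - ss_time
    df_t, df_e = t - 1, (t - 1) * (s - 1)
    F = (ss_time / df_t) / (ss_err / df_e)
    return F, df_t, df_e, float(stats.f.sf(F, df_t, df_e))


class TestWcv:
    def test_identical_sessions_give_zero(self):
        res = wcv_from_values([[10, 10], [7, 7], [3, 3]])
        assert res.wcv == 0.0

    def test_hand_evaluated_two_session_subject(self):
        # sessions (9, 11): s = sqrt(2), m = 10 -> 14.142...%
        res = wcv_from_values([[9, 11], [9, 11]])
        assert res.wcv == pytest.approx(14.142135623730951, abs=1e-9)

    def test_scale_invariance(self, rng):
        groups = [rng.uniform(5, 15, 2) for _ in range(10)]
        base = wcv_from_values(groups).wcv
        scaled = wcv_from_values([g * 3.7 for g in groups]).wcv
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_monte_carlo_recovery_of_8_percent(self):
        rng = np.random.default_rng(8)
        groups = [10.0 * (1 + rng.normal(0, 0.08, 2)) for _ in range(2000)]
        res = wcv_from_values(groups)
        assert res.wcv == pytest.approx(8.0, abs=0.5)

    def test_incomplete_subjects_excluded_and_counted(self):
        res = wcv_from_values([[9, 11], [9, 11], [10]])
        assert res.n_subjects == 2 and res.n_excluded == 1

    def test_too_few_subjects_is_hard_error(self):
        with pytest.raises(ValueError):
            wcv_from_values([[9, 11], [10]])

    def test_table_interface_filters_biomarker_and_roi(self):
        recs = []
        for i, vals in enumerate([(9, 11), (19, 21)]):
            for j, v in enumerate(vals):
                recs.append(dict(subject_id=f"s{i}", group="healthy",
                                 session=f"ses{j}", roi_name="cervix",
                                 biomarker_name="D", value=v))
                recs.append(dict(subject_id=f"s{i}", group="healthy",
                                 session=f"ses{j}", roi_name="cervix",
                                 biomarker_name="f", value=0.2))
        table = BiomarkerTable.from_records(recs)
        res = wcv(table, "D", "cervix")
        assert res.n_subjects == 2 and res.wcv > 0
        assert wcv(table, "f", "cervix").wcv == 0.0


class TestRmCorrelation:
    def test_perfect_within_subject_linearity(self):
        subjects = np.repeat(["a", "b", "c"], 4)
        x = np.tile(np.arange(4.0), 3)
        offsets = np.repeat([0.0, 10.0, -5.0], 4)
        res = rm_correlation(subjects, x, 2 * x + offsets)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_constructed_orthogonal_residuals_give_zero(self):
        subjects = ["a"] * 4 + ["b"] * 4
        x = [0, 1, 0, 1, 0, 1, 0, 1]
        y = [0, 0, 1, 1, 5, 5, 6, 6]  # y residuals orthogonal to x residuals
        res = rm_correlation(subjects, x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_offset_invariance(self, rng):
        subjects = np.repeat(np.arange(6), 3)
        x = rng.normal(size=18)
        y = rng.normal(size=18)
        base = rm_correlation(subjects, x, y)
        shifted = rm_correlation(
            subjects, x + np.repeat(rng.normal(0, 50, 6), 3),
            y + np.repeat(rng.normal(0, 50, 6), 3))
        assert shifted.r == pytest.approx(base.r, abs=1e-10)

    def test_matches_ancova_oracle(self, rng):
        subjects = np.repeat([f"s{i}" for i in range(6)], 3)
        x = rng.normal(1, 0.3, 18)
        y = 0.5 * x + rng.normal(0, 0.2, 18)
        res = rm_correlation(subjects, x, y)
        r_o, dof_o = ancova_rmcorr_oracle(subjects, x, y)
        assert res.r == pytest.approx(r_o, abs=1e-10)
        assert res.dof == dof_o

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        subjects = np.repeat(np.arange(8), 3)
        x = rng.normal(1, 0.3, 24)
        y = 0.4 * x + rng.normal(0, 0.25, 24)
        res = rm_correlation(subjects, x, y)
        df = pd.DataFrame({"s": subjects, "x": x, "y": y})
        ref = pg.rm_corr(df, x="x", y="y", subject="s")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-4)
        assert res.dof == int(ref["dof"].iloc[0])

    def test_zero_within_subject_variance_flagged(self):
        res = rm_correlation(["a", "a", "b", "b"], [1, 1, 2, 2],
                             [1, 2, 3, 4])
        assert np.isnan(res.r) and np.isnan(res.p)


def long_table(wide, timepoints=("baseline", "week3", "week5")):
    rows = []
    for i, row in enumerate(wide):
        for tp, v in zip(timepoints, row):
            rows.append(dict(subject_id=f"p{i}", session=tp, value=v))
    return pd.DataFrame(rows)


class TestRmAnova:
    WIDE = np.array([
        [1.00, 1.15, 1.18],
        [0.95, 1.10, 1.05],
        [1.10, 1.12, 1.25],
        [1.02, 1.20, 1.15],
    ])

    def test_constant_over_time_gives_zero_F(self):
        wide = np.outer([1.0, 2.0, 3.0], np.ones(3))
        res = rm_anova(long_table(wide))
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_matches_sums_of_squares_oracle(self):
        res = rm_anova(long_table(self.WIDE))
        F_o, df_t, df_e, p_o = rm_anova_ss_oracle(self.WIDE)
        assert res.F == pytest.approx(F_o, abs=1e-10)
        assert (res.df_time, res.df_error) == (df_t, df_e)
        assert res.p == pytest.approx(p_o, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = long_table(self.WIDE)
        ref = pg.rm_anova(data=df, dv="value", within="session",
                          subject="subject_id")
        res = rm_anova(df)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_subject_offset_invariance(self):
        shifted = self.WIDE + np.array([[5.0], [-3.0], [0.7], [9.0]])
        assert rm_anova(long_table(shifted)).F == pytest.approx(
            rm_anova(long_table(self.WIDE)).F, rel=1e-9
        )

    def test_incomplete_subjects_dropped_and_counted(self):
        df = long_table(self.WIDE)
        df = df[~((df.subject_id == "p3") & (df.session == "week3"))]
        res = rm_anova(df)
        assert res.n_subjects == 3 and res.n_excluded == 1

    def test_posthoc_bonferroni_multiplies_and_caps(self):
        res = rm_anova(
            long_table(self.WIDE),
            contrasts=[("baseline", "week3"), ("baseline", "week5")],
        )
        assert len(res.posthoc) == 2
        for _, t, p_unc, p_bonf in res.posthoc:
            assert p_bonf == pytest.approx(min(1.0, 2 * p_unc), abs=1e-15)

    def test_bonferroni_doubling_pattern(self):
        """Uncorrected p ~ 0.037 and 0.045 double to the ~0.075/0.091
        borderline-nonsignificant pattern."""
        for p_unc, expected in [(0.0373, 0.075), (0.0455, 0.091)]:
            assert min(1.0, 2 * p_unc) == pytest.approx(expected, abs=0.001)

    def test_too_few_timepoints_or_subjects(self):
        with pytest.raises(ValueError):
            rm_anova(long_table(self.WIDE[:1]))
        with pytest.raises(ValueError):
            rm_anova(long_table(self.WIDE[:, :1], timepoints=("baseline",)))


class TestTreatmentEffectRecovery:
    def test_small_cohort_detects_15pct_D_increase_in_majority(self):
        """5 subjects x 3 timepoints, true D up 15% at weeks 3/5, 8%
        within-subject noise: ANOVA flags the change more often than not."""
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            base = 1.0 * (1 + rng.normal(0, 0.1, 5))
            wide = np.column_stack([
                base * (1 + rng.normal(0, 0.08, 5)),
                base * 1.15 * (1 + rng.normal(0, 0.08, 5)),
                base * 1.15 * (1 + rng.normal(0, 0.08, 5)),
            ])
            if rm_anova(long_table(wide)).p < 0.05:
                hits += 1
        assert hits > n_rep / 2


class TestDelegatedTests:
    def test_paired_t_on_identical_vectors_is_degenerate(self):
        res = delegated_test("ttest_rel", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.pvalue) or res.pvalue == 1.0

    def test_wilcoxon_delegation_identity(self):
        x = [1.1, 0.9, 1.3, 1.7, 0.8]
        y = [1.0, 1.0, 1.0, 1.0, 1.0]
        res = delegated_test("wilcoxon", x, y)
        ref = stats.wilcoxon(x, y)
        assert res.statistic == ref.statistic and res.pvalue == ref.pvalue

    def test_shapiro_sanity_on_normal_draws(self):
        rng = np.random.default_rng(5)
        res = delegated_test("shapiro", rng.normal(size=5000))
        assert res.pvalue > 0.001

    def test_unknown_test_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            delegated_test("kruskal", [1], [2])
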