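"""Repeatability and longitudinal statistics for ROI biomarker tables.

Three estimators are authored here because they carry the study design:

* ``wcv`` — the within-subject coefficient of variation,
  wCV = sqrt( (1/N) Σ_i s_i²/m_i² ) × 100, with s_i and m_i the sample
  standard deviation and mean of subject i across sessions.  This is the
  root-mean-square of per-subject relative SDs (the QIBA-style
  convention); for two sessions per subject it coincides with the
  paired-difference form.

* ``rm_correlation`` — repeated-measures correlation: each subject's
  means are subtracted from x and y, the pooled residuals are
  Pearson-correlated, and significance uses t = r·sqrt(dof/(1-r²)) with
  dof = N_observations - n_subjects - 1.  Equivalent to the common-slope
  ANCOVA with subject indicators.

* ``rm_anova`` — classical one-way repeated-measures ANOVA
  (SS_total = SS_subject + SS_time + SS_error, F = MS_time/MS_error) on
  complete cases, followed by post-hoc paired t-tests with Bonferroni
  correction by multiplication (capped at 1).

Standard tests (Shapiro-Wilk, paired/unpaired t, Wilcoxon) are delegated
to scipy.stats via thin pass-throughs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dwi_io import BiomarkerTable

__all__ = [
    "WcvResult",
    "RmCorrResult",
    "RmAnovaResult",
    "wcv",
    "wcv_from_values",
    "rm_correlation",
    "rm_anova",
    "delegated_test",
]


@dataclass(frozen=True)
class WcvResult:
    wcv: float  # percent
    n_subjects: int
    biomarker_name: str
    n_excluded: int = 0


@dataclass(frozen=True)
class RmCorrResult:
    r: float
    dof: int
    p: float
    n_subjects: int
    n_obs: int


@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df_time: int
    df_error: int
    p: float
    n_subjects: int
    n_excluded: int
    posthoc: tuple = field(default_factory=tuple)
    # posthoc entries: (contrast_label, t, p_uncorrected, p_bonferroni)


def wcv_from_values(per_subject: Sequence[Sequence[float]],
                    biomarker_name: str = "") -> WcvResult:
    """wCV (%) from raw per-subject session values.

    Subjects with fewer than 2 sessions are excluded (counted); fewer
    than 2 usable subjects is a hard error.  All values must be > 0.
    """
    usable, excluded = [], 0
    for vals in per_subject:
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            excluded += 1
            continue
        if np.any(vals <= 0):
            raise ValueError("wCV requires strictly positive values")
        usable.append(vals)
    if len(usable) < 2:
        raise ValueError(
            f"wCV needs >= 2 subjects with >= 2 sessions, got {len(usable)}"
        )
    ratios = [np.std(v, ddof=1) / np.mean(v) for v in usable]
    value = float(np.sqrt(np.mean(np.square(ratios))) * 100.0)
    return WcvResult(value, len(usable), biomarker_name, excluded)


def wcv(table: BiomarkerTable, biomarker: str, roi: str) -> WcvResult:
    """wCV of one biomarker in one ROI across each subject's sessions."""
    df = table.df
    df = df[(df.biomarker_name == biomarker) & (df.roi_name == roi)]
    groups = [g["value"].to_numpy() for _, g in df.groupby("subject_id")]
    return wcv_from_values(groups, biomarker_name=biomarker)


def rm_correlation(subjects, x, y) -> RmCorrResult:
    """Repeated-measures correlation of paired within-subject observations.

    Subjects with a single observation contribute nothing after centering
    and are dropped.  Zero within-subject variance in x or y flags the
    result undefined (NaN r and p).
    """
    df = pd.DataFrame({"s": np.asarray(subjects),
                       "x": np.asarray(x, dtype=float),
                       "y": np.asarray(y, dtype=float)})
    df = df.groupby("s").filter(lambda g: len(g) >= 2)
    k = df["s"].nunique()
    n = len(df)
    dof = n - k - 1
    if k < 1 or dof < 1:
        raise ValueError(
            f"repeated-measures correlation needs dof >= 1, got {dof}"
        )
    xr = df["x"] - df.groupby("s")["x"].transform("mean")
    yr = df["y"] - df.groupby("s")["y"].transform("mean")
    sx, sy = float(np.sum(xr**2)), float(np.sum(yr**2))
    if sx == 0 or sy == 0:
        return RmCorrResult(float("nan"), dof, float("nan"), k, n)
    r = float(np.sum(xr * yr) / np.sqrt(sx * sy))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return RmCorrResult(r, dof, p, k, n)


def rm_anova(
    data: pd.DataFrame,
    contrasts: Optional[Sequence[tuple]] = None,
    subject_col: str = "subject_id",
    time_col: str = "session",
    value_col: str = "value",
) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a long-format table.

    Subjects missing any timepoint are dropped (complete-case analysis;
    the count is reported).  ``contrasts`` lists timepoint-label pairs
    for post-hoc paired t-tests; Bonferroni correction multiplies each
    uncorrected p by the number of contrasts, capped at 1.
    """
    df = data[[subject_col, time_col, value_col]].copy()
    times = sorted(df[time_col].unique())
    t = len(times)
    if t < 2:
        raise ValueError("rm-ANOVA needs >= 2 timepoints")
    counts = df.groupby(subject_col)[time_col].nunique()
    complete = counts[counts == t].index
    n_excluded = int((counts != t).sum())
    df = df[df[subject_col].isin(complete)]
    s = df[subject_col].nunique()
    if s < 2:
        raise ValueError(
            f"rm-ANOVA needs >= 2 complete subjects, got {s}"
        )
    wide = df.pivot_table(index=subject_col, columns=time_col,
                          values=value_col).loc[:, times].to_numpy()
    grand = wide.mean()
    subj_means = wide.mean(axis=1)
    time_means = wide.mean(axis=0)
    ss_subject = t * float(np.sum((subj_means - grand) ** 2))
    ss_time = s * float(np.sum((time_means - grand) ** 2))
    ss_total = float(np.sum((wide - grand) ** 2))
    ss_error = ss_total - ss_subject - ss_time
    df_time = t - 1
    df_error = df_time * (s - 1)
    ms_time = ss_time / df_time
    ms_error = ss_error / df_error
    if ms_error <= 0:
        F = 0.0 if ms_time == 0 else float("inf")
        p = 1.0 if ms_time == 0 else 0.0
    else:
        F = float(ms_time / ms_error)
        p = float(stats.f.sf(F, df_time, df_error))

    posthoc = []
    if contrasts:
        m = len(contrasts)
        col = {lab: i for i, lab in enumerate(times)}
        for a, b in contrasts:
            res = stats.ttest_rel(wide[:, col[a]], wide[:, col[b]])
            p_unc = float(res.pvalue)
            posthoc.append(
                (f"{a} vs {b}", float(res.statistic), p_unc,
                 min(1.0, m * p_unc))
            )
    return RmAnovaResult(F, df_time, df_error, p, s, n_excluded,
                         tuple(posthoc))


_DELEGATED = {
    "shapiro": lambda x, **kw: stats.shapiro(x),
    "ttest_rel": lambda x, y, **kw: stats.ttest_rel(x, y),
    "ttest_ind": lambda x, y, **kw: stats.ttest_ind(x, y),
    "wilcoxon": lambda x, y=None, **kw: stats.wilcoxon(x, y, **kw),
}


def delegated_test(name: str, *args, **kwargs):
    """Thin pass-through to the standard routine for ``name``.

    Supported: shapiro, ttest_rel, ttest_ind, wilcoxon.  Results are
    returned unchanged (statistic, pvalue namedtuples); errors propagate.
    """
    try:
        fn = _DELEGATED[name]
    except KeyError:
        raise ValueError(
            f"unknown delegated test '{name}'; choose from {sorted(_DELEGATED)}"
        ) from None
    return fn(*args, **kwargs)
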