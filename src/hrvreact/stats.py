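"""Cohort statistics: normality-gated transforms, group comparisons,
repeated-measures ANOVA, categorical tests, correlation tables, and the
clinical classification rules (LASr significant reduction, cardiotoxicity
label from echo and troponin criteria).

Conventions: the normality gate is a one-sample Kolmogorov-Smirnov test
against a normal with the sample mean/SD (no Lilliefors correction, which
makes the gate conservative); t-tests use pooled variance when unpaired;
chi-squared carries no continuity correction and is swapped for Fisher's
exact test when any expected count falls below 5; no multiplicity correction
is applied anywhere, but the number of tests performed is reported where
tables are emitted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clinical import EchoPanel, SubjectRecord
from .config import BASELINE, CriteriaConfig, FOLLOWUP
from .errors import (ConfigurationError, DegenerateInputError,
                     InsufficientDataError, MissingDataError,
                     NonPositiveDataError)


# --------------------------------------------------------------------------
# normality gate
# --------------------------------------------------------------------------

def normality_gate(values, alpha: float = 0.05) -> Tuple[np.ndarray, bool]:
    """KS-test the sample against N(mean, sd); log10-transform on rejection.

    Returns (possibly transformed values, was_transformed).  Data are never
    altered when the flag is False.  Non-positive values with a triggered
    transform raise ``NonPositiveDataError`` — the offset/exclusion decision
    belongs to the caller.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise InsufficientDataError("normality_gate needs n >= 5")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("zero-variance sample: KS test undefined")
    p = sps.kstest(x, "norm", args=(float(np.mean(x)), sd)).pvalue
    if p >= alpha:
        return x, False
    if np.any(x <= 0):
        raise NonPositiveDataError(
            "log10 transform triggered on non-positive values; "
            "offset or exclude before transforming")
    return np.log10(x), True


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CompareResult:
    statistic: float
    p_value: float
    df: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    method: str


def compare_groups(values_a, values_b, paired: bool = False) -> CompareResult:
    """Student's t-test (pooled variance unpaired; difference scores paired)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    summ = dict(mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)))
    if paired:
        if a.size != b.size:
            raise ConfigurationError("paired comparison requires equal lengths")
        d = a - b
        sd_d = float(d.std(ddof=1))
        df = a.size - 1
        if sd_d == 0.0:
            # all differences identical: t is 0 when they vanish, else unbounded
            if float(d.mean()) == 0.0:
                return CompareResult(0.0, 1.0, df, method="paired t", **summ)
            return CompareResult(math.inf if d.mean() > 0 else -math.inf,
                                 0.0, df, method="paired t", **summ)
        t, p = sps.ttest_rel(a, b)
        return CompareResult(float(t), float(p), df, method="paired t", **summ)
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0.0:
        if summ["mean_a"] == summ["mean_b"]:
            return CompareResult(math.nan, math.nan, df,
                                 method="two-sample t (flagged: zero variance)", **summ)
        return CompareResult(math.inf if summ["mean_a"] > summ["mean_b"] else -math.inf,
                             0.0, df, method="two-sample t", **summ)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return CompareResult(float(t), float(p), df, method="two-sample t", **summ)


# --------------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df1: int
    df2: int
    p_value: float


def rm_anova(values) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Subject-blocked sum-of-squares decomposition; F on (k-1, (k-1)(n-1))
    degrees of freedom; no sphericity correction (documented limitation);
    missing cells are an error — no imputation.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ConfigurationError("rm_anova expects a 2-D subjects x conditions matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise InsufficientDataError("rm_anova needs >= 3 subjects and >= 2 conditions")
    if np.any(~np.isfinite(m)):
        raise MissingDataError("rm_anova requires a complete matrix (no missing cells)")
    grand = m.mean()
    ss_total = float(((m - grand) ** 2).sum())
    ss_subj = float(k * ((m.mean(axis=1) - grand) ** 2).sum())
    ss_cond = float(n * ((m.mean(axis=0) - grand) ** 2).sum())
    ss_resid = max(ss_total - ss_subj - ss_cond, 0.0)
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    if ss_resid == 0.0:
        if ss_cond == 0.0:
            return RMAnovaResult(0.0, df1, df2, 1.0)
        return RMAnovaResult(math.inf, df1, df2, 0.0)
    F = (ss_cond / df1) / (ss_resid / df2)
    return RMAnovaResult(float(F), df1, df2, float(sps.f.sf(F, df1, df2)))


# --------------------------------------------------------------------------
# categorical tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoricalResult:
    statistic: float
    p_value: float
    method: str


def categorical_test(table) -> CategoricalResult:
    """Chi-squared (no continuity correction) when all expected counts >= 5,
    otherwise Fisher's exact test (two-sided).  Method selection is a pure
    function of the expected counts."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = np.asarray(table, dtype=float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
            raise ConfigurationError("categorical_test expects a 2x2 table of counts")
        t = t.astype(int)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateInputError("zero margin: association test undefined")
    expected = np.outer(row, col) / t.sum()
    if np.all(expected >= 5.0):
        stat = float((((t - expected) ** 2) / expected).sum())
        return CategoricalResult(stat, float(sps.chi2.sf(stat, 1)), "chi-squared")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return CategoricalResult(float(odds), float(p), "fisher")


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------

def pearson_matrix(echo_table: pd.DataFrame,
                   hrv_table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided t-based p for every echo x HRV variable pair.

    Pairwise-complete observations; pairs with n < 4 or zero variance are
    flagged NaN.  P-values are unadjusted.
    """
    r = pd.DataFrame(index=echo_table.columns, columns=hrv_table.columns, dtype=float)
    p = r.copy()
    for ec in echo_table.columns:
        x_full = echo_table[ec].to_numpy(dtype=float)
        for hc in hrv_table.columns:
            y_full = hrv_table[hc].to_numpy(dtype=float)
            ok = np.isfinite(x_full) & np.isfinite(y_full)
            x, y = x_full[ok], y_full[ok]
            if x.size < 4 or np.std(x) == 0.0 or np.std(y) == 0.0:
                continue  # stays NaN (flagged missing)
            rv = sps.pearsonr(x, y)
            r.loc[ec, hc] = float(rv.statistic)
            p.loc[ec, hc] = float(rv.pvalue)
    return r, p


# --------------------------------------------------------------------------
# clinical classification rules
# --------------------------------------------------------------------------

def las_significant_reduction(lasr_baseline_pct: float, lasr_followup_pct: float,
                              criteria: CriteriaConfig = CriteriaConfig()) -> bool:
    """Significant left-atrial reservoir strain reduction.

    Baseline >= 35%: true if follow-up drops below 35% or shows a > 10%
    relative reduction.  Baseline already < 35%: only the > 10% relative
    reduction counts.
    """
    b, f = float(lasr_baseline_pct), float(lasr_followup_pct)
    if b <= 0 or f <= 0:
        raise ConfigurationError("LASr values must be positive percentages")
    rel = (b - f) / b
    if b >= criteria.lasr_normal_pct:
        return f < criteria.lasr_normal_pct or rel > criteria.lasr_relative_reduction
    return rel > criteria.lasr_relative_reduction


def echo_criterion(baseline: EchoPanel, followup: EchoPanel,
                   criteria: CriteriaConfig = CriteriaConfig()) -> bool:
    """Echocardiographic cardiotoxicity: LVEF below threshold with a large
    absolute drop, or relative GLS magnitude reduction beyond threshold."""
    lvef_hit = (followup.lvef3d_pct < criteria.lvef_threshold_pct
                and baseline.lvef3d_pct - followup.lvef3d_pct >= criteria.lvef_drop_pct)
    g0, g1 = abs(baseline.gls_pct), abs(followup.gls_pct)
    gls_hit = g0 > 0 and (g0 - g1) / g0 > criteria.gls_relative_reduction
    return bool(lvef_hit or gls_hit)


def classify_cardiotoxicity(record: SubjectRecord,
                            criteria: CriteriaConfig = CriteriaConfig()) -> str:
    """Label a subject as 'echo', 'troponin', 'both' or 'none'.

    The troponin criterion is new follow-up positivity (positive at follow-up,
    negative at baseline)."""
    for tp in (BASELINE, FOLLOWUP):
        if tp not in record.echo:
            raise MissingDataError(
                f"subject {record.subject_id!r}: {tp} echo panel missing — unclassifiable")
        if tp not in record.troponin_positive:
            raise MissingDataError(
                f"subject {record.subject_id!r}: {tp} troponin flag missing — unclassifiable")
    echo_hit = echo_criterion(record.echo[BASELINE], record.echo[FOLLOWUP], criteria)
    trop_hit = bool(record.troponin_positive[FOLLOWUP]
                    and not record.troponin_positive[BASELINE])
    if echo_hit and trop_hit:
        return "both"
    if echo_hit:
        return "echo"
    if trop_hit:
        return "troponin"
    return "none"
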