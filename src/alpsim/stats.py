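"""Group-comparison and correlation battery.

Continuous variables are compared with the classical pooled-variance
(Student) two-sample t-test, categorical variables with the Pearson
chi-square test without continuity correction, and associations are
quantified by Pearson's correlation coefficient, all two-tailed. When
several axis diffusivities are compared at once, a Bonferroni-adjusted
threshold alpha/m is applied (m = 9 for the three axes of three fibers;
0.05/9 displays as 0.0055 under the truncate-to-4-decimals convention).

The numerical kernels delegate to scipy.stats; this module adds the
degenerate-case contracts (zero pooled variance, constant samples, empty
marginals) and the report assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ComputationError, InputError, ParameterError


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def t_test_independent(a, b, welch: bool = False) -> TTestResult:
    """Two-sample t-test, pooled variance by default (Welch optional).

    Degenerate inputs: if both samples have zero variance and equal
    means, returns t=0, p=1; zero variance with unequal means is an
    error (an infinite t has no finite p to report).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each sample needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InputError("samples must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return TTestResult(t=0.0, df=float(df), p=1.0)
        raise ComputationError("zero pooled variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if welch else float(a.size + b.size - 2)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise InputError("table must be 2x2 with nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InputError("chi-square is undefined with a zero marginal")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(chi2=float(chi2), df=int(dof), p=float(p))


def pearson_r(x, y) -> CorrelationResult:
    """Pearson correlation with the two-tailed t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("samples must have equal length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("samples must be finite")
    if x.std() == 0 or y.std() == 0:
        raise InputError("Pearson r undefined for a constant sample")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Adjusted per-comparison significance threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if m < 1:
        raise ParameterError("m must be a positive integer")
    return alpha / m


def format_threshold(threshold: float, decimals: int = 4) -> str:
    """Display form of a threshold, truncated (not rounded) to
    ``decimals`` places — e.g. 0.05/9 -> '0.0055'."""
    scale = 10**decimals
    return f"{math.floor(threshold * scale) / scale:.{decimals}f}"


@dataclass
class StatsReport:
    """Tabular group comparison (and optional correlation) results."""

    comparisons: pd.DataFrame
    correlations: pd.DataFrame | None = None
    alpha: float = 0.05
    m_corrected: int = 9

    @property
    def adjusted_alpha(self) -> float:
        return bonferroni_alpha(self.alpha, self.m_corrected)

    def to_text(self) -> str:
        lines = [
            "Group comparison "
            f"(alpha={self.alpha}, Bonferroni-corrected threshold "
            f"{format_threshold(self.adjusted_alpha)} for marked rows)",
            self.comparisons.to_string(index=False),
        ]
        if self.correlations is not None:
            lines += ["", "Correlations with ALPS index",
                      self.correlations.to_string(index=False)]
        return "\n".join(lines)


def compare_groups(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    continuous: list[str],
    categorical: list[str] = (),
    corrected: list[str] = (),
    alpha: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
) -> StatsReport:
    """Run the comparison battery between two cohorts.

    Bonferroni correction (m = number of ``corrected`` variables) applies
    only to the variables listed in ``corrected`` — in the intended use,
    the nine per-axis fiber diffusivities; the ALPS index itself and the
    demographics are judged at the uncorrected two-tailed alpha.
    """
    if len(cohort_a) == 0 or len(cohort_b) == 0:
        raise InputError("cohorts must be non-empty")
    m = max(len(corrected), 1)
    thr_corrected = bonferroni_alpha(alpha, m)
    rows = []
    for name in list(continuous) + list(categorical):
        for df_, lab in ((cohort_a, labels[0]), (cohort_b, labels[1])):
            if name not in df_.columns:
                raise InputError(f"variable {name!r} missing from cohort {lab}")
    for name in continuous:
        a = cohort_a[name].dropna().to_numpy(dtype=float)
        b = cohort_b[name].dropna().to_numpy(dtype=float)
        thr = thr_corrected if name in corrected else alpha
        row = dict(
            variable=name, kind="continuous",
            mean_a=a.mean(), sd_a=a.std(ddof=1),
            mean_b=b.mean(), sd_b=b.std(ddof=1),
            statistic=np.nan, df=np.nan, p=np.nan,
            threshold=thr, significant=False, flagged=False,
        )
        try:
            res = t_test_independent(a, b)
            row.update(statistic=res.t, df=res.df, p=res.p,
                       significant=res.p < thr)
        except (InputError, ComputationError):
            # degenerate sample (too small / zero variance): flag, not fatal
            row["flagged"] = True
        rows.append(row)
    for name in categorical:
        a = cohort_a[name].dropna().astype(bool)
        b = cohort_b[name].dropna().astype(bool)
        table = [[int(a.sum()), int(b.sum())],
                 [int((~a).sum()), int((~b).sum())]]
        thr = thr_corrected if name in corrected else alpha
        row = dict(
            variable=name, kind="categorical",
            mean_a=a.mean(), sd_a=np.nan, mean_b=b.mean(), sd_b=np.nan,
            statistic=np.nan, df=np.nan, p=np.nan,
            threshold=thr, significant=False, flagged=False,
        )
        try:
            res = chi_square_2x2(table)
            row.update(statistic=res.chi2, df=res.df, p=res.p,
                       significant=res.p < thr)
        except InputError:
            # zero marginal (e.g. a single-sex mini-cohort): flag the row
            row["flagged"] = True
        rows.append(row)
    return StatsReport(
        comparisons=pd.DataFrame(rows), alpha=alpha, m_corrected=m
    )


def correlate_clinical(
    cohort: pd.DataFrame, variables: list[str], alps_col: str = "alps"
) -> pd.DataFrame:
    """Pearson r (and p) of the ALPS index against each clinical variable.

    Constant or undefined variables yield a flagged row (r, p = NaN)
    rather than aborting the table.
    """
    if alps_col not in cohort.columns:
        raise InputError(f"cohort has no {alps_col!r} column")
    rows = []
    for name in variables:
        if name not in cohort.columns:
            raise InputError(f"variable {name!r} missing from cohort")
        sub = cohort[[alps_col, name]].dropna()
        try:
            res = pearson_r(sub[alps_col], sub[name])
            rows.append(dict(variable=name, n=res.n, r=res.r, p=res.p, flagged=False))
        except InputError:
            rows.append(dict(variable=name, n=len(sub), r=np.nan, p=np.nan, flagged=True))
    return pd.DataFrame(rows)
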