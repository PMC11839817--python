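"""Test-retest reliability of LDAEP slopes.

The primary coefficient is the two-way, absolute-agreement, average-measures
intraclass correlation (McGraw & Wong ICC(A,k)) with its F-based 95%
confidence interval. The study protocol labels this "ICC(3,k)" while
describing absolute agreement; the verbal description is the more specific
statement, so the absolute-agreement form is primary and the consistency
form ICC(C,k) is available behind ``form="consistency"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def _anova_ms(values: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares for an n x k rating matrix:
    rows (subjects), columns (sessions), residual."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected an n x k matrix")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((values - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_agreement_k(values: np.ndarray, ci_level: float = 0.95,
                    form: str = "agreement") -> tuple[float, tuple[float, float]]:
    """Average-measures ICC with confidence interval.

    ``form="agreement"``: ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n),
    CI per McGraw & Wong. ``form="consistency"``: ICC(C,k) =
    (MSR - MSE)/MSR with the exact F-based interval.
    """
    msr, msc, mse, n, k = _anova_ms(values)
    if msr <= 0 and mse <= 0:
        raise ValueError("degenerate matrix: zero total variance")
    alpha = 1.0 - ci_level

    if form == "consistency":
        icc = (msr - mse) / msr
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        return float(icc), (float(1 - 1 / fl), float(1 - 1 / fu))
    if form != "agreement":
        raise ValueError("form must be 'agreement' or 'consistency'")

    icc = (msr - mse) / (msr + (msc - mse) / n)

    # Single-measure coefficient and its Satterthwaite df drive the interval;
    # the average-measures bounds follow by the Spearman-Brown step.
    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    denom = n * (1 - icc1)
    if denom <= 0:  # perfect agreement
        return float(icc), (float(icc), float(icc))
    a = k * icc1 / denom
    b = 1 + k * icc1 * (n - 1) / denom
    v = ((a * msc + b * mse) ** 2 /
         ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
    fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = (n * (msr - fl * mse) /
           (fl * (k * msc + (k * n - k - n) * mse) + n * msr))
    hi1 = (n * (fu * msr - mse) /
           (k * msc + (k * n - k - n) * mse + n * fu * msr))
    step = lambda r: k * r / (1 + (k - 1) * r)
    return float(icc), (float(step(lo1)), float(step(hi1)))


def koo_li_band(icc: float) -> str:
    """Qualitative reliability band (poor/moderate/good/excellent)."""
    if icc < 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


@dataclass
class ReliabilityResult:
    pearson_r: float
    pearson_p: float
    icc: float
    ci: tuple[float, float]
    band: str
    mean_diff: float   # session 2 - session 1, uV/dB
    sd_diff: float
    n: int
    k: int


def retest_summary(values: np.ndarray, ci_level: float = 0.95
                   ) -> ReliabilityResult:
    """Pearson correlation, session difference summary, and agreement ICC
    for a two-session slope matrix (subjects x 2)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 2:
        raise ValueError("expected a subjects x 2 matrix")
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    r, p = stats.pearsonr(values[:, 0], values[:, 1])
    diff = values[:, 1] - values[:, 0]
    icc, ci = icc_agreement_k(values, ci_level)
    return ReliabilityResult(float(r), float(p), icc, ci, koo_li_band(icc),
                             float(diff.mean()), float(diff.std(ddof=1)),
                             n, 2)


def extreme_change_screen(diffs: np.ndarray, z_threshold: float = 3.5
                          ) -> np.ndarray:
    """Flag subjects whose session difference is extreme on ALL components.

    ``diffs`` is subjects x components (session 2 - session 1, one column per
    component x channel cell). A subject is flagged only when every column's
    difference lies more than ``z_threshold`` SDs from that column's mean —
    the signature of a technical error rather than physiology. Flagged
    subjects are reported, not auto-removed.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim == 1:
        diffs = diffs[:, None]
    if diffs.shape[0] < 5:
        raise ValueError("need at least 5 subjects to screen")
    z = (diffs - diffs.mean(axis=0)) / diffs.std(axis=0, ddof=1)
    return np.flatnonzero(np.all(np.abs(z) > z_threshold, axis=1))
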