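"""Observer/model reproducibility statistics for paired cardiac-function series.

Implements the agreement toolkit used to compare two readings (two observers,
one observer twice, or observer vs model) of the same scans: Bland-Altman
bias and limits of agreement, single-measure two-way mixed-effects ICC with
absolute agreement, coefficient of variability (CoV), Pearson correlation,
and paired t-tests with a Shapiro-Wilk normality gate and Bonferroni-adjusted
significance threshold.

Conventions that must be fixed for reproducibility:

* CoV = 100 * SD(a - b) / grand mean of all values of both series. The grand
  mean (rather than the mean of per-pair means — identical for equal-length
  pairs, but the distinction matters for documentation) makes identical
  series score exactly 0%.
* ICC is the single-measure absolute-agreement form ICC(A,1); the
  average-measure form ICC(A,2) is available via ``form="A,2"``.
* Shapiro-Wilk failures warn but do not block the t-test; with the sample
  sizes typical here the t-test is considered robust enough.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class PairedSeries:
    """Two equal-length readings of the same parameter, aligned by scan."""

    parameter: str
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("paired series must be equal-length 1-D vectors")
        if self.values_a.size < 2:
            raise ValueError("paired series needs n >= 2")

    @property
    def n(self) -> int:
        return self.values_a.size

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass
class AgreementStats:
    parameter: str
    bias: float
    loa_low: float
    loa_high: float
    icc: float | None
    icc_band: str | None
    cov_percent: float
    pearson_r: float | None
    t_p_value: float | None
    normality_p_a: float
    normality_p_b: float
    n: int


def bland_altman(s: PairedSeries) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement: mean(a-b) -/+ 1.96 * sample SD(a-b)."""
    d = s.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def icc_absolute_agreement(s: PairedSeries, form: str = "A,1") -> float:
    """Two-way mixed-effects ICC with absolute agreement for k = 2 raters.

    Single-measure form (default)::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    where MSR, MSC, MSE are the rows (subjects), columns (raters) and error
    mean squares of the two-way ANOVA. ``form="A,2"`` gives the
    average-measure variant. Identical constant series have zero total
    variance and an undefined ICC (raises).
    """
    x = np.column_stack([s.values_a, s.values_b])
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("ICC undefined: zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "A,1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif form == "A,2":
        denom = msr + (msc - mse) / n
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise ValueError("ICC undefined: zero denominator")
    return float((msr - mse) / denom)


def icc_interpretation(icc: float) -> str:
    """Reliability band: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def cov_percent(s: PairedSeries, denominator: str = "grand_mean") -> float:
    """Coefficient of variability: 100 * SD of the paired differences / mean value.

    ``denominator="grand_mean"`` (default) divides by the mean of all values
    of both series; ``"pair_means"`` divides by the mean of the per-pair
    means (numerically identical for complete pairs, kept as an explicit
    option because the convention varies between reports).
    """
    sd = float(np.std(s.differences, ddof=1))
    if denominator == "grand_mean":
        mean = float(np.concatenate([s.values_a, s.values_b]).mean())
    elif denominator == "pair_means":
        mean = float(np.mean((s.values_a + s.values_b) / 2.0))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if mean == 0:
        raise ValueError("CoV undefined: zero mean value")
    return 100.0 * sd / mean


def relative_deviation(bias: float, reference_mean: float) -> float:
    """Systematic deviation as a percentage of a reference mean value."""
    if reference_mean == 0:
        raise ValueError("relative deviation undefined: zero reference mean")
    return 100.0 * abs(bias) / reference_mean


def pearson(s: PairedSeries) -> float:
    """Sample Pearson correlation between the two readings."""
    if s.n < 3:
        raise ValueError("Pearson r needs n >= 3")
    if np.all(s.values_a == s.values_a[0]) or np.all(s.values_b == s.values_b[0]):
        raise ValueError("Pearson r undefined for a constant series")
    return float(sps.pearsonr(s.values_a, s.values_b).statistic)


def bonferroni_threshold(overall_alpha: float = 0.05, m: int = 4) -> float:
    """Per-test significance threshold after Bonferroni correction."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return overall_alpha / m


def paired_tests(series: list[PairedSeries], overall_alpha: float = 0.05,
                 m: int = 4) -> dict:
    """Paired two-sided t-tests with a Shapiro-Wilk gate and Bonferroni threshold.

    Returns per-series Shapiro p-values (logged as warnings when < 0.05 — the
    tests proceed regardless), the t-test p-value (None when the differences
    have zero variance, flagged degenerate), a significance flag at the
    adjusted threshold, and the threshold itself.
    """
    threshold = bonferroni_threshold(overall_alpha, m)
    results = {}
    for s in series:
        sw_a = float(sps.shapiro(s.values_a).pvalue)
        sw_b = float(sps.shapiro(s.values_b).pvalue)
        for label, p in (("a", sw_a), ("b", sw_b)):
            if p < 0.05:
                warnings.warn(
                    f"{s.parameter} reading {label}: Shapiro-Wilk p={p:.3f} < 0.05; "
                    "proceeding with the paired t-test", stacklevel=2)
        d = s.differences
        if np.std(d, ddof=1) == 0:
            p_val = None
            significant = None
        else:
            p_val = float(sps.ttest_rel(s.values_a, s.values_b).pvalue)
            significant = p_val < threshold
        results[s.parameter] = {
            "normality_p_a": sw_a,
            "normality_p_b": sw_b,
            "t_p_value": p_val,
            "significant": significant,
            "degenerate": p_val is None,
            "n": s.n,
        }
    return {"threshold": threshold, "per_series": results}


def agreement_stats(s: PairedSeries, overall_alpha: float = 0.05, m: int = 4,
                    icc_form: str = "A,1",
                    cov_denominator: str = "grand_mean") -> AgreementStats:
    """Full agreement panel for one paired series; undefined pieces become None."""
    bias, lo, hi = bland_altman(s)
    try:
        icc = icc_absolute_agreement(s, form=icc_form)
        band = icc_interpretation(icc)
    except ValueError:
        icc, band = None, None
    try:
        r = pearson(s)
    except ValueError:
        r = None
    tests = paired_tests([s], overall_alpha, m)["per_series"][s.parameter]
    return AgreementStats(
        parameter=s.parameter, bias=bias, loa_low=lo, loa_high=hi,
        icc=icc, icc_band=band,
        cov_percent=cov_percent(s, cov_denominator),
        pearson_r=r, t_p_value=tests["t_p_value"],
        normality_p_a=tests["normality_p_a"], normality_p_b=tests["normality_p_b"],
        n=s.n)


def bland_altman_plot(s: PairedSeries, path: str) -> None:
    """Write a Bland-Altman scatter (difference vs mean) with bias and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bias, lo, hi = bland_altman(s)
    means = (s.values_a + s.values_b) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.axhspan(lo, hi, color="palegreen", alpha=0.4)
    ax.axhline(bias, color="tab:blue")
    ax.scatter(means, s.differences, s=18, color="k")
    ax.set_xlabel(f"mean {s.parameter}")
    ax.set_ylabel(f"difference in {s.parameter}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _loa_contains(s: PairedSeries) -> float:
    """Fraction of paired differences inside the limits of agreement."""
    _, lo, hi = bland_altman(s)
    d = s.differences
    return float(np.mean((d >= lo) & (d <= hi)))
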