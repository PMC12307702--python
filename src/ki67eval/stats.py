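"""Nonparametric agreement statistics for paired measurement series.

Three tools, matching standard practice for method-comparison studies on
skewed count data:

* **Intraclass correlation coefficient** for a two-way mixed model with
  single measures and two fixed raters (reference standard vs one detector).
  The *consistency* form ICC(3,1) ignores a systematic offset between raters;
  the *absolute agreement* form ICC(A,1) penalizes it.  Both are computed from
  the two-way ANOVA mean squares, with 95% confidence intervals from
  F-distribution bounds (Shrout-Fleiss / McGraw-Wong; the two
  parameterizations coincide for the consistency single-measures case).

* **Nonparametric Bland-Altman**: bias as the *median* of the paired
  differences and limits of agreement as their 2.5th/97.5th percentiles,
  appropriate when differences are not normally distributed.

* **Paired Wilcoxon signed-rank test**, exact for small tie-free samples and
  a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError

CONSISTENCY = "consistency"
ABSOLUTE_AGREEMENT = "absolute_agreement"

#: Largest effective sample size for which the exact signed-rank null
#: distribution is enumerated (2^n sign patterns).
_WILCOXON_EXACT_N = 25


def _paired(a, b, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired series must be equal-length 1-D arrays")
    if a.size < min_n:
        raise ValidationError(f"paired series require n >= {min_n}, got {a.size}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("paired series must not contain missing values")
    return a, b


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    f_value: float
    df1: int
    df2: int
    p_value: float
    variant: str

    def to_dict(self) -> dict:
        return {
            "icc": self.icc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "f_value": self.f_value, "df1": self.df1, "df2": self.df2,
            "p_value": self.p_value, "variant": self.variant,
        }


def _mean_squares(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares for an n x 2 table (targets x raters).

    Returns (MSR, MSC, MSE, n, k): rows (targets), columns (raters), residual.
    """
    m = np.column_stack([a, b])
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = float(((m - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)  # guard tiny negative rounding
    return msr, msc, mse, n, k


def icc_two_way_mixed_single(a, b, variant: str = CONSISTENCY, ci: float = 0.95) -> ICCResult:
    """ICC for two fixed raters, two-way mixed model, single measures.

    Parameters
    ----------
    a, b : array-like
        Paired measurements (one target per entry), e.g. per-ROI cell counts
        from the reference standard and from a detector.
    variant : {"consistency", "absolute_agreement"}
        ``consistency`` is ICC(3,1); ``absolute_agreement`` is ICC(A,1),
        which additionally penalizes a systematic rater offset.
    ci : float
        Confidence level of the interval (default 95%).

    Notes
    -----
    Identical series give ICC exactly 1.  A table with no variance at all is
    degenerate and raises.  The significance test is the one-sided F test of
    ICC = 0 with F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.
    """
    a, b = _paired(a, b, min_n=3)
    if variant not in (CONSISTENCY, ABSOLUTE_AGREEMENT):
        raise ValidationError(f"unknown ICC variant {variant!r}")
    msr, msc, mse, n, k = _mean_squares(a, b)
    if np.array_equal(a, b):
        # exact agreement: residual mean square is zero by construction, but
        # the sum-of-squares decomposition leaves float dust; force it
        mse = 0.0
    if msr == 0 and msc == 0 and mse == 0:
        raise DegenerateDataError("ICC undefined: the table has zero total variance")
    df1, df2 = n - 1, (n - 1) * (k - 1)
    alpha = 1.0 - ci

    if mse == 0:
        # Raters agree exactly on every target (up to a constant column shift
        # for the consistency form): perfect reliability, no sampling noise.
        if variant == CONSISTENCY or msc == 0:
            return ICCResult(1.0, 1.0, 1.0, math.inf, df1, df2, 0.0, variant)

    f_value = msr / mse if mse > 0 else math.inf
    p_value = float(sps.f.sf(f_value, df1, df2)) if mse > 0 else 0.0

    if variant == CONSISTENCY:
        icc = (msr - mse) / (msr + (k - 1) * mse)
        fl = f_value / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_value * sps.f.ppf(1 - alpha / 2, df2, df1)
        ci_low = (fl - 1) / (fl + k - 1)
        ci_high = (fu - 1) / (fu + k - 1)
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        # McGraw & Wong (1996) CI for ICC(A,1) with Satterthwaite df.
        r = icc
        av = k * r / (n * (1 - r)) if r < 1 else math.inf
        bv = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else math.inf
        if math.isinf(av):
            ci_low = ci_high = 1.0
        else:
            num = (av * msc + bv * mse) ** 2
            den = (av * msc) ** 2 / (k - 1) + (bv * mse) ** 2 / ((n - 1) * (k - 1))
            nu = num / den if den > 0 else 1.0
            f_star_l = sps.f.ppf(1 - alpha / 2, n - 1, nu)
            f_star_u = sps.f.ppf(1 - alpha / 2, nu, n - 1)
            denom_const = k * msc + (k * n - k - n) * mse
            ci_low = n * (msr - f_star_l * mse) / (f_star_l * denom_const + n * msr)
            ci_high = n * (f_star_u * msr - mse) / (denom_const + n * f_star_u * msr)

    ci_low = min(max(ci_low, -1.0), 1.0)
    ci_high = min(max(ci_high, ci_low), 1.0)
    icc = min(max(icc, -1.0), 1.0)
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return ICCResult(float(icc), float(ci_low), float(ci_high),
                     float(f_value), df1, df2, p_value, variant)


# ---------------------------------------------------------------------------
# Nonparametric Bland-Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    """Median bias and percentile limits of agreement for paired differences.

    Differences are oriented ``a - b`` (by convention reference minus tool, so
    a tool that over-estimates produces negative differences).
    """

    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {"bias": self.bias, "loa_low": self.loa_low, "loa_high": self.loa_high}


def bland_altman_nonparametric(a, b) -> BlandAltmanResult:
    """Nonparametric Bland-Altman summary of the agreement between two series.

    Bias is the median of the differences ``a - b``; the limits of agreement
    are their 2.5th and 97.5th percentiles, using linear interpolation between
    closest order statistics (the common "type 7" definition).
    """
    a, b = _paired(a, b, min_n=2)
    diffs = a - b
    means = (a + b) / 2.0
    lo, hi = np.percentile(diffs, [2.5, 97.5], method="linear")
    return BlandAltmanResult(
        bias=float(np.median(diffs)),
        loa_low=float(lo),
        loa_high=float(hi),
        means=means,
        diffs=diffs,
    )


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided paired signed-rank test.

    ``statistic`` is the smaller of the positive/negative signed-rank sums;
    ``n_effective`` counts pairs after zero differences are dropped.
    ``method`` is ``exact`` (full null enumeration; used for small tie-free
    samples), ``normal_approx`` (tie-corrected, no continuity correction) or
    ``degenerate`` when every difference is zero.
    """

    statistic: float
    n_effective: int
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "n_effective": self.n_effective,
            "p_value": self.p_value, "method": self.method,
        }


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test of ``a`` vs ``b``.

    Zero differences are dropped (standard signed-rank practice).  The exact
    null distribution is used when the effective sample size is at most 25
    and the absolute differences are tie-free; otherwise a tie-corrected
    normal approximation without continuity correction.
    """
    a, b = _paired(a, b, min_n=1)
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, n_effective=0, p_value=1.0,
                              method="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    statistic = min(w_pos, w_neg)
    has_ties = np.unique(np.abs(d)).size < n
    if n <= _WILCOXON_EXACT_N and not has_ties:
        res = sps.wilcoxon(d, zero_method="wilcox", correction=False,
                           alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", correction=False,
                           alternative="two-sided", method="approx")
        method = "normal_approx"
    return WilcoxonResult(statistic=statistic, n_effective=n,
                          p_value=float(res.pvalue), method=method)


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementReport:
    """All agreement statistics for one paired series (reference vs tool)."""

    icc_consistency: ICCResult
    icc_absolute: ICCResult
    bland_altman: BlandAltmanResult
    wilcoxon: WilcoxonResult

    def to_dict(self) -> dict:
        return {
            "icc_consistency": self.icc_consistency.to_dict(),
            "icc_absolute_agreement": self.icc_absolute.to_dict(),
            "bland_altman": self.bland_altman.to_dict(),
            "wilcoxon": self.wilcoxon.to_dict(),
        }


def agreement_report(a, b) -> AgreementReport:
    """Compute ICC (both variants), Bland-Altman and Wilcoxon for one pair of
    series, oriented ``a`` = reference, ``b`` = tool."""
    return AgreementReport(
        icc_consistency=icc_two_way_mixed_single(a, b, CONSISTENCY),
        icc_absolute=icc_two_way_mixed_single(a, b, ABSOLUTE_AGREEMENT),
        bland_altman=bland_altman_nonparametric(a, b),
        wilcoxon=wilcoxon_signed_rank(a, b),
    )
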