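"""Method-agreement statistics: Pearson, ICC, Bland-Altman.

Two GFR estimates on the same patients are compared by (i) the Pearson
correlation with a Fisher-z 95% CI, (ii) the single-measures intraclass
correlation from the two-way ANOVA mean squares (Shrout-Fleiss), with
F-distribution confidence bounds and the Koo & Li quality categories, and
(iii) Bland-Altman bias with its t-based CI and 1.96-SD limits of agreement.

Differences are taken second-series-minus-first (new method minus
reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .frames import ValidationError

__all__ = [
    "PairedSeries",
    "AgreementResult",
    "pearson_ci",
    "icc_two_way",
    "classify_icc",
    "bland_altman",
    "compare",
]


@dataclass(frozen=True)
class PairedSeries:
    """Paired measurements of the same quantity by two methods."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValidationError("x and y must be 1-d and the same length")
        if x.size < 3:
            raise ValidationError("need at least 3 pairs")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise ValidationError("missing/non-finite values are not allowed")

    @property
    def n(self) -> int:
        return int(self.x.size)

    def subset(self, mask: np.ndarray) -> "PairedSeries":
        mask = np.asarray(mask, dtype=bool)
        labels = (
            tuple(np.asarray(self.labels)[mask]) if self.labels is not None else None
        )
        return PairedSeries(self.x[mask], self.y[mask], labels)


def pearson_ci(s: PairedSeries) -> tuple[float, float, float]:
    """Pearson r with a 95% Fisher-z confidence interval (needs n >= 4)."""
    if s.n < 4:
        raise ValidationError("Pearson CI needs at least 4 pairs")
    if np.std(s.x) == 0 or np.std(s.y) == 0:
        raise ValidationError("correlation undefined: a series has zero variance")
    r = float(stats.pearsonr(s.x, s.y).statistic)
    if abs(r) >= 1.0:  # degenerate perfect correlation
        return r, r, r
    z = np.arctanh(r)
    half = stats.norm.ppf(0.975) / np.sqrt(s.n - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


def _two_way_mean_squares(s: PairedSeries) -> tuple[float, float, float, int, int]:
    """Mean squares of the two-way (subjects x raters) ANOVA, k = 2 raters."""
    data = np.column_stack([s.x, s.y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_tot = float(np.sum((data - grand) ** 2))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_two_way(
    s: PairedSeries, form: str = "consistency"
) -> tuple[float, float, float]:
    """Single-measures two-way ICC with 95% confidence bounds.

    ``form="consistency"`` is ICC(3,1) of the two-way mixed model (the
    default here); ``form="agreement"`` is ICC(2,1), which additionally
    penalizes a systematic offset between the methods.  Bounds follow
    Shrout-Fleiss / McGraw-Wong.
    """
    msr, msc, mse, n, k = _two_way_mean_squares(s)
    if msr == 0 and mse == 0:
        raise ValidationError("ICC undefined: no between-subject variance")
    alpha = 0.05
    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:  # perfect consistency
            return float(icc), float(icc), float(icc)
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lower = (fl - 1) / (fl + k - 1)
        upper = (fu - 1) / (fu + k - 1)
        return float(icc), float(lower), float(upper)
    if form == "agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom
        if mse == 0 and msc == 0:
            return float(icc), float(icc), float(icc)
        # Satterthwaite df for the (a*MSC + b*MSE) combination
        a = k * icc / (n * (1 - icc)) if icc < 1 else 0.0
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else 1.0
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
        f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
        lower = (
            n * (msr - f_star * mse)
            / (f_star * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        upper = (
            n * (f_star2 * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_star2 * msr)
        )
        return float(icc), float(lower), float(upper)
    raise ValidationError(f"unknown ICC form {form!r}")


def classify_icc(icc: float) -> str:
    """Koo & Li reliability category for an ICC point estimate."""
    if not -1.0 <= icc <= 1.0:
        raise ValidationError(f"ICC must lie in [-1, 1], got {icc}")
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


def bland_altman(
    s: PairedSeries,
) -> tuple[float, tuple[float, float], float, float]:
    """Bland-Altman bias, its 95% CI, and 1.96-SD limits of agreement.

    Differences are y - x.  Returns (bias, (ci_lo, ci_hi), loa_low, loa_high).
    """
    d = s.y - s.x
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return (
        bias,
        (bias - float(half), bias + float(half)),
        bias - 1.96 * sd,
        bias + 1.96 * sd,
    )


@dataclass(frozen=True)
class AgreementResult:
    """The full comparison battery for one method pair."""

    pcc: float
    pcc_ci: tuple[float, float]
    icc: float
    icc_bounds: tuple[float, float]
    icc_category: str
    bias: float
    bias_ci: tuple[float, float]
    loa: tuple[float, float]
    n: int


def compare(s: PairedSeries, icc_form: str = "consistency") -> AgreementResult:
    """Run Pearson + ICC + Bland-Altman on one paired series."""
    r, r_lo, r_hi = pearson_ci(s)
    icc, icc_lo, icc_hi = icc_two_way(s, form=icc_form)
    bias, bias_ci, loa_lo, loa_hi = bland_altman(s)
    return AgreementResult(
        pcc=r,
        pcc_ci=(r_lo, r_hi),
        icc=icc,
        icc_bounds=(icc_lo, icc_hi),
        icc_category=classify_icc(icc),
        bias=bias,
        bias_ci=bias_ci,
        loa=(loa_lo, loa_hi),
        n=s.n,
    )
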