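"""Reproducibility and association statistics.

Scan-rescan agreement is summarized with the two-way random-effects,
single-measurement, absolute-agreement intraclass correlation ICC(A,1) in
the McGraw-Wong taxonomy, computed from the two-way ANOVA mean squares

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with the F-distribution 95% confidence interval for that form. The variant
is fixed and labelled explicitly in the result, since "absolute agreement"
alone admits several two-way models.

Associations between the volumetric and conventional morphometric measures
use Pearson's product-moment correlation; summaries are mean +/- sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError

__all__ = ["ICCResult", "icc_agreement", "pearson_correlation", "summarize"]


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_measurements: int
    variant: str = "ICC(A,1)"

    def __post_init__(self):
        if not (self.ci_low <= self.icc <= self.ci_high):
            raise ValueError("confidence bounds must bracket the ICC")

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "icc": float(self.icc),
            "ci95": [float(self.ci_low), float(self.ci_high)],
            "mean_squares": {
                "rows": float(self.ms_rows),
                "columns": float(self.ms_cols),
                "error": float(self.ms_error),
            },
            "n_subjects": int(self.n_subjects),
            "k_measurements": int(self.k_measurements),
        }


def _validate_table(table) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValidationError("rating table must be 2D (subjects x measurements)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need >= 2 subjects and >= 2 measurements, got {x.shape}")
    if not np.isfinite(x).all():
        raise ValidationError("rating table has missing/non-finite cells")
    return x


def _anova_mean_squares(x: np.ndarray) -> Tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows = subjects, columns = measurements)."""
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * ((row_m - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_m - grand) ** 2).sum() / (k - 1)
    resid = x - row_m[:, None] - col_m[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_agreement(table, confidence: float = 0.95) -> ICCResult:
    """Absolute-agreement ICC(A,1) with its F-method confidence interval.

    Rows are subjects, columns repeated measurements (e.g. scan 1 / scan 2
    of the same hemisphere). Raises for tables with zero total variance,
    where agreement is undefined.
    """
    x = _validate_table(table)
    n, k = x.shape
    if np.ptp(x) == 0:
        raise DegenerateInputError("rating table is constant; ICC undefined")
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise DegenerateInputError("zero total variance; ICC undefined")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse <= 0 and msc <= 0:
        lo = hi = icc  # exact agreement: interval degenerates
    else:
        one_minus = max(1.0 - icc, 1e-12)
        a = (k * icc) / (n * one_minus)
        b = 1.0 + (k * icc * (n - 1)) / (n * one_minus)
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / max(v_den, 1e-300)
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        lo = float(np.clip(min(lo, icc), -1.0, 1.0))
        hi = float(np.clip(max(hi, icc), -1.0, 1.0))
    return ICCResult(
        icc=float(icc),
        ci_low=lo,
        ci_high=hi,
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        n_subjects=n,
        k_measurements=k,
    )


def pearson_correlation(x, y) -> Tuple[float, float]:
    """Pearson r with a two-sided p from the t-transform (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1D and of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant series")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def summarize(values) -> Tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n - 1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("need a 1D series of length >= 2 to compute an SD")
    return float(v.mean()), float(v.std(ddof=1))
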