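"""Reliability and association statistics for fitted parameters.

Test-retest reliability uses the two-way, absolute-agreement,
single-measure intraclass correlation ICC(2,1) with an F-based confidence
interval; associations use Spearman's rank correlation with a seeded
permutation test.  Reliability is intended to be computed on the
unconstrained parameter scale, where the fitting prior is Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ICCResult", "icc21", "spearman_perm"]


@dataclass
class ICCResult:
    """ICC(2,1) point estimate with a 95 % confidence interval."""

    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_occasions: int


def icc21(ratings, confidence: float = 0.95) -> ICCResult:
    """Two-way absolute-agreement single-measure intraclass correlation.

    ``ratings`` is an (n subjects x k occasions) matrix with no missing
    cells.  From the two-way ANOVA mean squares (rows = subjects,
    columns = occasions, error = residual):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

    The confidence interval follows the standard F-based construction for
    this ICC form.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 occasions")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        warnings.warn(
            "degenerate (constant) ratings matrix; ICC defined as 1 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return ICCResult(1.0, np.nan, np.nan, msr, msc, mse, n, k)
    r = (msr - mse) / denom

    # F-based interval (two-way agreement, single measure)
    alpha = 1.0 - confidence
    fj = msc / mse if mse > 0 else np.inf
    a = k * r / (n * (1.0 - r)) if r < 1.0 else np.inf
    b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r)) if r < 1.0 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1.0 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:
        lo = hi = np.nan
    return ICCResult(float(r), float(lo), float(hi), msr, msc, mse, n, k)


def spearman_perm(
    x, y, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Spearman correlation with a two-sided seeded permutation test.

    The statistic is the Pearson correlation of (average-tie) ranks; the
    p-value uses the add-one correction
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm) so it can never be 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranks")

    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    r_obs = float(rxc @ ryc / denom)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(ryc) for _ in range(n_perm)])
    r_perm = perms @ rxc / denom
    hits = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    p = (1 + hits) / (1 + n_perm)
    return r_obs, p
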