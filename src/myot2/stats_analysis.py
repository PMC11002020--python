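"""Method-agreement statistics: Bland-Altman, Lin's concordance, Pearson.

Bland-Altman limits of agreement use the sample standard deviation (n-1) of
the paired differences; the bias is tested against zero with a two-sided
one-sample t-test.  Lin's concordance correlation coefficient is computed
with population (1/n) moments, per its original definition — the choice
matters at small n, so it is fixed and documented here.  Results report the
LOA half-width (+/- 1.96 SD) alongside the limits, matching the customary
"bias +/- half-width" presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["AgreementResult", "bland_altman", "lin_ccc", "pearson_corr", "agreement_report"]


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    loa_half_width: float
    bias_p_value: float
    r_c: float
    pearson_r: float
    n: int


def _check_pair(x, y, min_n=3):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def bland_altman(x, y) -> tuple[float, tuple[float, float], float]:
    """Bias, (low, high) limits of agreement, and bias-test p-value.

    Differences are ``x - y``; LOA = bias +/- 1.96 * sample SD.
    """
    x, y = _check_pair(x, y)
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        p = 0.0 if bias != 0 else 1.0
    else:
        p = float(sps.ttest_1samp(d, 0.0).pvalue)
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd), p


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x, y = _check_pair(x, y)
    vx, vy = np.var(x), np.var(y)
    if vx == 0 or vy == 0:
        raise ValueError("lin_ccc undefined for zero-variance input")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided t-based p-value."""
    x, y = _check_pair(x, y)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = sps.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def agreement_report(x, y) -> AgreementResult:
    """All agreement metrics between two paired measurement series."""
    x, y = _check_pair(x, y)
    bias, (lo, hi), p = bland_altman(x, y)
    r, _ = pearson_corr(x, y)
    return AgreementResult(
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        loa_half_width=(hi - lo) / 2.0,
        bias_p_value=p,
        r_c=lin_ccc(x, y),
        pearson_r=r,
        n=int(x.size),
    )
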