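"""Reliability and validity estimators for the SAHL instrument.

Cronbach's alpha (internal consistency), ICC(2,1) (two-way random effects,
absolute agreement, single measurement — the standard test-retest form), and
Pearson convergent validity against the biologically anchored density metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._errors import ConfigError, StateError, UndefinedStatisticError

__all__ = [
    "ReliabilityReport",
    "cronbach_alpha",
    "icc_test_retest",
    "convergent_validity",
]


@dataclass(frozen=True)
class ReliabilityReport:
    alpha_baseline: float
    alpha_week24: float
    icc_test_retest: float
    convergent_r: float

    def to_dict(self) -> dict:
        return {
            "alpha_baseline": self.alpha_baseline,
            "alpha_week24": self.alpha_week24,
            "icc_test_retest": self.icc_test_retest,
            "convergent_r": self.convergent_r,
        }


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha from the item variance / total variance decomposition.

        alpha = k/(k-1) * (1 - sum_j var(item_j) / var(sum_j item_j))

    Sample variances use the n-1 denominator.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ConfigError("items must be a 2-D matrix with at least 2 columns")
    if x.shape[0] < 2:
        raise ConfigError("need at least 2 subjects")
    k = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError("total score has zero variance")
    item_vars = np.var(x, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def icc_test_retest(s0: np.ndarray, s24: np.ndarray, form: str = "icc2_1") -> float:
    """Intraclass correlation between the two measurement occasions.

    ``icc2_1`` (default) is ICC(2,1): two-way random effects, absolute
    agreement, single measurement, from the mean-squares decomposition of the
    subjects x occasions table:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    ``icc3_1`` (two-way mixed, consistency) is available behind the ``form``
    parameter.
    """
    a = np.asarray(s0, dtype=float)
    b = np.asarray(s24, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StateError("s0 and s24 must be 1-D vectors of equal length")
    n = a.size
    if n < 3:
        raise StateError("need at least 3 subjects")
    x = np.column_stack([a, b])
    k = 2
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
    if form == "icc2_1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif form == "icc3_1":
        denom = msr + (k - 1) * mse
    else:
        raise ConfigError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise UndefinedStatisticError("ICC denominator is zero")
    return float((msr - mse) / denom)


def convergent_validity(s24: np.ndarray, d24: np.ndarray) -> float:
    """Signed Pearson correlation between Week-24 severity and density.

    Under the generative model severity and density move in opposite
    directions, so the signed value is negative; consumers comparing against
    a magnitude should take ``abs``.
    """
    a = np.asarray(s24, dtype=float)
    b = np.asarray(d24, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise StateError("inputs must be equal-length 1-D vectors, length >= 3")
    if np.var(a) == 0 or np.var(b) == 0:
        raise UndefinedStatisticError("zero variance input")
    return float(stats.pearsonr(a, b).statistic)
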