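"""Cohort-level outlier flagging via the skew-adjusted boxplot.

The per-sample dispersion scores are summarized with a medcouple-adjusted
(Hubert-Vandervieren) boxplot.  The upper fence is the cohort quality
threshold sigma_t; samples whose score strictly exceeds it fail QC.  Only the
upper fence is used — unusually low dispersion is not a failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_is_fitted, column_or_1d

from .bln import SampleFit
from .exceptions import CohortTooSmallError, ValidationError

__all__ = [
    "CohortQCResult",
    "medcouple",
    "adjusted_fences",
    "qc_cohort",
    "AdjustedBoxplotDetector",
]


def medcouple(values: Sequence[float]) -> float:
    """Robust skewness statistic in [-1, 1]; 0 for symmetric samples.

    Median over all pairs (x_i <= m <= x_j) of the kernel
    h = ((x_j - m) - (m - x_i)) / (x_j - x_i), with the sign kernel
    sign(i + j - (k - 1)) on the k-by-k block of observations tied with the
    median m.  O(n^2) all-pairs evaluation; adequate for cohort-size inputs.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 3:
        raise ValidationError(f"medcouple needs at least 3 values, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("medcouple requires finite values")
    m = np.median(x)
    z = x - m
    lower = z[z <= 0.0]  # ascending, ties with the median last
    upper = z[z >= 0.0]  # ascending, ties with the median first

    denom = upper[:, None] - lower[None, :]
    numer = upper[:, None] + lower[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        h = numer / denom

    k = int(np.sum(lower == 0.0))  # == number of upper zeros
    if k:
        i = np.arange(k)[:, None]  # rows: zeros lead the upper group
        j = np.arange(k)[None, :]  # cols: zeros trail the lower group
        h[:k, lower.size - k :] = np.sign(i + j - (k - 1))
    return float(np.median(h))


def adjusted_fences(
    values: Sequence[float],
) -> tuple[float, float, float, float, float]:
    """Skew-adjusted boxplot fences.

    Returns (lower_fence, upper_fence, medcouple, q1, q3) with quartiles by
    linear interpolation (R type 7).  With MC = medcouple and IQR = q3 - q1:

        MC >= 0:  [q1 - 1.5*exp(-4*MC)*IQR, q3 + 1.5*exp(+3*MC)*IQR]
        MC <  0:  [q1 - 1.5*exp(-3*MC)*IQR, q3 + 1.5*exp(+4*MC)*IQR]

    At MC = 0 both reduce to the classic Tukey fences.
    """
    x = np.asarray(values, dtype=float)
    mc = medcouple(x)
    q1, q3 = np.quantile(x, [0.25, 0.75])  # type 7 / linear
    iqr = q3 - q1
    if mc >= 0:
        lower = q1 - 1.5 * np.exp(-4.0 * mc) * iqr
        upper = q3 + 1.5 * np.exp(3.0 * mc) * iqr
    else:
        lower = q1 - 1.5 * np.exp(-3.0 * mc) * iqr
        upper = q3 + 1.5 * np.exp(4.0 * mc) * iqr
    return float(lower), float(upper), float(mc), float(q1), float(q3)


@dataclass
class CohortQCResult:
    """Cohort scores, adjusted-boxplot threshold and per-sample flags.

    ``flags`` maps sample_id -> 'pass'/'fail' (strict sigma_hat > sigma_t, or
    non-convergence); ``annotations`` explains non-score-based failures.
    """

    fits: list[SampleFit]
    q1: float
    median: float
    q3: float
    medcouple: float
    sigma_t: float
    flags: dict[str, str]
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def n_pass(self) -> int:
        return sum(1 for v in self.flags.values() if v == "pass")

    @property
    def n_fail(self) -> int:
        return sum(1 for v in self.flags.values() if v == "fail")


def qc_cohort(fits: Iterable[SampleFit]) -> CohortQCResult:
    """Derive the cohort threshold sigma_t and flag each sample.

    The fence is estimated from converged fits only; non-converged fits are
    flagged 'fail' with an annotation and take no part in the threshold.
    A sample fails iff sigma_hat > sigma_t (strict), so a score exactly at
    the threshold passes.
    """
    fits = list(fits)
    converged = [f for f in fits if f.converged]
    if len(converged) < 3:
        raise CohortTooSmallError(
            f"need at least 3 converged fits to derive a threshold, got {len(converged)}"
        )
    scores = np.array([f.sigma_hat for f in converged])
    _, sigma_t, mc, q1, q3 = adjusted_fences(scores)
    med = float(np.median(scores))

    flags: dict[str, str] = {}
    annotations: dict[str, str] = {}
    for f in fits:
        if not f.converged:
            flags[f.sample_id] = "fail"
            annotations[f.sample_id] = "non_converged"
        else:
            flags[f.sample_id] = "fail" if f.sigma_hat > sigma_t else "pass"
    return CohortQCResult(
        fits=fits,
        q1=q1,
        median=med,
        q3=q3,
        medcouple=mc,
        sigma_t=float(sigma_t),
        flags=flags,
        annotations=annotations,
    )


class AdjustedBoxplotDetector(OutlierMixin, BaseEstimator):
    """Skew-adjusted boxplot outlier detector over 1-D scores, sklearn-style.

    ``fit`` learns the quartiles, medcouple and fences from the training
    scores; ``predict`` returns +1 (inlier) / -1 (outlier), where only values
    strictly above the upper fence are outliers.
    """

    def fit(self, X, y=None):
        x = column_or_1d(np.atleast_1d(np.asarray(X, dtype=float).squeeze()))
        lower, upper, mc, q1, q3 = adjusted_fences(x)
        self.q1_ = q1
        self.median_ = float(np.median(x))
        self.q3_ = q3
        self.medcouple_ = mc
        self.lower_fence_ = lower
        self.upper_fence_ = upper
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        """Positive for inliers: upper_fence - score."""
        check_is_fitted(self, "upper_fence_")
        x = column_or_1d(np.atleast_1d(np.asarray(X, dtype=float).squeeze()))
        return self.upper_fence_ - x

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "upper_fence_")
        return np.where(self.decision_function(X) >= 0.0, 1, -1)
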