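"""Cohort-level orchestration: fit every sample, then threshold.

Samples are statistically independent, so the cohort fit is embarrassingly
parallel; scheduling must not change results, and does not — each fit is
deterministic given its records and config, and results are collected in
sample order regardless of completion order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from joblib import Parallel, delayed

from .bln import FitConfig, SampleFit, fit_sample
from .exceptions import InsufficientDataError
from .outliers import CohortQCResult, qc_cohort

__all__ = ["SampleStatus", "fit_cohort", "qc_pipeline"]

STATUS_OK = "ok"
STATUS_INSUFFICIENT = "insufficient_data"
STATUS_NON_CONVERGED = "non_converged"


@dataclass(frozen=True)
class SampleStatus:
    """Outcome of one sample's fit attempt (soft-failure model)."""

    sample_id: str
    status: str
    fit: SampleFit | None = None
    message: str = ""


def _fit_one(sample_id: str, records: pd.DataFrame, config: FitConfig) -> SampleStatus:
    try:
        fit = fit_sample(records, config, sample_id=sample_id)
    except InsufficientDataError as exc:
        return SampleStatus(sample_id, STATUS_INSUFFICIENT, None, str(exc))
    status = STATUS_OK if fit.converged else STATUS_NON_CONVERGED
    return SampleStatus(sample_id, status, fit)


def fit_cohort(
    records: pd.DataFrame, config: FitConfig | None = None, threads: int = 1
) -> list[SampleStatus]:
    """Fit every sample in a gene-level table; never raises per-sample errors.

    Returns one :class:`SampleStatus` per sample, ordered by sample_id.
    Samples with too few usable genes are reported as ``insufficient_data``
    rather than aborting the cohort.
    """
    config = config or FitConfig()
    groups = [(str(sid), grp) for sid, grp in records.groupby("sample_id", sort=True)]
    if threads > 1:
        results = Parallel(n_jobs=threads)(
            delayed(_fit_one)(sid, grp, config) for sid, grp in groups
        )
    else:
        results = [_fit_one(sid, grp, config) for sid, grp in groups]
    return list(results)


def qc_pipeline(
    records: pd.DataFrame, config: FitConfig | None = None, threads: int = 1
) -> tuple[CohortQCResult, list[SampleStatus]]:
    """Fit the cohort and derive the outlier threshold in one step.

    Samples without a fit (insufficient data) are excluded from thresholding
    entirely; non-converged fits are excluded from the fence but flagged fail.
    """
    statuses = fit_cohort(records, config, threads=threads)
    fits = [s.fit for s in statuses if s.fit is not None]
    result = qc_cohort(fits)
    for s in statuses:
        if s.fit is None:
            result.annotations[s.sample_id] = STATUS_INSUFFICIENT
    return result, statuses
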