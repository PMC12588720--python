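"""Per-subject, per-ROI linear tau-PET trajectories and annual percent change.

For every subject and ROI with at least two scans, an ordinary least squares
line ``SUVR = b0 + b1 * time`` is fitted over follow-up time in years; the
relative change rate is ``100 * b1 / b0`` percent per year, normalising the
slope by the fitted baseline SUVR (the model value at time 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoiTrajectory:
    beta0: float           # fitted SUVR at time 0
    beta1: float           # SUVR per year
    residual_sd: float
    pct_change: float      # percent per year; NaN when beta0 <= 0
    n_timepoints: int


def fit_trajectory(timepoints: np.ndarray, suvrs: np.ndarray,
                   baseline: str = "fitted") -> RoiTrajectory:
    """OLS line through one ROI's SUVR series.

    ``baseline`` selects the denominator of the percent change: the fitted
    intercept (``"fitted"``, default) or the observed first scan
    (``"observed"``).  With exactly two scans the slope is the exact
    difference quotient.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(suvrs, dtype=float)
    if t.size != y.size or t.size < 2:
        raise InvalidArgumentError("need >= 2 matching timepoints")
    if np.ptp(t) == 0:
        raise InvalidArgumentError("undefined slope: all timepoints identical")
    if t[0] != 0:
        logger.info("shifting timepoints so the first scan is at t=0")
        t = t - t[0]

    beta1, beta0 = np.polyfit(t, y, 1)
    resid = y - (beta0 + beta1 * t)
    dof = t.size - 2
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0

    denom = beta0 if baseline == "fitted" else y[np.argmin(t)]
    pct = 100.0 * beta1 / denom if denom > 0 else float("nan")
    return RoiTrajectory(beta0=float(beta0), beta1=float(beta1),
                         residual_sd=residual_sd, pct_change=float(pct),
                         n_timepoints=int(t.size))


def cohort_change_maps(cohort: pd.DataFrame, value: str = "suvr",
                       baseline: str = "fitted") -> pd.DataFrame:
    """Annual percent change per subject x ROI from a longitudinal cohort.

    Subjects with a single scan are excluded (logged); ROIs with a
    non-positive fitted baseline are set missing (logged).  Returns a
    long-format table (subject_id, roi_id, beta0, beta1, pct_change).
    """
    n_scans = cohort.groupby("subject_id")["timepoint_years"].nunique()
    single = n_scans[n_scans < 2].index
    if len(single):
        logger.warning("cohort_change_maps: excluding %d single-scan subject(s)",
                       len(single))
    usable = cohort[~cohort["subject_id"].isin(single)]

    rows = []
    n_flagged = 0
    for subject, block in usable.groupby("subject_id"):
        wide = block.pivot(index="timepoint_years", columns="roi_id", values=value)
        t = wide.index.to_numpy(dtype=float) - float(wide.index.min())
        beta1, beta0 = np.polyfit(t, wide.to_numpy(), 1)  # vectorized over ROIs
        if baseline == "fitted":
            denom = beta0
        else:
            denom = wide.to_numpy()[np.argmin(t)]
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(denom > 0, 100.0 * beta1 / denom, np.nan)
        n_flagged += int(np.isnan(pct).sum())
        rows.append(pd.DataFrame({"subject_id": subject, "roi_id": wide.columns,
                                  "beta0": beta0, "beta1": beta1,
                                  "pct_change": pct}))
    if n_flagged:
        logger.warning("cohort_change_maps: %d ROI fit(s) with non-positive "
                       "baseline set missing", n_flagged)
    return pd.concat(rows, ignore_index=True)
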