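"""Tab-delimited readers/writers for matrices and long-format tables.

All tabular artefacts are plain TSV with header rows.  Square ROI x ROI
matrices carry the roi_id both as header row and as first column; infinite
distances (disconnected pairs) are encoded as the literal string ``inf``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

COHORT_COLUMNS = [
    "subject_id", "roi_id", "timepoint_years", "suvr",
    "tracer", "site", "age", "sex", "group",
]


def write_matrix(matrix: np.ndarray, path) -> None:
    """Write a square matrix as TSV with roi_id header row/column."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise InvalidArgumentError(f"expected a square matrix, got shape {matrix.shape}")
    ids = np.arange(matrix.shape[0])
    frame = pd.DataFrame(matrix, index=ids, columns=ids)
    frame.to_csv(path, sep="\t", index_label="roi_id")


def read_matrix(path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", index_col="roi_id")
    return frame.to_numpy(dtype=float)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a long-format tau cohort table."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise InvalidArgumentError(f"cohort table missing columns: {missing}")
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def cohort_to_wide(cohort: pd.DataFrame, value: str = "suvr",
                   timepoint: float | None = 0.0) -> pd.DataFrame:
    """Pivot a long cohort table to a subject x ROI matrix.

    Parameters
    ----------
    value:
        Column to pivot (``suvr`` or a derived value column).
    timepoint:
        Restrict to a single timepoint (default: baseline, 0.0).  ``None``
        keeps all rows (caller must guarantee uniqueness of subject x ROI).
    """
    frame = cohort
    if timepoint is not None and "timepoint_years" in frame.columns:
        frame = frame[frame["timepoint_years"] == timepoint]
    wide = frame.pivot(index="subject_id", columns="roi_id", values=value)
    return wide.sort_index(axis=1)


def subject_metadata(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row of metadata (tracer, site, age, sex, group) per subject."""
    cols = [c for c in ("tracer", "site", "age", "sex", "group") if c in cohort.columns]
    meta = cohort.groupby("subject_id")[cols].first()
    return meta
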