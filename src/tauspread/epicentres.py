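"""Subject-level tau epicentres and group epicentre-probability maps.

The epicentre of a subject is the set of ROIs carrying the highest tau load:
the top 5% of ROIs (10 of 200) ranked by baseline SUVR.  Accumulation
epicentres use the same rule on annual percent change.  Group probability
maps give, per ROI, the percentage of subjects whose epicentre contains it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError

EPICENTRE_FRACTION = 0.05


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class Epicentre:
    subject_id: str
    roi_set: tuple[int, ...]
    basis: str   # "baseline_suvr" | "pct_change"


def identify_epicentre(values: np.ndarray, k_fraction: float = EPICENTRE_FRACTION,
                       subject_id: str = "", basis: str = "baseline_suvr") -> Epicentre:
    """Top-``k_fraction`` ROIs by value (k rounded half away from zero).

    Boundary ties are broken toward the lower ROI index for determinism.
    NaN values never enter the epicentre; fewer than k finite values is an
    error.
    """
    v = np.asarray(values, dtype=float)
    if not 0 < k_fraction <= 1:
        raise InvalidArgumentError("k_fraction must be in (0, 1]")
    k = _round_half_away(k_fraction * v.size)
    k = max(k, 1)
    finite = np.isfinite(v)
    if finite.sum() < k:
        raise InsufficientDataError(
            f"need >= {k} finite values, got {int(finite.sum())}")
    # sort by (-value, roi_id); NaNs pushed past the end
    key = np.where(finite, -v, np.inf)
    order = np.lexsort((np.arange(v.size), key))
    rois = tuple(sorted(int(i) for i in order[:k]))
    return Epicentre(subject_id=subject_id, roi_set=rois, basis=basis)


def cohort_epicentres(values: pd.DataFrame, k_fraction: float = EPICENTRE_FRACTION,
                      basis: str = "baseline_suvr") -> list[Epicentre]:
    """Identify one epicentre per row of a subject x ROI value table."""
    return [identify_epicentre(row.to_numpy(), k_fraction,
                               subject_id=str(subject), basis=basis)
            for subject, row in values.iterrows()]


def probability_map(epicentres: list[Epicentre], n_roi: int,
                    display_threshold: float = 0.0) -> pd.DataFrame:
    """Per-ROI epicentre probability: selection frequency x 100.

    The full map is always returned in the ``probability`` column; the
    ``displayed`` column zeroes values below ``display_threshold`` (percent)
    for rendering only.
    """
    if not epicentres:
        raise InvalidArgumentError("need at least one epicentre")
    counts = np.zeros(n_roi)
    for epi in epicentres:
        counts[list(epi.roi_set)] += 1
    prob = 100.0 * counts / len(epicentres)
    return pd.DataFrame({
        "roi_id": np.arange(n_roi),
        "probability": prob,
        "displayed": np.where(prob >= display_threshold, prob, 0.0),
    })


def epicentres_to_frame(epicentres: list[Epicentre]) -> pd.DataFrame:
    """Long (subject_id, basis, roi_id) table for on-disk storage."""
    rows = [{"subject_id": e.subject_id, "basis": e.basis, "roi_id": r}
            for e in epicentres for r in e.roi_set]
    return pd.DataFrame(rows)
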