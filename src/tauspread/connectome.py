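"""Group functional connectivity and its shortest-path distance transform.

The connectome template is built from ROI-level BOLD time series of a control
sample: motion-scrub each subject's series, correlate ROI pairs (Fisher z),
average across subjects, keep the strongest 30% of positive connections, and
convert the thresholded graph to a functional distance where an edge of weight
``w`` has length ``1/w`` and the distance between two ROIs is their shortest
weighted path.  Strongly (directly or indirectly) connected regions are
therefore "close"; weakly connected regions are "distant".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist

from .atlas import RoiAtlas
from .errors import EmptyGraphError, InvalidArgumentError

logger = logging.getLogger(__name__)

#: Correlations are clipped to +/- this value before the Fisher z-transform so
#: that duplicated series stay finite.
R_CLIP = 0.999999

#: Frame-wise displacement threshold (mm) above which a frame is scrubbed.
FD_THRESHOLD_MM = 0.5

#: Minimum usable resting-state duration after scrubbing (seconds).
MIN_USABLE_SECONDS = 300.0


@dataclass(frozen=True)
class ScrubReport:
    """Outcome of motion scrubbing one subject's frame-wise displacement trace."""

    kept: np.ndarray            # boolean mask over frames, True = retained
    n_removed: int
    usable_seconds: float
    valid: bool


@dataclass(frozen=True)
class ConnectomeDistance:
    """All-pairs shortest functional path lengths on the thresholded FC graph.

    ``matrix[i, j]`` is dimensionless path length (sum of 1/weight along the
    shortest path); disconnected pairs hold ``inf``.
    """

    matrix: np.ndarray
    density: float

    @property
    def n_roi(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_disconnected_pairs(self) -> int:
        iu = np.triu_indices(self.n_roi, k=1)
        return int(np.isinf(self.matrix[iu]).sum())


def scrub(fd_trace: np.ndarray, tr: float,
          threshold: float = FD_THRESHOLD_MM,
          min_usable_seconds: float = MIN_USABLE_SECONDS) -> ScrubReport:
    """Motion-scrub a frame-wise displacement trace.

    Every frame with FD above ``threshold`` is removed together with one
    preceding and two following frames (windows clipped at the boundaries).
    The report is flagged valid when the retained duration reaches
    ``min_usable_seconds`` (default five minutes).
    """
    fd = np.asarray(fd_trace, dtype=float)
    if fd.size == 0:
        raise InvalidArgumentError("empty frame-wise displacement trace")
    if tr <= 0:
        raise InvalidArgumentError("TR must be positive")
    if np.any(fd < 0):
        raise InvalidArgumentError("frame-wise displacement must be nonnegative")

    kept = np.ones(fd.size, dtype=bool)
    for i in np.flatnonzero(fd > threshold):
        kept[max(i - 1, 0): min(i + 3, fd.size)] = False
    usable = float(kept.sum() * tr)
    return ScrubReport(kept=kept, n_removed=int((~kept).sum()),
                       usable_seconds=usable,
                       valid=usable >= min_usable_seconds)


def compute_fc(series: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Fisher z-transformed Pearson correlations between ROI time series.

    Parameters
    ----------
    series:
        (n_roi, n_frames) BOLD matrix.
    mask:
        Optional boolean kept-frame mask from :func:`scrub`.

    Returns
    -------
    (n_roi, n_roi) symmetric matrix of z = atanh(r) with r clipped to
    +/-0.999999.  The diagonal is NaN (undefined), as are rows/columns of
    zero-variance ROIs.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise InvalidArgumentError("series must be 2-D (ROI x frame)")
    if mask is not None:
        series = series[:, np.asarray(mask, dtype=bool)]
    if series.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 kept frames")

    sd = series.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        logger.warning("compute_fc: %d zero-variance ROI(s) set missing", flat.size)

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(series)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    z[flat, :] = np.nan
    z[:, flat] = np.nan
    np.fill_diagonal(z, np.nan)
    return z


def group_fc(matrices: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean FC across subjects, ignoring missing entries pairwise."""
    if not matrices:
        raise InvalidArgumentError("need at least one FC matrix")
    shapes = {m.shape for m in matrices}
    if len(shapes) != 1:
        raise InvalidArgumentError(f"mismatched atlas sizes: {sorted(shapes)}")
    stack = np.stack([np.asarray(m, dtype=float) for m in matrices])
    finite = np.isfinite(stack)
    counts = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(finite, stack, 0.0).sum(axis=0) / np.where(counts, counts, 1)
    mean[counts == 0] = np.nan
    np.fill_diagonal(mean, np.nan)
    return mean


def threshold_density(fc: np.ndarray, density: float = 0.30) -> np.ndarray:
    """Keep the strongest positive connections at the requested density.

    Among the P positive off-diagonal pairs, the ``ceil(density * P)``
    largest are retained with their weights; everything else (including all
    negative weights) is zeroed.  Ties at the boundary are broken by
    lexicographic ROI-pair order for determinism.
    """
    if not 0 < density <= 1:
        raise InvalidArgumentError(f"density must be in (0, 1], got {density}")
    fc = np.asarray(fc, dtype=float)
    n = fc.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = fc[iu, ju]
    positive = np.flatnonzero(w > 0)  # NaN compares False: missing pairs dropped
    if positive.size == 0:
        raise EmptyGraphError("no positive off-diagonal entries to retain")
    k = math.ceil(density * positive.size)
    # sort by (-weight, i, j): equal weights resolve to the lower ROI pair
    order = np.lexsort((ju[positive], iu[positive], -w[positive]))
    keep = positive[order[:k]]
    out = np.zeros((n, n))
    out[iu[keep], ju[keep]] = w[keep]
    out += out.T
    return out


def fc_to_distance(thresholded: np.ndarray, density: float = 0.30) -> ConnectomeDistance:
    """Transform a thresholded weight matrix to shortest functional path lengths.

    Each retained edge gets length 1/weight; distances are all-pairs shortest
    paths (Dijkstra).  Disconnected pairs are marked infinite and the count is
    logged so downstream regressions can exclude them.
    """
    w = np.asarray(thresholded, dtype=float)
    if np.any(w < 0):
        raise InvalidArgumentError("thresholded matrix must be nonnegative")
    if not np.count_nonzero(w):
        raise EmptyGraphError("thresholded matrix has no edges")
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    dist = shortest_path(csr_matrix(lengths), method="D", directed=False)
    dist = np.minimum(dist, dist.T)  # guard against directed round-off asymmetry
    result = ConnectomeDistance(matrix=dist, density=density)
    if result.n_disconnected_pairs:
        logger.warning("fc_to_distance: %d disconnected ROI pair(s)",
                       result.n_disconnected_pairs)
    return result


def euclidean_distance(atlas: RoiAtlas) -> np.ndarray:
    """Inter-regional Euclidean distance between ROI centroids (millimetres)."""
    coords = atlas.centroids
    return cdist(coords, coords)


def epicentre_distance(dist: ConnectomeDistance | np.ndarray,
                       epicentre: np.ndarray) -> "pd.Series":
    """Mean shortest-path distance from each non-epicentre ROI to the epicentre.

    For each ROI outside the epicentre set, averages its finite distances to
    the epicentre ROIs; ROIs disconnected from the entire epicentre are
    excluded (logged).  Returns a Series indexed by roi_id of length
    ``n_roi - |epicentre|`` (minus any excluded ROI).
    """
    import pandas as pd

    matrix = dist.matrix if isinstance(dist, ConnectomeDistance) else np.asarray(dist)
    epicentre = np.asarray(epicentre, dtype=int)
    n = matrix.shape[0]
    if epicentre.size == 0:
        raise InvalidArgumentError("epicentre set is empty")
    if epicentre.min() < 0 or epicentre.max() >= n:
        raise InvalidArgumentError("epicentre indices outside atlas")

    others = np.setdiff1d(np.arange(n), epicentre)
    block = matrix[np.ix_(others, epicentre)]
    finite = np.isfinite(block)
    counts = finite.sum(axis=1)
    sums = np.where(finite, block, 0.0).sum(axis=1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.Series(means, index=pd.Index(others, name="roi_id"), name="epicentre_distance")
    dropped = out.isna().sum()
    if dropped:
        logger.warning("epicentre_distance: %d ROI(s) disconnected from the epicentre", dropped)
    return out.dropna()
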