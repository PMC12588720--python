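"""ROI parcellation: the spatial frame shared by every matrix in the pipeline.

An atlas is a table of cortical regions of interest (ROIs), each carrying a
resting-state network label, a hemisphere and a centroid in millimetres.  The
default configuration mirrors a 200-ROI cortical parcellation partitioned into
the seven canonical resting-state networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

#: Canonical resting-state network names, used when <= 7 networks are requested.
CANONICAL_NETWORKS = (
    "default_mode",
    "dorsal_attention",
    "ventral_attention",
    "frontoparietal",
    "limbic",
    "motor",
    "visual",
)

ATLAS_COLUMNS = ["roi_id", "roi_name", "network", "hemisphere", "x", "y", "z"]


@dataclass(frozen=True)
class RoiAtlas:
    """Immutable ROI parcellation.

    Parameters
    ----------
    table:
        DataFrame with columns ``roi_id`` (contiguous ints from 0),
        ``roi_name``, ``network``, ``hemisphere`` (``left``/``right``) and
        centroid coordinates ``x``, ``y``, ``z`` in millimetres.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ATLAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise InvalidArgumentError(f"atlas table missing columns: {missing}")
        ids = self.table["roi_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise InvalidArgumentError("roi_ids must be unique and contiguous from 0")
        coords = self.table[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise InvalidArgumentError("centroid coordinates must be finite")
        bad_hemi = set(self.table["hemisphere"]) - {"left", "right"}
        if bad_hemi:
            raise InvalidArgumentError(f"unknown hemisphere labels: {sorted(bad_hemi)}")

    @property
    def n_roi(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        """Network labels in order of first appearance."""
        return list(dict.fromkeys(self.table["network"]))

    @property
    def network_labels(self) -> np.ndarray:
        """Per-ROI network label, aligned with roi_id."""
        return self.table["network"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        """(n_roi, 3) centroid coordinates in millimetres."""
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def rois_in_network(self, network: str) -> np.ndarray:
        """Indices of ROIs belonging to ``network``."""
        return np.flatnonzero(self.table["network"].to_numpy() == network)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RoiAtlas":
        return cls(pd.read_csv(path, sep="\t"))
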