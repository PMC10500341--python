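"""Cell-cycle filters: EdU gating of S-phase nuclei and sister-pair G2 exclusion.

Centromere counts are only meaningful in G1 (one CENP-A punctum per
chromosome).  S-phase nuclei are excluded by thresholding mean EdU intensity
within the segment mask; late-S/G2 nuclei — EdU-negative but with replicated
centromeres — are excluded when more than ``max_pairs`` sister-chromatid pairs
(centromere pairs closer than 0.8 um) are found among the detected spots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator
from scipy.spatial.distance import pdist


class CellCycleParams(BaseModel):
    model_config = dict(frozen=True)

    edu_threshold: float = 300.0  # same intensity scale as the EdU channel
    pair_cutoff_um: float = 0.8
    max_pairs: int = 20

    @field_validator("pair_cutoff_um")
    @classmethod
    def _cutoff(cls, v):
        if v <= 0:
            raise ValueError("pair_cutoff_um must be positive")
        return v

    @field_validator("max_pairs")
    @classmethod
    def _pairs(cls, v):
        if v < 0:
            raise ValueError("max_pairs must be non-negative")
        return v


def _project(mask, channel):
    """Work on the z max-projection: nuclei are flat, so the projected mean
    is not diluted by out-of-nucleus z-slices of the broadcast 3D mask."""
    if channel.ndim == 3:
        channel = channel.max(axis=0)
    if mask.ndim == 3:
        mask = mask.max(axis=0)
    return mask, channel


def edu_filter(
    mask: np.ndarray, edu_channel: np.ndarray, threshold: float
) -> pd.Series:
    """Per-segment ``edu_positive`` flag: mean EdU inside the mask > threshold.

    Flagged nuclei are excluded from centromere counting.  Raises if a label
    has an empty mask (cannot happen for labels produced by segmentation, but
    guards table/mask mismatches).
    """
    mask2d, edu2d = _project(mask, edu_channel)
    labels = np.unique(mask2d)
    labels = labels[labels > 0]
    flags = {}
    for lab in labels:
        sel = mask2d == lab
        if not sel.any():
            raise ValueError(f"segment {lab} has an empty mask")
        flags[int(lab)] = float(edu2d[sel].mean()) > threshold
    return pd.Series(flags, name="edu_positive", dtype=bool)


def segment_mean_edu(mask: np.ndarray, edu_channel: np.ndarray, label: int) -> float:
    mask2d, edu2d = _project(mask, edu_channel)
    sel = mask2d == label
    if not sel.any():
        raise ValueError(f"segment {label} has an empty mask")
    return float(edu2d[sel].mean())


def count_sister_pairs(positions_um: np.ndarray, cutoff_um: float = 0.8) -> int:
    """Number of disjoint centromere pairs closer than ``cutoff_um``.

    Pairs are formed by greedy ascending-distance matching: candidate pairs
    sorted by (distance, index, index), each accepted if neither member is
    already matched.  Each centromere joins at most one pair.  Distances are
    Euclidean in calibrated um coordinates.
    """
    pos = np.asarray(positions_um, dtype=float).reshape(-1, 3)
    if np.isnan(pos).any():
        raise ValueError("spot positions contain NaN")
    n = len(pos)
    if n < 2:
        return 0
    d = pdist(pos)
    ii, jj = np.triu_indices(n, k=1)
    close = d < cutoff_um
    order = np.lexsort((jj[close], ii[close], d[close]))
    used = np.zeros(n, dtype=bool)
    n_pairs = 0
    for k in order:
        i, j = ii[close][k], jj[close][k]
        if not used[i] and not used[j]:
            used[i] = used[j] = True
            n_pairs += 1
    return n_pairs


def g2_filter(positions_um: np.ndarray, params: CellCycleParams) -> bool:
    """True iff the nucleus is excluded as late-S/G2 (> max_pairs sister pairs)."""
    return count_sister_pairs(positions_um, params.pair_cutoff_um) > params.max_pairs
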