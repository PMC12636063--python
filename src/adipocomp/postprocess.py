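"""Mask hygiene and depot-level fatty-acid summaries.

Two filters precede any depot summary: in-slice binary erosion of the depot
mask (to strip partial-volume boundary voxels) and exclusion of voxels whose
fitted fat fraction falls below 20%.  The participant-level trait is the
arithmetic mean of each fraction over the retained voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fitting import FractionMaps

logger = logging.getLogger(__name__)

#: Fat-fraction exclusion threshold: voxels below 20% are dropped.
FF_THRESHOLD = 0.20


def _default_structure(ndim: int) -> np.ndarray:
    """In-slice 3x3 square; no through-slice erosion for 3-D masks."""
    if ndim == 2:
        return np.ones((3, 3), dtype=bool)
    structure = np.zeros((3, 3, 1), dtype=bool)
    structure[:, :, 0] = True
    return structure


def erode_mask(
    mask: np.ndarray, iterations: int = 1, structure: np.ndarray | None = None
) -> np.ndarray:
    """Morphological erosion of a binary mask; output is a subset of input."""
    mask = np.asarray(mask).astype(bool)
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    if iterations == 0 or not mask.any():
        return mask.copy()
    if structure is None:
        structure = _default_structure(mask.ndim)
    return ndimage.binary_erosion(mask, structure=structure, iterations=iterations)


def apply_ff_filter(
    maps: FractionMaps, mask: np.ndarray, threshold: float = FF_THRESHOLD
) -> np.ndarray:
    """Retain mask voxels whose fitted fat fraction is at or above threshold.

    Strictly-below-threshold voxels are excluded; NaN fat fractions (unfitted
    or failed voxels) are excluded as well.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    mask = np.asarray(mask).astype(bool)
    ff = maps.fat_fraction
    with np.errstate(invalid="ignore"):
        keep = np.where(np.isfinite(ff), ff >= threshold, False)
    return mask & keep


@dataclass(frozen=True)
class DepotSummary:
    depot: str
    n_voxels_initial: int
    n_voxels_after_erosion: int
    n_voxels_after_ff_filter: int
    mean_f_sfa: float
    mean_f_mufa: float
    mean_f_pufa: float
    mean_fat_fraction: float
    sd_f_sfa: float
    sd_f_mufa: float
    sd_f_pufa: float
    sd_fat_fraction: float

    @property
    def missing(self) -> bool:
        return self.n_voxels_after_ff_filter == 0


def summarize_depot(
    maps: FractionMaps,
    mask: np.ndarray,
    label: str,
    erosion_iterations: int = 1,
    ff_threshold: float = FF_THRESHOLD,
) -> DepotSummary:
    """Depot mean/SD of the fatty-acid fractions after erosion + FF filter.

    Counts are recorded at each pipeline stage and are monotone
    non-increasing.  An empty retained set yields a summary flagged missing
    (NaN means) with a warning.
    """
    mask = np.asarray(mask).astype(bool)
    n0 = int(mask.sum())
    eroded = erode_mask(mask, iterations=erosion_iterations)
    n1 = int(eroded.sum())
    retained = apply_ff_filter(maps, eroded, threshold=ff_threshold)
    n2 = int(retained.sum())

    def stats(arr):
        vals = arr[retained]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=0))

    if n2 == 0:
        logger.warning("depot %r: no voxels retained; summary is missing", label)
    m_sfa, s_sfa = stats(maps.f_sfa)
    m_mufa, s_mufa = stats(maps.f_mufa)
    m_pufa, s_pufa = stats(maps.f_pufa)
    m_ff, s_ff = stats(maps.fat_fraction)
    return DepotSummary(
        depot=label,
        n_voxels_initial=n0,
        n_voxels_after_erosion=n1,
        n_voxels_after_ff_filter=n2,
        mean_f_sfa=m_sfa,
        mean_f_mufa=m_mufa,
        mean_f_pufa=m_pufa,
        mean_fat_fraction=m_ff,
        sd_f_sfa=s_sfa,
        sd_f_mufa=s_mufa,
        sd_f_pufa=s_pufa,
        sd_fat_fraction=s_ff,
    )
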