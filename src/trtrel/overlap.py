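"""Spatial agreement between two reconstructions of the same bundle.

The weighted Dice similarity coefficient (wDSC) compares two streamline
density maps W_i and W_j on a shared grid:

    D(W_i, W_j) = (sum_{v'} W_i,v' + sum_{v'} W_j,v')
                  / (sum_v W_i,v + sum_v W_j,v)

where v' ranges over voxels with positive weight in *both* maps.  Voxels
visited by many streamlines — the dense bundle core — therefore weigh more
than the sparse fringes.  The unweighted DSC is the usual set overlap
2|A∩B|/(|A|+|B|) of the binary supports.  A wDSC of at least 0.70 is
conventionally read as acceptable test-retest overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bundle_geometry import DensityMap, affines_equal

__all__ = ["OverlapResult", "wdsc", "dsc", "classify_overlap", "WDSC_THRESHOLD"]

WDSC_THRESHOLD = 0.70


@dataclass
class OverlapResult:
    wdsc: float
    dsc: float
    overlap_voxels: int
    support_i: int
    support_j: int
    total_weight_i: float
    total_weight_j: float
    acceptable: bool
    threshold: float = WDSC_THRESHOLD


def _check_pair(wi: DensityMap, wj: DensityMap):
    if wi.data.shape != wj.data.shape:
        raise ValueError("density maps have different grid shapes")
    if not affines_equal(wi.affine, wj.affine):
        raise ValueError("density maps have different affines")
    if wi.total_weight <= 0 or wj.total_weight <= 0:
        raise ValueError("both maps must have positive total weight")


def wdsc(wi: DensityMap, wj: DensityMap,
         threshold: float = WDSC_THRESHOLD) -> OverlapResult:
    """Weighted Dice similarity of two density maps on a common grid.

    Symmetric in its arguments; equals 1 exactly when the two supports are
    identical (regardless of the weights) and 0 when they are disjoint.
    """
    _check_pair(wi, wj)
    si = wi.data > 0
    sj = wj.data > 0
    both = si & sj
    d = float((wi.data[both].sum() + wj.data[both].sum())
              / (wi.data.sum() + wj.data.sum()))
    plain = 2.0 * np.count_nonzero(both) / (np.count_nonzero(si) + np.count_nonzero(sj))
    return OverlapResult(
        wdsc=d,
        dsc=float(plain),
        overlap_voxels=int(np.count_nonzero(both)),
        support_i=int(np.count_nonzero(si)),
        support_j=int(np.count_nonzero(sj)),
        total_weight_i=wi.total_weight,
        total_weight_j=wj.total_weight,
        acceptable=classify_overlap(d, threshold) == "good",
        threshold=threshold,
    )


def dsc(wi: DensityMap, wj: DensityMap) -> float:
    """Unweighted Dice coefficient of the two binary supports."""
    return wdsc(wi, wj).dsc


def classify_overlap(d: float, threshold: float = WDSC_THRESHOLD) -> str:
    """Classify a Dice value against the acceptability threshold (>= passes)."""
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"Dice value {d} outside [0, 1]")
    return "good" if d >= threshold else "below_threshold"
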