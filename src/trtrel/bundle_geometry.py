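"""Geometry of streamline bundles.

All geometry in this package lives in a single coordinate frame: world RAS
millimetres.  A :class:`StreamlineBundle` is an ordered collection of 3-D
polylines; a :class:`DensityMap` is a voxel grid counting how many distinct
streamlines of a bundle visit each voxel (the weights behind the weighted
Dice coefficient).  A world point belongs to the voxel whose index is the
floor of its inverse-affine image, i.e. voxel ``v`` owns the half-open cell
``[v, v+1)`` in index coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StreamlineBundle",
    "DensityMap",
    "transform_streamlines",
    "density_map",
    "streamline_length",
    "mean_length",
    "bundle_volume",
    "mean_scalar_along_tract",
]

#: maximum absolute elementwise difference for two affines to count as equal
AFFINE_TOL = 1e-4


@dataclass
class StreamlineBundle:
    """One bundle's streamlines as 3-D polylines in world millimetres.

    Parameters
    ----------
    streamlines : list of (m_i, 3) float arrays
        Each polyline has at least two points; all coordinates finite.
    name : str
        Bundle label, e.g. ``"AF_L"``.
    space : str
        Frame tag: ``"time1"``, ``"time2"`` or ``"synthetic"``.
    """

    streamlines: list = field(default_factory=list)
    name: str = ""
    space: str = "synthetic"

    def __post_init__(self):
        cleaned = []
        for i, s in enumerate(self.streamlines):
            a = np.asarray(s, dtype=float)
            if a.ndim != 2 or a.shape[1] != 3:
                raise ValueError(f"streamline {i} is not an (m, 3) point array")
            if a.shape[0] < 2:
                raise ValueError(f"streamline {i} has fewer than 2 points")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            cleaned.append(a)
        self.streamlines = cleaned

    def __len__(self):
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class DensityMap:
    """Voxel grid of streamline-visitation weights with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("density map data must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.data < 0):
            raise ValueError("density weights must be non-negative")

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3: |det| of the 3x3 affine block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths of a voxel (norms of the affine's spatial columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def total_weight(self) -> float:
        return float(self.data.sum())

    @property
    def support_size(self) -> int:
        """Number of voxels with positive weight."""
        return int(np.count_nonzero(self.data > 0))


def affines_equal(a: np.ndarray, b: np.ndarray, tol: float = AFFINE_TOL) -> bool:
    return bool(np.max(np.abs(np.asarray(a) - np.asarray(b))) <= tol)


def transform_streamlines(bundle: StreamlineBundle, transform: np.ndarray,
                          space: str | None = None) -> StreamlineBundle:
    """Apply a 4x4 affine to every point of every streamline.

    Used to carry a subject's session-1 bundles into session-2 space before
    computing spatial overlap.  Streamline and point counts are unchanged.
    """
    T = np.asarray(transform, dtype=float)
    if T.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    if abs(np.linalg.det(T[:3, :3])) < 1e-12:
        raise ValueError("transform is singular")
    R, t = T[:3, :3], T[:3, 3]
    moved = [s @ R.T + t for s in bundle.streamlines]
    return replace(bundle, streamlines=moved,
                   space=space if space is not None else bundle.space)


def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world points to integer voxel indices (floor of the inverse-affine image)."""
    inv = np.linalg.inv(affine)
    ijk = points @ inv[:3, :3].T + inv[:3, 3]
    return np.floor(ijk).astype(np.int64)


def _polyline_voxels(ijk: np.ndarray) -> np.ndarray:
    """All voxels a polyline passes through, given its points in continuous
    index coordinates.

    Exact traversal: for each segment, collect the parameters where the
    segment crosses integer index planes, and read off the voxel of each
    inter-crossing interval at its midpoint.  Voxels touched only at a
    boundary point (zero-length intersection) are not counted.
    """
    out = []
    for u0, u1 in zip(ijk[:-1], ijk[1:]):
        d = u1 - u0
        ts = [np.array([0.0, 1.0])]
        for a in range(3):
            if d[a] != 0.0:
                lo, hi = sorted((u0[a], u1[a]))
                planes = np.arange(np.floor(lo) + 1.0, np.ceil(hi))
                ts.append((planes - u0[a]) / d[a])
        t = np.unique(np.concatenate(ts))
        t = t[(t >= 0.0) & (t <= 1.0)]
        mid = (t[:-1] + t[1:]) / 2.0
        if mid.size:
            out.append(np.floor(u0 + mid[:, None] * d).astype(np.int64))
    if not out:
        return np.floor(ijk[:1]).astype(np.int64)
    return np.unique(np.vstack(out), axis=0)


def density_map(bundle: StreamlineBundle, shape, affine: np.ndarray) -> DensityMap:
    """Rasterize a bundle into a streamline-visitation count map.

    Each voxel's weight is the number of distinct streamlines whose path
    intersects it: segment-voxel intersections are enumerated exactly (no
    resampling), and a streamline contributes at most 1 to any voxel.
    Voxels outside the grid are dropped.
    """
    affine = np.asarray(affine, dtype=float)
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError("grid shape must be three positive integers")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("degenerate grid affine")
    if len(bundle) == 0:
        warnings.warn("empty bundle: returning an all-zero density map")
        return DensityMap(np.zeros(shape), affine)

    inv = np.linalg.inv(affine)
    counts = np.zeros(shape, dtype=np.int64)
    for s in bundle:
        ijk = s @ inv[:3, :3].T + inv[:3, 3]
        vox = _polyline_voxels(ijk)
        inside = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
        vox = vox[inside]
        if vox.size:
            counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return DensityMap(counts.astype(float), affine)


def streamline_length(polyline) -> float:
    """Arc length of one streamline: sum of Euclidean segment lengths (mm)."""
    p = np.asarray(polyline, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
        raise ValueError("polyline must have at least 2 points of dimension 3")
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def mean_length(bundle: StreamlineBundle) -> float:
    """Mean length of streamlines (MLS, mm): the bundle macro-measure."""
    if len(bundle) == 0:
        raise ValueError("mean_length of an empty bundle is undefined")
    return float(np.mean([streamline_length(s) for s in bundle]))


def bundle_volume(dmap: DensityMap, threshold: float = 0.0) -> float:
    """Bundle volume in mm^3: voxels with weight above ``threshold`` x voxel volume."""
    return float(np.count_nonzero(dmap.data > threshold)) * dmap.voxel_volume


def mean_scalar_along_tract(scalar: np.ndarray, scalar_affine: np.ndarray,
                            dmap: DensityMap, weighted: bool = True) -> float:
    """Aggregate a scalar map (FA, MD, ...) over a tract's voxel support.

    ``weighted=True`` computes the streamline-count-weighted mean
    ``sum(W*s)/sum(W)``; ``weighted=False`` the plain mean of the scalar over
    voxels the tract visits.  The scalar grid must match the density grid.
    """
    scalar = np.asarray(scalar, dtype=float)
    if scalar.shape != dmap.data.shape:
        raise ValueError("scalar grid shape does not match density map")
    if not affines_equal(scalar_affine, dmap.affine):
        raise ValueError("scalar affine does not match density map affine")
    support = dmap.data > 0
    if not support.any():
        raise ValueError("density map has empty support")
    if weighted:
        w = dmap.data[support]
        return float(np.sum(w * scalar[support]) / np.sum(w))
    return float(np.mean(scalar[support]))
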