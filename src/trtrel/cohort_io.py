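"""Reading and writing the formats a paired-session tractometry cohort uses.

On-disk layout (overridable through a YAML/JSON config)::

    <root>/metrics.csv                      subject,session,bundle,metric,value
    <root>/<subject>/affine_t1_to_t2.txt    plain-text 4x4, session-1 -> session-2 mm
    <root>/<subject>/<session>/<bundle>.trk|.tck        streamlines
    <root>/<subject>/<session>/<bundle>.nii.gz          density map (optional)

Streamlines are converted to world RAS millimetres on load regardless of the
on-disk convention (TRK stores voxel-mm with a corner origin, TCK scanner
mm); density maps are NIfTI-1 with their affine retained exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .agreement import MetricTable, metric_table_from_long
from .bundle_geometry import DensityMap, StreamlineBundle

__all__ = [
    "CohortLayout",
    "read_streamlines",
    "write_streamlines",
    "read_density_map",
    "write_density_map",
    "read_metric_table",
    "read_affine",
    "write_affine",
    "load_cohort",
    "DEFAULT_BUNDLES",
    "DEFAULT_METRICS",
    "DEFAULT_SESSIONS",
]

DEFAULT_BUNDLES = ["AF_L", "AF_R", "ILF_L", "ILF_R",
                   "IFOF_L", "IFOF_R", "UF_L", "UF_R"]
DEFAULT_METRICS = ["FA", "MD", "AD", "RD", "NuFO", "volume", "MLS"]
DEFAULT_SESSIONS = ["ses-1", "ses-2"]

_STREAMLINE_EXTS = (".trk", ".tck")


@dataclass
class CohortLayout:
    """Resolved file layout of one cohort directory.

    Exactly two ordered sessions (test then retest).  Absent files are
    recorded as ``None`` rather than raising: a bundle that could not be
    reconstructed for a subject simply drops that subject from the
    analyses that need it.
    """

    root: Path
    subject_ids: list
    session_labels: list = field(default_factory=lambda: list(DEFAULT_SESSIONS))
    bundle_names: list = field(default_factory=lambda: list(DEFAULT_BUNDLES))
    metric_names: list = field(default_factory=lambda: list(DEFAULT_METRICS))

    def __post_init__(self):
        self.root = Path(self.root)
        if len(self.session_labels) != 2:
            raise ValueError("a cohort has exactly two sessions")

    def streamline_path(self, subject: str, session: str, bundle: str):
        d = self.root / subject / session
        hits = [d / f"{bundle}{ext}" for ext in _STREAMLINE_EXTS
                if (d / f"{bundle}{ext}").exists()]
        if len(hits) > 1:
            raise ValueError(
                f"ambiguous streamline files for {subject}/{session}/{bundle}")
        return hits[0] if hits else None

    def density_path(self, subject: str, session: str, bundle: str):
        for ext in (".nii.gz", ".nii"):
            p = self.root / subject / session / f"{bundle}{ext}"
            if p.exists():
                return p
        return None

    def affine_path(self, subject: str):
        p = self.root / subject / "affine_t1_to_t2.txt"
        return p if p.exists() else None

    @property
    def metrics_path(self) -> Path:
        return self.root / "metrics.csv"


def load_cohort(root, session_labels=None, bundle_names=None,
                metric_names=None) -> CohortLayout:
    """Scan a cohort directory and build its layout deterministically.

    Subjects are the sorted subdirectory names containing at least one
    session directory.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"cohort root {root} is not a directory")
    sessions = list(session_labels) if session_labels else list(DEFAULT_SESSIONS)
    subjects = sorted(
        d.name for d in root.iterdir()
        if d.is_dir() and any((d / s).is_dir() for s in sessions))
    return CohortLayout(
        root=root, subject_ids=subjects, session_labels=sessions,
        bundle_names=list(bundle_names) if bundle_names else list(DEFAULT_BUNDLES),
        metric_names=list(metric_names) if metric_names else list(DEFAULT_METRICS))


def read_streamlines(path, name: str = "", space: str = "synthetic"
                     ) -> StreamlineBundle:
    """Load a TRK or TCK tractogram as world RAS-mm polylines.

    The format handlers apply the on-disk header transform so points come
    back in scanner millimetres whichever dialect stored them.  Streamline
    order is preserved; an empty file returns an empty bundle with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as e:  # surface the offending field/format
        raise ValueError(f"cannot read tractogram {path}: {e}") from e
    sls = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    if not sls:
        warnings.warn(f"{path} contains no streamlines")
    return StreamlineBundle(streamlines=sls, name=name or path.stem, space=space)


def write_streamlines(bundle: StreamlineBundle, path, header=None) -> None:
    """Write a bundle (world RAS mm) to TRK or TCK, chosen by extension."""
    path = Path(path)
    tg = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in bundle.streamlines],
        affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk" and header is None:
        header = {"voxel_to_rasmm": np.eye(4), "voxel_sizes": (1.0, 1.0, 1.0),
                  "dimensions": (1, 1, 1)}
    nib.streamlines.save(tg, str(path), header=header)


def read_density_map(path) -> DensityMap:
    """Load a 3-D NIfTI-1 streamline-density map; weights must be >= 0."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: density map must be 3-D, got {data.ndim}-D")
    if np.any(data < 0):
        raise ValueError(f"{path}: negative density weights")
    return DensityMap(np.asarray(data, dtype=float), np.asarray(img.affine))


def write_density_map(dmap: DensityMap, path) -> None:
    img = nib.Nifti1Image(dmap.data.astype(np.float32), dmap.affine)
    nib.save(img, str(path))


def read_metric_table(path, session_labels=None) -> dict:
    """Read metrics.csv into one :class:`MetricTable` per (bundle, metric).

    Missing (subject, session) cells stay absent (NaN rows dropped later by
    pairwise-complete analysis); duplicate or non-numeric rows are errors.
    """
    df = pd.read_csv(path, dtype={"subject": str, "session": str,
                                  "bundle": str, "metric": str})
    required = {"subject", "session", "bundle", "metric", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any() and df["value"].notna().any():
        bad = df.loc[values.isna() & df["value"].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric values, e.g. row {bad.index[0]}")
    df = df.assign(value=values)
    keys = ["subject", "session", "bundle", "metric"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"{path}: duplicate rows for {df.loc[dup, keys].iloc[0].tolist()}")
    tables = {}
    for (bundle, metric), _ in df.groupby(["bundle", "metric"], sort=True):
        tables[(bundle, metric)] = metric_table_from_long(
            df, bundle, metric, session_labels=session_labels)
    return tables


def read_affine(path) -> np.ndarray:
    """Read a plain-text 4x4 affine mapping session-1 mm to session-2 mm."""
    mat = np.loadtxt(path, dtype=float)
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {mat.shape}")
    if np.max(np.abs(mat[3] - [0, 0, 0, 1])) > 1e-6:
        raise ValueError(f"{path}: last row must be 0 0 0 1, got {mat[3]}")
    return mat


def write_affine(mat: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(mat, dtype=float), fmt="%.10g")
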