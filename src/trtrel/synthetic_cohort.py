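"""Paired-session synthetic cohorts with known ground truth.

The study design this emulates: a cohort of subjects scanned twice about a
week apart, eight language bundles (arcuate, inferior longitudinal,
inferior fronto-occipital and uncinate fasciculi, both hemispheres), and
seven per-bundle measures (FA, MD, AD, RD, NuFO, volume, MLS).

Scalar measures follow the two-way variance-components model the ICC
analysis assumes:

    y_ij = mu + b_i + s_j + e_ij,
    b_i ~ N(0, sigma_b^2)   subject effect
    s_j ~ N(0, sigma_s^2)   session effect
    e_ij ~ N(0, sigma_e^2)  residual

so the population absolute-agreement ICC has the closed form
``sigma_b^2 / (sigma_b^2 + sigma_s^2 + sigma_e^2)`` and estimator recovery
can be checked against an exact target.  Bundles are tubes of jittered
copies of a smooth centerline; the session-2 centerline can be displaced by
a controllable shift so spatial overlap degrades in a known way.

Randomness is driven by one master seed; every (subject, bundle, metric,
session) unit derives its own sub-seed from a spawn key, so generation is
independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline

from .bundle_geometry import StreamlineBundle, density_map, world_to_voxel
from .cohort_io import (DEFAULT_BUNDLES, DEFAULT_METRICS, DEFAULT_SESSIONS,
                        write_affine, write_density_map, write_streamlines)

__all__ = [
    "MetricSimSpec",
    "BundleSimSpec",
    "CohortSimSpec",
    "true_icc",
    "simulate_metric_table",
    "simulate_bundle_pair",
    "simulate_cohort",
    "default_metric_specs",
    "default_bundle_specs",
]


@dataclass
class MetricSimSpec:
    """Variance-components generator for one bundle x metric table."""

    mu: float = 0.0
    sigma_b: float = 1.0
    sigma_s: float = 0.1
    sigma_e: float = 0.3
    n_subjects: int = 18
    k_sessions: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_b, self.sigma_s, self.sigma_e) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")


def true_icc(spec: MetricSimSpec) -> float:
    """Population ICC: between-subject variance over total variance."""
    total = spec.sigma_b ** 2 + spec.sigma_s ** 2 + spec.sigma_e ** 2
    if total == 0:
        raise ValueError("all variance components are zero")
    return spec.sigma_b ** 2 / total


def simulate_metric_table(spec: MetricSimSpec, rng=None) -> np.ndarray:
    """Draw one n x k table from the two-way random-effects model."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, k = spec.n_subjects, spec.k_sessions
    b = rng.normal(0, spec.sigma_b, size=(n, 1))
    s = rng.normal(0, spec.sigma_s, size=(1, k))
    e = rng.normal(0, spec.sigma_e, size=(n, k))
    return spec.mu + b + s + e


@dataclass
class BundleSimSpec:
    """Tube-bundle generator: jittered copies of a smooth 3-D centerline.

    ``session_shift`` displaces the session-2 centerline along
    ``shift_direction`` (mm), degrading overlap with session 1;
    ``shared_session_noise`` reuses the session-1 jitter draws so a zero
    shift reproduces session 1 exactly.
    """

    centerline: np.ndarray = None
    n_streamlines: int = 30
    streamline_jitter_sd: float = 1.0
    session_shift: float = 0.0
    shift_direction: tuple = (0.0, 1.0, 0.0)
    grid_shape: tuple = (32, 32, 32)
    voxel_size: float = 1.0
    n_points: int = 60
    shared_session_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.centerline is None:
            self.centerline = np.array(
                [[16, 5, 16], [13, 12, 20], [13, 20, 20], [16, 27, 16]], float)
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.n_streamlines < 1:
            raise ValueError("need at least one streamline")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.session_shift < 0:
            raise ValueError("session shift must be non-negative")

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[0, 0] = A[1, 1] = A[2, 2] = self.voxel_size
        return A


def _smooth_curve(control: np.ndarray, n_points: int) -> np.ndarray:
    t = np.linspace(0, 1, len(control))
    k = min(3, len(control) - 1)
    spline = make_interp_spline(t, control, k=k, axis=0)
    return spline(np.linspace(0, 1, n_points))


def _tube(centerline: np.ndarray, n_streamlines: int, jitter_sd: float,
          rng) -> list:
    """Noisy copies of the centerline with a smooth per-streamline offset
    (constant component plus a linear drift along the tract)."""
    t = np.linspace(-0.5, 0.5, len(centerline))[:, None]
    out = []
    for _ in range(n_streamlines):
        u0 = rng.normal(0, jitter_sd, size=3)
        u1 = rng.normal(0, jitter_sd, size=3)
        out.append(centerline + u0 + t * u1)
    return out


def simulate_bundle_pair(spec: BundleSimSpec
                         ) -> tuple[StreamlineBundle, StreamlineBundle]:
    """Generate the session-1 and session-2 reconstructions of one bundle."""
    curve = _smooth_curve(spec.centerline, spec.n_points)
    shift = spec.session_shift * np.asarray(spec.shift_direction, float)
    curve2 = curve + shift
    vox2 = world_to_voxel(curve2, spec.affine)
    if np.any(vox2 < 0) or np.any(vox2 >= np.array(spec.grid_shape)):
        raise ValueError("shifted centerline exits the grid")
    kids = np.random.SeedSequence(spec.seed).spawn(2)
    rng1 = np.random.default_rng(kids[0])
    rng2 = np.random.default_rng(kids[0] if spec.shared_session_noise else kids[1])
    b1 = StreamlineBundle(_tube(curve, spec.n_streamlines,
                                spec.streamline_jitter_sd, rng1),
                          space="time1")
    b2 = StreamlineBundle(_tube(curve2, spec.n_streamlines,
                                spec.streamline_jitter_sd, rng2),
                          space="time2")
    return b1, b2


# --- cohort-level defaults -------------------------------------------------

#: per-metric (mu, sigma_b, sigma_s, sigma_e): plausible tractometry scales
#: (FA unitless, diffusivities in um^2/ms, volume mm^3, MLS mm) chosen to
#: give good-to-excellent population reliability; configuration values, not
#: estimates from any dataset.
DEFAULT_METRIC_PARAMS = {
    "FA": (0.45, 0.040, 0.004, 0.015),
    "MD": (0.80, 0.050, 0.005, 0.020),
    "AD": (1.20, 0.060, 0.006, 0.025),
    "RD": (0.60, 0.050, 0.005, 0.020),
    "NuFO": (1.80, 0.250, 0.030, 0.120),
    "volume": (9000.0, 1500.0, 150.0, 700.0),
    "MLS": (100.0, 8.0, 0.8, 3.5),
}

#: smooth mirrored arcs inside the default 32 mm grid, one per bundle
_BUNDLE_CONTROLS = {
    "AF": [[10, 6, 18], [8, 12, 22], [8, 20, 22], [10, 26, 16]],
    "ILF": [[9, 5, 12], [8, 14, 13], [9, 24, 14], [11, 27, 15]],
    "IFOF": [[10, 4, 15], [8, 12, 17], [8, 20, 17], [10, 28, 18]],
    "UF": [[10, 8, 10], [8, 12, 14], [9, 15, 18], [12, 17, 21]],
}


def default_bundle_specs(grid_shape=(32, 32, 32), voxel_size=1.0,
                         n_streamlines=30, jitter_sd=1.0,
                         session_shift=0.6) -> dict:
    """One BundleSimSpec per default bundle; _R mirrors _L in x."""
    specs = {}
    for base, ctrl in _BUNDLE_CONTROLS.items():
        c = np.asarray(ctrl, float)
        for side, pts in (("L", c), ("R", c * [-1, 1, 1] + [grid_shape[0] * voxel_size, 0, 0])):
            specs[f"{base}_{side}"] = BundleSimSpec(
                centerline=pts, n_streamlines=n_streamlines,
                streamline_jitter_sd=jitter_sd, session_shift=session_shift,
                grid_shape=grid_shape, voxel_size=voxel_size)
    return specs


def default_metric_specs(n_subjects=18) -> dict:
    return {m: MetricSimSpec(mu=mu, sigma_b=sb, sigma_s=ss, sigma_e=se,
                             n_subjects=n_subjects)
            for m, (mu, sb, ss, se) in DEFAULT_METRIC_PARAMS.items()}


@dataclass
class CohortSimSpec:
    """Full synthetic cohort: 18 subjects x 2 sessions x 8 bundles x 7 metrics
    by default, with one subject's right uncinate missing in both sessions."""

    n_subjects: int = 18
    bundle_names: list = field(default_factory=lambda: list(DEFAULT_BUNDLES))
    metric_names: list = field(default_factory=lambda: list(DEFAULT_METRICS))
    session_labels: list = field(default_factory=lambda: list(DEFAULT_SESSIONS))
    metric_specs: dict = None       # (bundle or metric) -> MetricSimSpec
    bundle_specs: dict = None       # bundle -> BundleSimSpec
    missing: list = None            # (subject, bundle, session) tuples
    master_seed: int = 0

    def __post_init__(self):
        if self.metric_specs is None:
            self.metric_specs = default_metric_specs(self.n_subjects)
        if self.bundle_specs is None:
            self.bundle_specs = default_bundle_specs()
        if self.missing is None:
            last = f"sub-{self.n_subjects:02d}"
            self.missing = [(last, "UF_R", s) for s in self.session_labels]

    @property
    def subject_ids(self) -> list:
        return [f"sub-{i + 1:02d}" for i in range(self.n_subjects)]

    def metric_spec_for(self, bundle: str, metric: str) -> MetricSimSpec:
        if (bundle, metric) in self.metric_specs:
            return self.metric_specs[(bundle, metric)]
        return self.metric_specs[metric]


def _subseed(master: int, *key) -> np.random.SeedSequence:
    return np.random.SeedSequence(master, spawn_key=tuple(key))


def simulate_cohort(spec: CohortSimSpec, out_dir) -> Path:
    """Write a full synthetic cohort in the standard directory layout.

    Emits per subject x session x bundle a TRK file and a density map, a
    per-subject identity session-1 -> session-2 affine, and metrics.csv.
    Deterministic given the master seed: sub-seeds are derived from
    (kind, subject index, bundle index) spawn keys, not call order.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = spec.subject_ids
    missing = set(spec.missing)

    for si, subject in enumerate(subjects):
        sdir = out / subject
        sdir.mkdir(exist_ok=True)
        write_affine(np.eye(4), sdir / "affine_t1_to_t2.txt")
        for ses in spec.session_labels:
            (sdir / ses).mkdir(exist_ok=True)
        for bi, bundle in enumerate(spec.bundle_names):
            bspec = spec.bundle_specs[bundle]
            seed = _subseed(spec.master_seed, 1, si, bi)
            sub_bspec = BundleSimSpec(
                centerline=bspec.centerline,
                n_streamlines=bspec.n_streamlines,
                streamline_jitter_sd=bspec.streamline_jitter_sd,
                session_shift=bspec.session_shift,
                shift_direction=bspec.shift_direction,
                grid_shape=bspec.grid_shape,
                voxel_size=bspec.voxel_size,
                n_points=bspec.n_points,
                shared_session_noise=bspec.shared_session_noise,
                seed=int(seed.generate_state(1)[0] % (2 ** 31)))
            pair = simulate_bundle_pair(sub_bspec)
            for ses, bundle_obj in zip(spec.session_labels, pair):
                if (subject, bundle, ses) in missing:
                    continue
                write_streamlines(bundle_obj, sdir / ses / f"{bundle}.trk")
                dm = density_map(bundle_obj, sub_bspec.grid_shape,
                                 sub_bspec.affine)
                write_density_map(dm, sdir / ses / f"{bundle}.nii.gz")

    rows = []
    for bi, bundle in enumerate(spec.bundle_names):
        for mi, metric in enumerate(spec.metric_names):
            mspec = spec.metric_spec_for(bundle, metric)
            rng = np.random.default_rng(_subseed(spec.master_seed, 2, bi, mi))
            table = simulate_metric_table(mspec, rng=rng)
            for si, subject in enumerate(subjects):
                for ki, ses in enumerate(spec.session_labels):
                    if (subject, bundle, ses) in missing:
                        continue
                    rows.append((subject, ses, bundle, metric, table[si, ki]))
    df = pd.DataFrame(rows, columns=["subject", "session", "bundle",
                                     "metric", "value"])
    df.to_csv(out / "metrics.csv", index=False, float_format="%.12g")
    return out
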