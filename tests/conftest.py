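import numpy as np
import pytest

from trtrel import StreamlineBundle


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_polyline(rng, n_points=30, start_lo=3.0, start_hi=12.0,
                    step_sd=0.4):
    start = rng.uniform(start_lo, start_hi, 3)
    return start + np.cumsum(rng.normal(0, step_sd, size=(n_points, 3)), axis=0)


def supersampling_density_oracle(polylines, shape, affine, step=0.01):
    """Brute-force visitation counts: resample each polyline at ``step`` mm
    arc length, floor the voxel index of every sample, deduplicate per
    streamline.  Independent of the package's exact segment traversal."""
    counts = np.zeros(shape, dtype=int)
    inv = np.linalg.inv(np.asarray(affine, float))
    for p in polylines:
        p = np.asarray(p, float)
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(int(np.ceil(arc[-1] / step)), 1)
        t = np.linspace(0.0, arc[-1], n + 1)
        pts = np.column_stack([np.interp(t, arc, p[:, d]) for d in range(3)])
        vox = np.floor(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
        for v in {tuple(x) for x in vox[ok]}:
            counts[v] += 1
    return counts


def voxel_intersection_length(polylines, voxel, affine):
    """Exact total arc length (mm) the polylines spend inside one voxel.

    Clips every segment against the voxel's half-open index cell in index
    space and measures the clipped piece in world millimetres.  Used to
    confirm that any voxel a finite-step supersampling oracle misses is
    clipped for less than the oracle's step.
    """
    inv = np.linalg.inv(np.asarray(affine, float))
    v = np.asarray(voxel, float)
    total = 0.0
    for p in polylines:
        pts = np.asarray(p, float)
        ijk = pts @ inv[:3, :3].T + inv[:3, 3]
        for i in range(len(pts) - 1):
            u0, u1 = ijk[i], ijk[i + 1]
            d = u1 - u0
            t0, t1 = 0.0, 1.0
            ok = True
            for a in range(3):
                if d[a] == 0.0:
                    if not (v[a] <= u0[a] < v[a] + 1):
                        ok = False
                        break
                else:
                    ta = (v[a] - u0[a]) / d[a]
                    tb = (v[a] + 1 - u0[a]) / d[a]
                    t0 = max(t0, min(ta, tb))
                    t1 = min(t1, max(ta, tb))
            if ok and t1 > t0:
                total += (t1 - t0) * np.linalg.norm(pts[i + 1] - pts[i])
    return total


def assert_density_matches_oracle(dmap, polylines, shape, affine, step=0.01):
    """Density counts equal the supersampling oracle at its resolution:
    identical everywhere except voxels the exact traversal finds whose true
    intersection length is below the oracle's sampling step."""
    oracle = supersampling_density_oracle(polylines, shape, affine, step=step)
    impl = dmap.data.astype(int)
    assert np.all(impl >= oracle), "exact traversal missed oracle voxels"
    for vox in map(tuple, np.argwhere(impl != oracle)):
        length = voxel_intersection_length(polylines, vox, affine)
        assert length < step, (
            f"voxel {vox} differs from oracle but is clipped for {length} mm")


def tube_bundle(rng, n_streamlines=20, length=10.0, radius_sd=0.8,
                offset=(0.0, 0.0, 0.0)):
    """Straight tube along +y around x=z=8, for overlap tests."""
    base = np.column_stack([np.full(25, 8.0), np.linspace(2, 2 + length, 25),
                            np.full(25, 8.0)]) + np.asarray(offset, float)
    sls = [base + rng.normal(0, radius_sd, 3) for _ in range(n_streamlines)]
    return StreamlineBundle(sls, name="tube")
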