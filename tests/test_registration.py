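"""Downsampling, normals, FPFH, matching, robust global estimator, ICP, pipeline."""

import numpy as np
import pytest
import trimesh

from surfnav import (
    ICPParams,
    PipelineConfig,
    PointCloud,
    RegistrationError,
    compute_fpfh,
    crop_reference,
    downsample_voxel,
    estimate_normals,
    global_register,
    match_correspondences,
    refine_icp,
    register_pipeline,
)
from surfnav.depthsim import DepthCamera, NoiseModel, corrupt, depth_to_pointcloud, look_at, render_depth, sample_surface
from surfnav.geometry import RigidTransform, apply_transform, random_rigid_transform, rotation_angle_deg
from surfnav.registration import CorrespondenceSet, _max_clique


class TestDownsample:
    def test_two_points_in_one_voxel_become_centroid(self):
        cloud = PointCloud([[0.1, 0.1, 0.1], [0.3, 0.3, 0.3]])
        out = downsample_voxel(cloud, 1.0)
        assert len(out) == 1
        assert np.allclose(out.points[0], [0.2, 0.2, 0.2])

    def test_every_point_near_some_output(self, rng):
        cloud = PointCloud(rng.uniform(-50, 50, (500, 3)))
        s = 4.0
        out = downsample_voxel(cloud, s)
        d = np.linalg.norm(cloud.points[:, None] - out.points[None], axis=2).min(axis=1)
        # a voxel's centroid can sit anywhere inside it, so the voxel
        # diagonal bounds the distance to the representative point
        assert d.max() <= s * np.sqrt(3) + 1e-9

    def test_matches_grid_bucketing_oracle(self, rng):
        pts = rng.uniform(-30, 30, (1000, 3))
        s = 2.5
        out = downsample_voxel(PointCloud(pts), s)
        buckets = {}
        for p in pts:
            key = tuple(np.floor(p / s).astype(int))
            buckets.setdefault(key, []).append(p)
        want = np.array([np.mean(v, axis=0) for k, v in sorted(buckets.items())])
        assert len(out) == len(want)
        assert np.allclose(np.sort(out.points, axis=0), np.sort(want, axis=0), atol=1e-9)

    def test_empty_cloud_rejected(self):
        with pytest.raises(RegistrationError):
            downsample_voxel(PointCloud(np.zeros((0, 3))), 1.0)


class TestNormals:
    def test_planar_cloud_normals_match_plane(self, rng):
        pts = np.column_stack([rng.uniform(-10, 10, (200, 2)), np.zeros(200)])
        out = estimate_normals(PointCloud(pts), k_neighbors=10, viewpoint=[0, 0, 100])
        ang = np.degrees(np.arccos(np.clip(np.abs(out.normals[:, 2]), -1, 1)))
        assert ang.max() < 1.0

    def test_normals_are_unit_length(self, rng):
        pts = rng.normal(size=(300, 3)) * 20
        out = estimate_normals(PointCloud(pts), k_neighbors=15)
        n = np.linalg.norm(out.normals[np.all(np.isfinite(out.normals), axis=1)], axis=1)
        assert np.abs(n - 1).max() < 1e-9

    def test_sphere_normals_point_radially_outward(self, rng):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=30.0)
        pts, _ = sample_surface(mesh, 3000, rng)
        # exterior orientation: away from the cloud centroid
        out = estimate_normals(PointCloud(pts), k_neighbors=20)
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        dots = np.einsum("ij,ij->i", out.normals, radial)
        assert (dots > 0.95).mean() > 0.99


def _fpfh_oracle(pts, nrm, radius):
    """Literal double-loop SPFH/FPFH from the published formulas."""
    n = len(pts)
    spfh = np.zeros((n, 33))
    nbrs = [
        [j for j in range(n) if j != i and np.linalg.norm(pts[j] - pts[i]) <= radius]
        for i in range(n)
    ]

    def angles(p, np_, q, nq):
        d = q - p
        dist = np.linalg.norm(d)
        dhat = d / dist
        if abs(np.dot(np_, dhat)) < abs(np.dot(nq, -dhat)):
            p, np_, q, nq = q, nq, p, np_
            dhat = -dhat
        u = np_
        v = np.cross(dhat, u)
        v = v / np.linalg.norm(v)
        w = np.cross(u, v)
        return np.dot(v, nq), np.dot(u, dhat), np.arctan2(np.dot(w, nq), np.dot(u, nq))

    def binit(val, lo, hi):
        return min(int((val - lo) / (hi - lo) * 11), 10) if val >= lo else 0

    for i in range(n):
        for j in nbrs[i]:
            a, f, t = angles(pts[i], nrm[i], pts[j], nrm[j])
            spfh[i, binit(a, -1, 1)] += 1
            spfh[i, 11 + binit(f, -1, 1)] += 1
            spfh[i, 22 + binit(t, -np.pi, np.pi)] += 1
    fpfh = np.zeros((n, 33))
    for i in range(n):
        if not nbrs[i]:
            continue
        acc = spfh[i].copy()
        for j in nbrs[i]:
            acc += spfh[j] / np.linalg.norm(pts[j] - pts[i]) / len(nbrs[i])
        fpfh[i] = acc
    for off in (0, 11, 22):
        for i in range(n):
            s = fpfh[i, off:off + 11].sum()
            if s > 0:
                fpfh[i, off:off + 11] *= 100.0 / s
    return fpfh


@pytest.fixture(scope="module")
def toy_cloud():
    rng = np.random.default_rng(3)
    pts = rng.uniform(-5, 5, (20, 3))
    nrm = rng.normal(size=(20, 3))
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return PointCloud(pts, nrm)


class TestFPFH:
    def test_histograms_nonnegative_33_bins(self, toy_cloud):
        fs = compute_fpfh(toy_cloud, radius_mm=6.0)
        assert fs.descriptors.shape == (20, 33)
        assert (fs.descriptors >= 0).all()

    def test_rotation_invariance(self, toy_cloud, rng):
        fs = compute_fpfh(toy_cloud, radius_mm=6.0)
        T = random_rigid_transform(rng)
        fs2 = compute_fpfh(apply_transform(T, toy_cloud), radius_mm=6.0)
        l1 = np.abs(fs.descriptors - fs2.descriptors).sum(axis=1)
        assert l1.max() < 1e-6 * fs.descriptors.sum(axis=1).max()

    def test_matches_double_loop_oracle(self, toy_cloud):
        got = compute_fpfh(toy_cloud, radius_mm=6.0).descriptors
        want = _fpfh_oracle(toy_cloud.points, toy_cloud.normals, 6.0)
        assert np.abs(got - want).max() < 1e-9

    def test_isolated_point_flagged(self):
        pts = np.vstack([np.zeros((5, 3)) + np.arange(5)[:, None], [[500.0, 0, 0]]])
        nrm = np.tile([0.0, 0.0, 1.0], (6, 1))
        fs = compute_fpfh(PointCloud(pts, nrm), radius_mm=5.0)
        assert not fs.valid[-1]
        assert np.all(fs.descriptors[-1] == 0)

    def test_missing_normals_rejected(self):
        with pytest.raises(RegistrationError):
            compute_fpfh(PointCloud(np.zeros((5, 3))), 5.0)


class TestMatching:
    def test_identical_clouds_pair_identically(self, rng):
        pts = rng.uniform(-20, 20, (100, 3))
        nrm = rng.normal(size=(100, 3))
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        fs = compute_fpfh(PointCloud(pts, nrm), radius_mm=15.0)
        corr = match_correspondences(fs, fs)
        # keypoints with unique descriptors must match themselves
        pairs = dict(corr.pairs)
        desc = fs.descriptors
        for i in range(100):
            dists = np.linalg.norm(desc - desc[i], axis=1)
            if (dists < 1e-12).sum() == 1 and i in pairs:
                assert pairs[i] == i

    def test_pair_count_bounded(self, rng):
        a = PointCloud(rng.uniform(-20, 20, (60, 3)), _rand_normals(rng, 60))
        b = PointCloud(rng.uniform(-20, 20, (40, 3)), _rand_normals(rng, 40))
        fa = compute_fpfh(a, 15.0)
        fb = compute_fpfh(b, 15.0)
        corr = match_correspondences(fa, fb)
        assert len(corr) <= min(len(a), len(b))

    def test_matches_all_pairs_descriptor_oracle(self, rng):
        a = PointCloud(rng.uniform(-20, 20, (50, 3)), _rand_normals(rng, 50))
        b = PointCloud(rng.uniform(-20, 20, (50, 3)), _rand_normals(rng, 50))
        fa = compute_fpfh(a, 15.0)
        fb = compute_fpfh(b, 15.0)
        corr = match_correspondences(fa, fb)
        D = np.linalg.norm(fa.descriptors[:, None] - fb.descriptors[None], axis=2)
        want = {
            (i, int(np.argmin(D[i])))
            for i in range(50)
            if np.argmin(D[:, np.argmin(D[i])]) == i
        }
        assert set(map(tuple, corr.pairs)) == want


def _rand_normals(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _synthetic_correspondences(rng, n=100, outlier_frac=0.7, noise_sd=0.5):
    T = random_rigid_transform(rng, 180, 100)
    src = rng.uniform(-100, 100, (n, 3))
    dst = T.apply(src)
    if noise_sd > 0:
        dst = dst + rng.normal(0, noise_sd, (n, 3))
    k = int(n * outlier_frac)
    out = rng.choice(n, k, replace=False)
    dst[out] = rng.uniform(-150, 150, (k, 3))
    corr = CorrespondenceSet(
        np.column_stack([np.arange(n), np.arange(n)]), PointCloud(src), PointCloud(dst)
    )
    return T, corr


class TestGlobalRegister:
    def test_exact_inliers_equal_svd_closed_form(self, rng):
        T, corr = _synthetic_correspondences(rng, n=50, outlier_frac=0.0, noise_sd=0.0)
        g = global_register(corr, 1.0)
        src, dst = corr.src_points, corr.dst_points
        cp, cq = src.mean(0), dst.mean(0)
        U, _, Vt = np.linalg.svd((src - cp).T @ (dst - cq))
        R = Vt.T @ U.T
        if np.linalg.det(R) < 0:
            R = Vt.T @ np.diag([1.0, 1.0, -1.0]) @ U.T
        assert np.abs(g.transform.rotation - R).max() < 1e-9
        assert np.abs(g.transform.translation - (cq - R @ cp)).max() < 1e-9

    def test_recovers_under_70_percent_outliers(self):
        """Parameter recovery against a known generating transform."""
        ok = 0
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            T, corr = _synthetic_correspondences(rng)
            g = global_register(corr, 1.5)
            err = g.transform.compose(T.inverse())
            if rotation_angle_deg(err) < 1.0 and np.linalg.norm(err.translation) < 1.0:
                ok += 1
        assert ok >= 19

    def test_permutation_invariance(self, rng):
        T, corr = _synthetic_correspondences(rng, n=60, outlier_frac=0.5)
        g1 = global_register(corr, 1.5)
        perm = rng.permutation(len(corr))
        corr2 = CorrespondenceSet(corr.pairs[perm], corr.source, corr.target)
        g2 = global_register(corr2, 1.5)
        assert np.abs(g1.transform.matrix() - g2.transform.matrix()).max() < 1e-6

    def test_too_few_correspondences_rejected(self, rng):
        T, corr = _synthetic_correspondences(rng, n=2, outlier_frac=0.0)
        with pytest.raises(RegistrationError):
            global_register(corr, 1.0)

    def test_incompatible_correspondences_rejected(self):
        # pairwise distances disagree wildly: no clique of 3 exists
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        dst = np.array([[0, 0, 0], [50, 0, 0], [0, 200, 0], [0, 0, 500]], dtype=float)
        corr = CorrespondenceSet(
            np.column_stack([np.arange(4), np.arange(4)]), PointCloud(src), PointCloud(dst)
        )
        with pytest.raises(RegistrationError):
            global_register(corr, 0.5)


class TestMaxClique:
    def test_agrees_with_networkx_on_random_graphs(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(0)
        for _ in range(15):
            n = int(rng.integers(10, 50))
            A = rng.random((n, n)) < rng.uniform(0.2, 0.7)
            A = np.triu(A, 1)
            A = A | A.T
            want, _ = nx.max_weight_clique(nx.from_numpy_array(A), weight=None)
            got = _max_clique(A)
            assert len(got) == len(want)
            assert A[np.ix_(got, got)].sum() == len(got) * (len(got) - 1)


class TestICP:
    def test_identity_on_identical_clouds(self, rng):
        pts = rng.uniform(-50, 50, (500, 3))
        cloud = PointCloud(pts)
        r = refine_icp(cloud, cloud, RigidTransform.identity(),
                       ICPParams(method="point_to_point"))
        assert r.success
        assert len(r.rmse_history) <= 2
        assert r.rmse_history[0] < 1e-9

    def test_recovers_small_perturbation(self, rng):
        pts = rng.uniform(-80, 80, (2000, 3))
        axis = rng.normal(size=3)
        t = rng.normal(size=3)
        T = RigidTransform.from_axis_angle(axis, np.radians(2.0), t / np.linalg.norm(t) * 2.0)
        model = PointCloud(T.inverse().apply(pts))
        r = refine_icp(model, PointCloud(pts), RigidTransform.identity(),
                       ICPParams(method="point_to_point", d_max_mm=1e9))
        err = r.transform.compose(T.inverse())
        assert rotation_angle_deg(err) < 0.05
        assert np.linalg.norm(err.translation) < 0.05

    def test_point_to_point_rmse_never_increases(self):
        for trial in range(50):
            rng = np.random.default_rng(trial)
            pts = rng.uniform(-50, 50, (300, 3))
            T = random_rigid_transform(rng, 10, 10)
            model = PointCloud(T.apply(pts) + rng.normal(0, 1.0, (300, 3)))
            r = refine_icp(model, PointCloud(pts), RigidTransform.identity(),
                           ICPParams(method="point_to_point", d_max_mm=1e9))
            h = np.asarray(r.rmse_history)
            assert np.all(np.diff(h) <= 1e-9)

    def test_out_of_range_start_returns_failure_not_exception(self, rng):
        model = PointCloud(rng.uniform(0, 10, (50, 3)))
        scene = PointCloud(rng.uniform(500, 510, (50, 3)))
        r = refine_icp(model, scene, RigidTransform.identity(), ICPParams(d_max_mm=5.0))
        assert not r.success
        assert r.reason == "no_correspondences"

    def test_point_to_plane_converges_on_surface(self, rng):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=40.0)
        pts, nrm = sample_surface(mesh, 3000, rng)
        scene = PointCloud(pts, nrm)
        T = RigidTransform.from_axis_angle([0, 0, 1], np.radians(3.0), [1.5, -1.0, 0.5])
        model = PointCloud(T.inverse().apply(pts[::2]))
        r = refine_icp(model, scene, RigidTransform.identity(), ICPParams())
        err = r.transform.compose(T.inverse())
        assert rotation_angle_deg(err) < 0.2
        assert np.linalg.norm(err.translation) < 0.2


class TestPipeline:
    def test_exact_scene_registers_to_identity(self, head):
        ref = crop_reference(head, "face_only")
        cfg = PipelineConfig(seed=11)
        rng = np.random.default_rng(cfg.seed)
        pts, _ = sample_surface(ref, cfg.model_samples, rng)
        res = register_pipeline(ref, PointCloud(pts), cfg)
        assert res.success
        assert rotation_angle_deg(res.transform) < 1e-4
        assert np.linalg.norm(res.transform.translation) < 1e-4

    def test_equivariance_under_reference_motion(self, head, rng):
        ref = crop_reference(head, "face_only")
        cfg = PipelineConfig(seed=5)
        rngs = np.random.default_rng(cfg.seed)
        pts, _ = sample_surface(ref, cfg.model_samples, rngs)
        scene = PointCloud(pts)
        base = register_pipeline(ref, scene, cfg)
        T = random_rigid_transform(rng, 20, 50)
        moved = apply_transform(T, ref)
        res = register_pipeline(moved, scene, cfg)
        expect = base.transform.compose(T.inverse())
        diff = res.transform.compose(expect.inverse())
        assert rotation_angle_deg(diff) < 0.1
        assert np.linalg.norm(diff.translation) < 0.5

    def test_heavy_occlusion_fails_cleanly(self, head):
        ref = crop_reference(head, "face_only")
        cam = DepthCamera.hololens_like(pose=look_at([0, 420, 0], [0, 0, 0]))
        cloud = depth_to_pointcloud(render_depth(head, cam), cam)
        # emulate a clamp covering the face: keep a thin chin strip (<10% of
        # the reference area)
        keep = cloud.points[:, 2] < np.quantile(cloud.points[:, 2], 0.1)
        occluded = PointCloud(cloud.points[keep], view_origin=cloud.view_origin)
        res = register_pipeline(ref, occluded, PipelineConfig(seed=0))
        assert not res.success
        assert res.reason != ""

    def test_noisy_frontal_view_recovers_pose(self, head, rng):
        ref = crop_reference(head, "face_only")
        T_true = random_rigid_transform(rng, 30, 100)
        posed = trimesh.Trimesh(T_true.apply(np.asarray(head.vertices)), head.faces, process=False)
        center = np.asarray(posed.bounds).mean(axis=0)
        ant = T_true.apply_vectors(np.array([0.0, 1.0, 0.0]))
        up = T_true.apply_vectors(np.array([0.0, 0.0, 1.0]))
        cam = DepthCamera.hololens_like(pose=look_at(center + ant * 420, center, up))
        cloud = corrupt(depth_to_pointcloud(render_depth(posed, cam), cam), NoiseModel(seed=0))
        res = register_pipeline(ref, cloud, PipelineConfig(seed=0))
        err = res.transform.compose(T_true.inverse())
        assert res.success
        assert rotation_angle_deg(err) < 1.0
        assert np.linalg.norm(err.translation) < 2.0
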