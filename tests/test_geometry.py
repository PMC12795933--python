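"""Rigid transforms, trajectory metrics and point-mesh distance queries."""

import numpy as np
import pytest
import trimesh

from surfnav.geometry import (
    PointCloud,
    RigidTransform,
    Trajectory,
    apply_transform,
    closest_point_on_mesh,
    compose,
    entry_point_offset,
    invert,
    off_plan_distance,
    random_rigid_transform,
)


class TestRigidTransform:
    def test_identity_maps_points_to_themselves(self, rng):
        T = RigidTransform.identity()
        p = rng.normal(size=(10, 3))
        assert np.allclose(T.apply(p), p)

    def test_axis_rotation_quarter_turn(self):
        T = RigidTransform.from_axis_angle([0, 0, 1], np.pi / 2)
        assert np.allclose(T.apply([1.0, 0.0, 0.0]), [0.0, 1.0, 0.0], atol=1e-12)

    def test_compose_with_identity(self, rng):
        T = random_rigid_transform(rng)
        TI = compose(RigidTransform.identity(), T)
        assert np.allclose(TI.matrix(), T.matrix())

    def test_invert_identity(self):
        assert np.allclose(invert(RigidTransform.identity()).matrix(), np.eye(4))

    def test_inverse_composition_is_identity(self, rng):
        for _ in range(20):
            T = random_rigid_transform(rng)
            E = compose(invert(T), T)
            assert np.abs(E.rotation - np.eye(3)).max() < 1e-9
            assert np.linalg.norm(E.translation) < 1e-9
            p = rng.normal(size=3) * 50
            assert np.allclose(apply_transform(E, p), p, atol=1e-9)

    def test_pairwise_distances_preserved(self, rng):
        pts = rng.normal(size=(40, 3)) * 100
        for _ in range(10):
            T = random_rigid_transform(rng)
            q = T.apply(pts)
            d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            d1 = np.linalg.norm(q[:, None] - q[None, :], axis=2)
            assert np.abs(d0 - d1).max() < 1e-9

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_quaternion_normalised_on_ingest(self):
        T = RigidTransform.from_quaternion([2.0, 0.0, 0.0, 0.0], [1, 2, 3])
        assert np.allclose(T.rotation, np.eye(3))

    def test_normals_rotated_without_translation(self, rng):
        T = random_rigid_transform(rng)
        cloud = PointCloud(rng.normal(size=(5, 3)), normals=np.tile([0.0, 0.0, 1.0], (5, 1)))
        out = apply_transform(T, cloud)
        assert np.allclose(out.normals, np.tile(T.rotation[:, 2], (5, 1)))
        assert np.allclose(np.linalg.norm(out.normals, axis=1), 1.0)


class TestOffPlanDistance:
    def test_tip_on_line_gives_zero(self):
        traj = Trajectory(entry=[0, 0, 0], target=[0, 0, 10])
        assert off_plan_distance(traj.entry, traj) == 0.0

    def test_perpendicular_offset(self):
        traj = Trajectory(entry=[0, 0, 0], target=[0, 0, 10])
        assert off_plan_distance([3.0, 4.0, 5.0], traj) == pytest.approx(5.0)

    def test_line_extends_beyond_segment(self):
        traj = Trajectory(entry=[0, 0, 0], target=[0, 0, 10])
        # beyond the target: line distance is perpendicular only
        assert off_plan_distance([3.0, 4.0, 25.0], traj) == pytest.approx(5.0)
        # segment mode clamps to the endpoint instead
        seg = off_plan_distance([3.0, 4.0, 25.0], traj, mode="segment")
        assert seg == pytest.approx(np.sqrt(25 + 15**2))

    def test_matches_dense_sampling_oracle(self, rng):
        """1000 random configurations vs brute-force line sampling."""
        for _ in range(1000):
            entry = rng.normal(size=3) * 50
            target = entry + rng.normal(size=3) * 30
            if np.linalg.norm(target - entry) < 1e-3:
                continue
            tip = rng.normal(size=3) * 60
            traj = Trajectory(entry=entry, target=target)
            got = off_plan_distance(tip, traj)
            # oracle: coarse scan over the line parameter, then golden refine
            d = target - entry
            span = np.linalg.norm(tip - entry) / np.linalg.norm(d) + 1.0
            s = np.linspace(-span, span, 4001)
            vals = np.linalg.norm(tip - (entry + s[:, None] * d), axis=1)
            k = int(np.argmin(vals))
            lo, hi = s[max(k - 1, 0)], s[min(k + 1, len(s) - 1)]
            from scipy.optimize import minimize_scalar

            ref = minimize_scalar(
                lambda x: float(np.linalg.norm(tip - (entry + x * d))),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-12},
            ).fun
            assert got == pytest.approx(ref, abs=1e-6)

    def test_invariant_under_common_rigid_transform(self, rng):
        traj = Trajectory(entry=[1, 2, 3], target=[4, 5, 9])
        tip = np.array([0.0, 7.0, 2.0])
        d0 = off_plan_distance(tip, traj)
        for _ in range(25):
            T = random_rigid_transform(rng)
            assert off_plan_distance(T.apply(tip), traj.transformed(T)) == pytest.approx(d0, abs=1e-9)

    def test_bounded_by_distances_to_endpoints(self, rng):
        for _ in range(200):
            entry = rng.normal(size=3) * 40
            target = entry + rng.normal(size=3) * 25
            if np.linalg.norm(target - entry) < 1e-3:
                continue
            tip = rng.normal(size=3) * 50
            traj = Trajectory(entry=entry, target=target)
            d = off_plan_distance(tip, traj)
            assert d <= np.linalg.norm(tip - entry) + 1e-12
            assert d <= np.linalg.norm(tip - target) + 1e-12

    def test_degenerate_trajectory_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(entry=[0, 0, 0], target=[0, 0, 0])


class TestEntryPointOffset:
    def test_identical_points(self):
        assert entry_point_offset([1, 2, 3], [1, 2, 3]) == 0.0

    def test_axis_separation(self):
        assert entry_point_offset([0, 0, 0], [2, 0, 0]) == 2.0

    def test_rigid_invariance(self, rng):
        a, b = rng.normal(size=3) * 30, rng.normal(size=3) * 30
        d0 = entry_point_offset(a, b)
        for _ in range(100):
            T = random_rigid_transform(rng)
            assert entry_point_offset(T.apply(a), T.apply(b)) == pytest.approx(d0, abs=1e-9)


class TestClosestPointOnMesh:
    def test_vertex_query_returns_zero(self, small_mesh):
        p = np.asarray(small_mesh.vertices[7])
        cp, d = closest_point_on_mesh(p, small_mesh)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(cp, p)

    def test_point_above_single_triangle(self):
        tri = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]], process=False
        )
        centroid = np.array([1 / 3, 1 / 3, 0.0])
        cp, d = closest_point_on_mesh(centroid + [0, 0, 1.0], tri)
        assert d == pytest.approx(1.0)
        assert np.allclose(cp, centroid, atol=1e-12)

    def test_matches_per_triangle_oracle(self, small_mesh, rng):
        """500 random queries vs exhaustive dense-sampled triangle distances."""
        tri = np.asarray(small_mesh.triangles)
        # oracle: fine barycentric sampling of every triangle
        s = np.linspace(0, 1, 60)
        U, V = np.meshgrid(s, s)
        m = U + V <= 1
        u, v = U[m], V[m]
        samples = (
            tri[:, None, 0]
            + u[None, :, None] * (tri[:, None, 1] - tri[:, None, 0])
            + v[None, :, None] * (tri[:, None, 2] - tri[:, None, 0])
        ).reshape(-1, 3)
        for _ in range(500):
            p = rng.normal(size=3) * 15
            _, d = closest_point_on_mesh(p, small_mesh)
            d_oracle = np.linalg.norm(samples - p, axis=1).min()
            # sampled oracle can only overestimate; the exact answer is below it
            assert d <= d_oracle + 1e-9
            assert d >= d_oracle - 0.05

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError):
            closest_point_on_mesh([0, 0, 0], None)
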