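"""Millimetre-scale 3D geometry: rigid transforms, distance queries, error metrics.

All coordinates are millimetres in an arbitrary right-handed frame.  Nothing in
this module assumes a RAS/LPS anatomical convention; volumes carry an explicit
voxel-to-world affine instead (see :mod:`surfnav.surface`).

The navigation error metric used throughout the package is the *off-plan
distance*: the shortest Euclidean distance from a probe tip to the line through
a planned biopsy trajectory's entry and target points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "RigidTransform",
    "Trajectory",
    "PointCloud",
    "as_point",
    "off_plan_distance",
    "entry_point_offset",
    "closest_point_on_mesh",
    "apply_transform",
    "compose",
    "invert",
    "random_rigid_transform",
    "rotation_angle_deg",
]

_ORTHO_TOL = 1e-9
_DEGENERATE_TRAJECTORY_MM = 1e-6


def as_point(p) -> np.ndarray:
    """Coerce to a finite float64 (3,) point in mm."""
    a = np.asarray(p, dtype=np.float64).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError("point has non-finite coordinates")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """SE(3) pose: ``p -> rotation @ p + translation`` (mm).

    The rotation matrix must be orthonormal with determinant +1.  Quaternions
    are accepted at I/O boundaries only (see :func:`from_quaternion`) and are
    normalised on ingest; internally everything is a matrix.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.3g})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")
        if err > _ORTHO_TOL:
            # re-project onto SO(3) so composition chains stay orthonormal
            U, _, Vt = np.linalg.svd(R)
            R = U @ Vt
            if np.linalg.det(R) < 0:
                R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # --- constructors -----------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(M) -> "RigidTransform":
        M = np.asarray(M, dtype=np.float64).reshape(4, 4)
        return RigidTransform(M[:3, :3], M[:3, 3])

    @staticmethod
    def from_quaternion(q, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from a (w, x, y, z) quaternion; normalised on ingest."""
        from scipy.spatial.transform import Rotation

        q = np.asarray(q, dtype=np.float64).reshape(4)
        n = np.linalg.norm(q)
        if n == 0:
            raise ValueError("zero quaternion")
        w, x, y, z = q / n
        R = Rotation.from_quat([x, y, z, w]).as_matrix()
        return RigidTransform(R, np.asarray(translation, dtype=np.float64))

    @staticmethod
    def from_axis_angle(axis, angle_rad: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=np.float64).reshape(3)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("zero rotation axis")
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(axis / n * angle_rad).as_matrix()
        return RigidTransform(R, np.asarray(translation, dtype=np.float64))

    # --- group ops --------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    # --- application ------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        """Map an (n,3) array or a single (3,) point."""
        p = np.asarray(points, dtype=np.float64)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def apply_vectors(self, vecs) -> np.ndarray:
        """Rotate direction vectors / normals (no translation)."""
        v = np.asarray(vecs, dtype=np.float64)
        single = v.ndim == 1
        v = np.atleast_2d(v)
        out = v @ self.rotation.T
        return out[0] if single else out


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Transform acting as *t1 after t2*."""
    return t1.compose(t2)


def invert(t: RigidTransform) -> RigidTransform:
    return t.inverse()


def rotation_angle_deg(R_or_T) -> float:
    """Geodesic rotation angle (degrees) of a rotation matrix or transform."""
    R = R_or_T.rotation if isinstance(R_or_T, RigidTransform) else np.asarray(R_or_T)
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def random_rigid_transform(
    rng: np.random.Generator,
    max_angle_deg: float = 180.0,
    max_translation_mm: float = 100.0,
) -> RigidTransform:
    """Uniform random axis, uniform angle in [0, max], uniform translation ball."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_angle_deg))
    t_dir = rng.normal(size=3)
    t_dir /= np.linalg.norm(t_dir)
    t = t_dir * rng.uniform(0.0, max_translation_mm)
    return RigidTransform.from_axis_angle(axis, angle, t)


@dataclass(frozen=True)
class Trajectory:
    """Planned biopsy line: entry point on the skin, target point at depth."""

    entry: np.ndarray
    target: np.ndarray
    label: str = ""

    def __post_init__(self):
        e = as_point(self.entry)
        t = as_point(self.target)
        if np.linalg.norm(e - t) <= _DEGENERATE_TRAJECTORY_MM:
            raise ValueError("degenerate trajectory: entry and target coincide")
        object.__setattr__(self, "entry", e)
        object.__setattr__(self, "target", t)

    @property
    def direction(self) -> np.ndarray:
        d = self.target - self.entry
        return d / np.linalg.norm(d)

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.target - self.entry))

    def transformed(self, T: RigidTransform) -> "Trajectory":
        return Trajectory(T.apply(self.entry), T.apply(self.target), self.label)


@dataclass
class PointCloud:
    """Unstructured set of points (mm) with optional unit normals."""

    points: np.ndarray
    normals: np.ndarray | None = None
    view_origin: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
            if len(self.normals) != len(self.points):
                raise ValueError("normals/points length mismatch")
        if self.view_origin is not None:
            self.view_origin = as_point(self.view_origin)

    def __len__(self) -> int:
        return len(self.points)


def apply_transform(T: RigidTransform, obj):
    """Apply a rigid transform to a point, PointCloud or trimesh.Trimesh.

    Normals are rotated only; pairwise distances are preserved.
    """
    if isinstance(obj, PointCloud):
        return PointCloud(
            T.apply(obj.points),
            None if obj.normals is None else T.apply_vectors(obj.normals),
            None if obj.view_origin is None else T.apply(obj.view_origin),
        )
    if isinstance(obj, trimesh.Trimesh):
        out = obj.copy()
        out.vertices = T.apply(np.asarray(obj.vertices))
        return out
    if isinstance(obj, Trajectory):
        return obj.transformed(T)
    return T.apply(obj)


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

def off_plan_distance(tip, traj: Trajectory, mode: str = "line") -> float:
    """Shortest Euclidean distance from a probe tip to the planned trajectory.

    By default the distance is taken to the *infinite line* through the entry
    and target points.  ``mode="segment"`` clamps to the entry–target segment
    instead (provided for comparison; not the default metric).
    """
    tip = as_point(tip)
    d = traj.target - traj.entry
    w = tip - traj.entry
    s = float(np.dot(w, d) / np.dot(d, d))
    if mode == "segment":
        s = min(1.0, max(0.0, s))
    elif mode != "line":
        raise ValueError(f"unknown mode {mode!r}")
    closest = traj.entry + s * d
    return float(np.linalg.norm(tip - closest))


def entry_point_offset(overlaid_entry, reference_entry) -> float:
    """Euclidean distance between an overlaid and a reference entry point."""
    return float(np.linalg.norm(as_point(overlaid_entry) - as_point(reference_entry)))


# ---------------------------------------------------------------------------
# Point–mesh distance
# ---------------------------------------------------------------------------

def _closest_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest point to ``p`` on each triangle (a,b,c); vectorised Ericson."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex A
    out[m] = a[m]
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex B
    out[m] = b[m]
    done |= m

    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex C
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done  # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def closest_point_on_mesh(p, mesh: trimesh.Trimesh) -> tuple[np.ndarray, float]:
    """Globally nearest point on any triangle of the mesh, plus its distance."""
    if mesh is None or len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    p = as_point(p)
    tri = np.asarray(mesh.triangles)
    cand = _closest_on_triangles(p, tri[:, 0], tri[:, 1], tri[:, 2])
    d2 = np.einsum("ij,ij->i", cand - p, cand - p)
    i = int(np.argmin(d2))
    return cand[i], float(np.sqrt(d2[i]))


def mesh_distances(points, mesh: trimesh.Trimesh) -> np.ndarray:
    """Distance from each query point to the mesh surface."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    return np.array([closest_point_on_mesh(p, mesh)[1] for p in pts])


class MeshDistanceQuery:
    """Repeated exact point-to-surface distance queries against one mesh.

    The nearest face *centroid* upper-bounds the true surface distance, so
    the exact point-triangle test only needs the faces whose centroid lies
    within that bound plus the longest edge — a small neighbourhood instead
    of the whole mesh.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        from scipy.spatial import cKDTree

        if mesh is None or len(mesh.faces) == 0:
            raise ValueError("empty mesh")
        self._tri = np.asarray(mesh.triangles)
        centroids = self._tri.mean(axis=1)
        self._tree = cKDTree(centroids)
        edges = np.linalg.norm(self._tri[:, 1] - self._tri[:, 0], axis=1)
        self._edge_max = float(edges.max())

    def distance(self, p) -> float:
        p = as_point(p)
        upper = float(self._tree.query(p)[0])
        near = self._tree.query_ball_point(p, upper + self._edge_max)
        sub = self._tri[near]
        cand = _closest_on_triangles(p, sub[:, 0], sub[:, 1], sub[:, 2])
        return float(np.sqrt(np.einsum("ij,ij->i", cand - p, cand - p).min()))

    def distances(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return np.array([self.distance(p) for p in pts])
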