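"""Simulated head-mounted depth sensor.

Renders a z-buffer depth image of a scene mesh from a pinhole camera,
converts it to a world-frame point cloud, and corrupts it with a
time-of-flight-style noise model (axial Gaussian jitter along the view ray,
range quantization, Bernoulli dropout).

Camera convention: +x right, +y down, +z forward (optical axis); the pixel at
row ``i``, column ``j`` samples the ray through image coordinates
``(u, v) = (j, i)``.  Depth is the distance along the camera z axis, in mm.
Invalid pixels carry depth 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .geometry import PointCloud, RigidTransform

__all__ = [
    "DepthCamera",
    "DepthImage",
    "NoiseModel",
    "look_at",
    "render_depth",
    "depth_to_pointcloud",
    "corrupt",
    "coverage_fraction",
    "sample_surface",
]


@dataclass(frozen=True)
class DepthCamera:
    """Pinhole depth camera with a camera-to-world pose."""

    width: int = 320
    height: int = 288
    fx: float = 208.55
    fy: float = 208.55
    cx: float = 160.0
    cy: float = 144.0
    pose: RigidTransform = None
    max_range_mm: float = 1500.0
    invalid_value: float = 0.0

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside the image")
        if self.pose is None:
            object.__setattr__(self, "pose", RigidTransform.identity())

    @staticmethod
    def hololens_like(pose: RigidTransform | None = None,
                      width: int = 320, height: int = 288,
                      hfov_deg: float = 75.0,
                      max_range_mm: float = 1500.0) -> "DepthCamera":
        """Default sensor: 320x288 pixels, 75 deg horizontal field of view."""
        fx = (width / 2.0) / np.tan(np.radians(hfov_deg) / 2.0)
        return DepthCamera(width=width, height=height, fx=fx, fy=fx,
                           cx=width / 2.0, cy=height / 2.0, pose=pose,
                           max_range_mm=max_range_mm)


@dataclass
class DepthImage:
    """Per-pixel depth (mm) along camera z; 0 marks invalid pixels."""

    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.ndim != 2:
            raise ValueError("depth image must be 2D")

    @property
    def valid(self) -> np.ndarray:
        return self.depth > 0


@dataclass(frozen=True)
class NoiseModel:
    """Axial time-of-flight noise: Gaussian along the ray, then quantization,
    then dropout.  Lateral jitter is deliberately omitted."""

    axial_sd_mm: float = 1.0
    dropout_rate: float = 0.05
    quantization_mm: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0,1]")
        if self.axial_sd_mm < 0 or self.quantization_mm < 0:
            raise ValueError("noise scales must be nonnegative")


def look_at(eye, target, up=(0.0, 0.0, 1.0)) -> RigidTransform:
    """Camera-to-world pose with the optical axis pointing at ``target``."""
    eye = np.asarray(eye, dtype=np.float64)
    f = np.asarray(target, dtype=np.float64) - eye
    f = f / np.linalg.norm(f)
    up = np.asarray(up, dtype=np.float64)
    r = np.cross(f, up)
    n = np.linalg.norm(r)
    if n < 1e-9:  # looking straight along up: pick any perpendicular
        alt = np.array([1.0, 0.0, 0.0]) if abs(f[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        r = np.cross(f, alt)
        n = np.linalg.norm(r)
    r = r / n
    d = np.cross(f, r)
    R = np.column_stack([r, d, f])
    return RigidTransform(R, eye)


def render_depth(mesh: trimesh.Trimesh, cam: DepthCamera) -> DepthImage:
    """Perspective-correct z-buffer rasterization of the mesh.

    Each pixel holds the camera-z distance to the first surface hit along the
    pixel-centre ray, or 0 if no triangle covers it (or the hit is beyond
    ``max_range_mm``).  Triangles with any vertex behind the camera are
    dropped rather than clipped; scenes are assumed fully in front.
    """
    if mesh is None or len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    w2c = cam.pose.inverse()
    V = w2c.apply(np.asarray(mesh.vertices))
    F = np.asarray(mesh.faces)
    z = V[:, 2]
    u = cam.fx * V[:, 0] / np.where(z > 0, z, 1.0) + cam.cx
    v = cam.fy * V[:, 1] / np.where(z > 0, z, 1.0) + cam.cy
    inv_z = 1.0 / np.where(z > 0, z, 1.0)

    zbuf = np.full((cam.height, cam.width), np.inf)
    front = (z[F] > 0.5).all(axis=1)
    for a, b, c in F[front]:
        ua, ub, uc = u[a], u[b], u[c]
        va, vb, vc = v[a], v[b], v[c]
        det = (vb - vc) * (ua - uc) + (uc - ub) * (va - vc)
        if abs(det) < 1e-12:
            continue
        j0 = max(int(np.ceil(min(ua, ub, uc))), 0)
        j1 = min(int(np.floor(max(ua, ub, uc))), cam.width - 1)
        i0 = max(int(np.ceil(min(va, vb, vc))), 0)
        i1 = min(int(np.floor(max(va, vb, vc))), cam.height - 1)
        if j1 < j0 or i1 < i0:
            continue
        JJ, II = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
        l0 = ((vb - vc) * (JJ - uc) + (uc - ub) * (II - vc)) / det
        l1 = ((vc - va) * (JJ - uc) + (ua - uc) * (II - vc)) / det
        l2 = 1.0 - l0 - l1
        inside = (l0 >= -1e-12) & (l1 >= -1e-12) & (l2 >= -1e-12)
        if not inside.any():
            continue
        depth = 1.0 / (l0 * inv_z[a] + l1 * inv_z[b] + l2 * inv_z[c])
        tile = zbuf[i0:i1 + 1, j0:j1 + 1]
        upd = inside & (depth < tile)
        tile[upd] = depth[upd]

    out = np.where(np.isfinite(zbuf) & (zbuf <= cam.max_range_mm), zbuf, 0.0)
    return DepthImage(out)


def depth_to_pointcloud(img: DepthImage, cam: DepthCamera) -> PointCloud:
    """One world-frame point per valid pixel via inverse pinhole projection.

    Points are emitted in row-major pixel order; the camera origin is stored
    on the cloud as ``view_origin`` for downstream axial-noise models and
    normal orientation.
    """
    ii, jj = np.nonzero(img.valid)
    d = img.depth[ii, jj]
    x = (jj - cam.cx) / cam.fx * d
    y = (ii - cam.cy) / cam.fy * d
    p_cam = np.column_stack([x, y, d])
    return PointCloud(cam.pose.apply(p_cam), view_origin=cam.pose.translation)


def project(cam: DepthCamera, points_world) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World points -> (u, v, camera-z depth)."""
    p = cam.pose.inverse().apply(np.atleast_2d(np.asarray(points_world, dtype=np.float64)))
    z = p[:, 2]
    u = cam.fx * p[:, 0] / z + cam.cx
    v = cam.fy * p[:, 1] / z + cam.cy
    return u, v, z


def corrupt(cloud: PointCloud, model: NoiseModel, sensor_origin=None) -> PointCloud:
    """Apply the sensor-noise model; deterministic for a fixed seed.

    Order: axial Gaussian perturbation along the view ray, range
    quantization, Bernoulli dropout.
    """
    origin = sensor_origin if sensor_origin is not None else cloud.view_origin
    if origin is None:
        raise ValueError("corrupt needs a sensor origin (cloud.view_origin unset)")
    origin = np.asarray(origin, dtype=np.float64).reshape(3)
    rng = np.random.default_rng(model.seed)
    pts = cloud.points.copy()
    if model.axial_sd_mm > 0 or model.quantization_mm > 0:
        rel = pts - origin
        r = np.linalg.norm(rel, axis=1)
        dirs = rel / r[:, None]
        if model.axial_sd_mm > 0:
            r = r + rng.normal(0.0, model.axial_sd_mm, size=len(r))
        if model.quantization_mm > 0:
            r = np.round(r / model.quantization_mm) * model.quantization_mm
        pts = origin + dirs * r[:, None]
    if model.dropout_rate > 0:
        keep = rng.random(len(pts)) >= model.dropout_rate
        pts = pts[keep]
    return PointCloud(pts, view_origin=origin)


def sample_surface(mesh: trimesh.Trimesh, n: int, rng: np.random.Generator):
    """Area-weighted random surface samples; returns (points, face normals)."""
    areas = np.asarray(mesh.area_faces)
    fid = rng.choice(len(areas), size=n, p=areas / areas.sum())
    r1, r2 = rng.random(n), rng.random(n)
    flip = r1 + r2 > 1
    r1[flip], r2[flip] = 1 - r1[flip], 1 - r2[flip]
    tri = np.asarray(mesh.triangles)[fid]
    pts = tri[:, 0] + r1[:, None] * (tri[:, 1] - tri[:, 0]) + r2[:, None] * (tri[:, 2] - tri[:, 0])
    return pts, np.asarray(mesh.face_normals)[fid]


def coverage_fraction(mesh: trimesh.Trimesh, cam: DepthCamera,
                      n_samples: int = 2000, seed: int = 0,
                      tol_mm: float = 2.0) -> float:
    """Fraction of the mesh's surface area visible in the rendered depth image.

    Used to label partial-view scenarios (e.g. heavy occlusion cases).
    """
    img = render_depth(mesh, cam)
    rng = np.random.default_rng(seed)
    pts, _ = sample_surface(mesh, n_samples, rng)
    u, v, z = project(cam, pts)
    jj = np.round(u).astype(int)
    ii = np.round(v).astype(int)
    ok = (z > 0) & (jj >= 0) & (jj < cam.width) & (ii >= 0) & (ii < cam.height)
    vis = np.zeros(n_samples, dtype=bool)
    d = img.depth[ii[ok], jj[ok]]
    vis[ok] = (d > 0) & (np.abs(d - z[ok]) < tol_mm)
    return float(vis.mean())
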