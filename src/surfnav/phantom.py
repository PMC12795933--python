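"""Digital head phantoms with conical fiducials — the in-silico stand-in for a
3D-printed head and for patients.

The phantom is a watertight, genus-0 head-like surface: an ellipsoidal cranium
with procedural facial relief (nose, brow, chin, cheekbones, eye sockets and a
seeded low-amplitude asymmetry field).  The facial asymmetry is what makes
markerless surface registration well-posed, so the relief amplitude is a
first-class parameter.

Fiducials follow the conical-divot design used for phantom accuracy studies:
each is an inverted cone whose apex sits ``fiducial_depth_mm`` (default 20 mm)
below the skin along the inward surface normal, with the planned trajectory
running from the centre of the surface opening to the apex.  Coordinate
convention: +x right, +y anterior (face direction), +z superior; units mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import Trajectory
from .surface import Volume

__all__ = [
    "PhantomSpec",
    "Fiducial",
    "DeformationField",
    "generate_head_phantom",
    "place_fiducials",
    "plan_trajectories",
    "voxelize",
    "points_in_mesh",
    "make_skin_shift_field",
    "apply_skin_shift",
]

_MAX_SUBDIV_VERTS = 163_842  # icosphere at 7 subdivisions


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head phantom."""

    seed: int = 0
    head_dims_mm: tuple = (155.0, 195.0, 225.0)  # width, depth (A-P), height
    feature_amplitude_mm: float = 15.0
    n_fiducials: int = 51
    fiducial_depth_mm: float = 20.0
    cone_margin_mm: float = 0.2
    mesh_resolution: int = 10_000  # target vertex count
    min_fiducial_spacing_mm: float = 15.0

    def __post_init__(self):
        if self.n_fiducials < 1:
            raise ValueError("n_fiducials must be >= 1")
        if self.fiducial_depth_mm <= 0:
            raise ValueError("fiducial_depth_mm must be positive")
        if any(d <= 0 for d in self.head_dims_mm):
            raise ValueError("head extents must be positive")


@dataclass(frozen=True)
class Fiducial:
    """One conical measurement point."""

    id: int
    tip: np.ndarray            # cone apex, inside the head
    surface_center: np.ndarray  # centre of the skin-surface opening
    axis: np.ndarray           # unit vector surface_center -> tip (inward)


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Head synthesis
# ---------------------------------------------------------------------------

# (direction on the unit sphere, angular sigma in rad, amplitude as a fraction
# of feature_amplitude_mm); y is anterior, z superior
_FEATURES = [
    ((0.00, 0.97, -0.22), 0.13, 1.00),   # nose
    ((-0.25, 0.88, 0.40), 0.18, 0.35),   # left brow
    ((0.25, 0.88, 0.40), 0.18, 0.35),    # right brow
    ((0.00, 0.78, -0.62), 0.16, 0.50),   # chin
    ((-0.52, 0.72, 0.02), 0.20, 0.30),   # left cheekbone
    ((0.52, 0.72, 0.02), 0.20, 0.30),    # right cheekbone
    ((-0.30, 0.92, 0.20), 0.10, -0.45),  # left eye socket
    ((0.30, 0.92, 0.20), 0.10, -0.45),   # right eye socket
    ((0.00, -0.95, 0.30), 0.30, 0.30),   # occipital bump
]
_EYE_DIRS = [(-0.30, 0.92, 0.20), (0.30, 0.92, 0.20)]


def _unit(v):
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


def generate_head_phantom(spec: PhantomSpec) -> trimesh.Trimesh:
    """Deterministic head-like watertight mesh for a given spec.

    The bounding-box extents of the result equal ``head_dims_mm`` exactly
    (the relief is applied first, then the mesh is rescaled per axis), and
    the bounding box is centred on the origin.
    """
    subdiv, nvert = 0, 12
    while nvert < spec.mesh_resolution:
        subdiv += 1
        nvert = 10 * 4**subdiv + 2
        if nvert > _MAX_SUBDIV_VERTS:
            raise PhantomError(
                f"mesh_resolution {spec.mesh_resolution} exceeds the maximum "
                f"supported vertex count {_MAX_SUBDIV_VERTS}"
            )
    base = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    u = np.asarray(base.vertices, dtype=np.float64)  # unit directions
    faces = np.asarray(base.faces, dtype=np.int64)

    rng = np.random.default_rng(spec.seed)
    semi = np.asarray(spec.head_dims_mm, dtype=np.float64) / 2.0
    mean_r = float(np.mean(semi))

    # radial displacement in mm as a function of direction on the sphere
    bump_total = np.zeros(len(u))
    feats = list(_FEATURES)
    for _ in range(8):  # seeded asymmetry field
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        amp = rng.uniform(-0.08, 0.08)
        sig = rng.uniform(0.15, 0.35)
        feats.append((tuple(d), sig, amp))
    for dirn, sigma, amp in feats:
        c = _unit(dirn)
        ang = np.arccos(np.clip(u @ c, -1.0, 1.0))
        bump_total += amp * spec.feature_amplitude_mm * np.exp(-0.5 * (ang / sigma) ** 2)

    radial = 1.0 + bump_total / mean_r
    verts = u * semi * radial[:, None]

    # rescale so the bounding box matches head_dims_mm exactly, centred
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    verts = (verts - (lo + hi) / 2.0) * (2.0 * semi / (hi - lo))

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    eye_ids = [int(np.argmax(u @ _unit(d))) for d in _EYE_DIRS]
    mesh.metadata["landmarks"] = {
        "nose_tip": verts[int(np.argmax(verts[:, 1]))].copy(),
        "eye_left": verts[eye_ids[0]].copy(),
        "eye_right": verts[eye_ids[1]].copy(),
        "ear_plane_y": np.array([0.0]),
    }
    mesh.metadata["spec_seed"] = spec.seed
    return mesh


# ---------------------------------------------------------------------------
# Point-in-mesh (column parity)
# ---------------------------------------------------------------------------

def points_in_mesh(mesh: trimesh.Trimesh, points) -> np.ndarray:
    """Watertight containment test by ray-crossing parity.

    Casts one ray per query point along a fixed irrational direction and
    counts Möller–Trumbore intersections over all faces (exact-edge hits are
    measure-zero for generic data).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    d = _unit([0.5773502691896258, 0.5773502691896257, 0.5773502691896259])
    tri = np.asarray(mesh.triangles)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    inside = np.zeros(len(pts), dtype=bool)
    for i, p in enumerate(pts):
        tvec = p - v0
        uu = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)
        vv = qvec @ d * inv_det
        t = np.einsum("ij,ij->i", e2, qvec) * inv_det
        hit = ok & (uu >= 0) & (vv >= 0) & (uu + vv <= 1) & (t > 1e-9)
        inside[i] = (hit.sum() % 2) == 1
    return inside


# ---------------------------------------------------------------------------
# Fiducials & trajectories
# ---------------------------------------------------------------------------

def place_fiducials(mesh: trimesh.Trimesh, spec: PhantomSpec) -> list[Fiducial]:
    """Distribute fiducials over the face/scalp by farthest-point sampling.

    Each fiducial's cone apex sits ``fiducial_depth_mm`` below its surface
    centre along the inward surface normal.  Candidates whose apex would fall
    outside the head or closer than 96% of the nominal depth to the surface
    (e.g. under high-curvature relief) are rejected.  A minimum Euclidean
    spacing between surface centres is enforced.
    """
    if not mesh.is_watertight:
        raise PhantomError("fiducial placement requires a watertight mesh")
    V = np.asarray(mesh.vertices)
    N = np.asarray(mesh.vertex_normals)
    zlo = V[:, 2].min()
    zhi = V[:, 2].max()
    cand = np.nonzero(V[:, 2] > zlo + 0.18 * (zhi - zlo))[0]

    depth = spec.fiducial_depth_mm
    chosen: list[int] = []
    tips: list[np.ndarray] = []
    min_d = np.full(len(cand), np.inf)
    rejected = np.zeros(len(cand), dtype=bool)

    # cheap prefilter: approximate tip-to-surface distance from a KD-tree over
    # vertices + face centroids; exact checks run only on selected candidates
    from scipy.spatial import cKDTree

    n_unit = N[cand] / np.linalg.norm(N[cand], axis=1, keepdims=True)
    tips_all = V[cand] - depth * n_unit
    surf_pts = np.vstack([V, np.asarray(mesh.triangles).mean(axis=1)])
    # nearest-sample distance upper-bounds the true surface distance, so
    # anything already below the bound here can never pass the exact check
    approx_d = cKDTree(surf_pts).query(tips_all)[0]
    rejected |= approx_d < 0.96 * depth

    # start at the most anterior admissible candidate (nose region)
    next_idx = int(np.argmax(np.where(~rejected, V[cand, 1], -np.inf)))

    tri = np.asarray(mesh.triangles)
    centroids = tri.mean(axis=1)
    ctree = cKDTree(centroids)
    edge_max = float(np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1).max())

    def exact_surface_dist(tip: np.ndarray, radius: float) -> float:
        # any face with a point within `radius` of tip has its centroid
        # within radius + edge_max, so this local search is exact
        fids_near = ctree.query_ball_point(tip, radius + edge_max)
        sub = tri[fids_near]
        from .geometry import _closest_on_triangles

        cand_pts = _closest_on_triangles(tip, sub[:, 0], sub[:, 1], sub[:, 2])
        return float(np.sqrt(np.einsum("ij,ij->i", cand_pts - tip, cand_pts - tip).min()))

    def tip_ok(cidx: int):
        vid = int(cand[cidx])
        tip = V[vid] - depth * _unit(N[vid])
        if exact_surface_dist(tip, float(approx_d[cidx])) < 0.96 * depth:
            return None
        if not points_in_mesh(mesh, tip[None])[0]:
            return None
        return tip

    while len(chosen) < spec.n_fiducials:
        vid = int(cand[next_idx])
        tip = tip_ok(next_idx)
        if tip is None:
            rejected[next_idx] = True
        else:
            chosen.append(vid)
            tips.append(tip)
            d = np.linalg.norm(V[cand] - V[vid], axis=1)
            min_d = np.minimum(min_d, d)
        avail = ~rejected & (min_d >= spec.min_fiducial_spacing_mm)
        if len(chosen) >= spec.n_fiducials:
            break
        if not avail.any():
            raise PhantomError(
                f"could only place {len(chosen)} of {spec.n_fiducials} fiducials "
                f"at {spec.min_fiducial_spacing_mm} mm spacing"
            )
        # farthest-point step: maximise distance to already-chosen set
        masked = np.where(avail, min_d, -np.inf)
        next_idx = int(np.argmax(masked))

    fids = []
    for k, (vid, tip) in enumerate(zip(chosen, tips)):
        sc = V[vid].copy()
        fids.append(Fiducial(id=k, tip=tip, surface_center=sc, axis=_unit(tip - sc)))
    return fids


def plan_trajectories(fiducials: list[Fiducial]) -> list[Trajectory]:
    """One biopsy plan per fiducial: entry at the surface opening, target at
    the cone apex."""
    return [
        Trajectory(entry=f.surface_center, target=f.tip, label=f"F{f.id:02d}")
        for f in fiducials
    ]


# ---------------------------------------------------------------------------
# Voxelization (column-parity fill)
# ---------------------------------------------------------------------------

def voxelize(
    mesh: trimesh.Trimesh,
    voxel_mm,
    inside_value: float = 100.0,
    outside_value: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Volume:
    """Scalar volume whose voxels with centre inside the mesh get
    ``inside_value`` (plus optional Gaussian noise), else ``outside_value``.

    Containment is resolved per (x, y) column by counting surface crossings
    along z (even–odd rule), which is exact for watertight meshes.
    """
    if not mesh.is_watertight:
        raise PhantomError("voxelize requires a watertight mesh")
    voxel = np.broadcast_to(np.asarray(voxel_mm, dtype=np.float64).ravel(), (3,)).copy()
    if np.any(voxel <= 0):
        raise ValueError("voxel size must be positive")
    lo = mesh.bounds[0] - voxel
    hi = mesh.bounds[1] + voxel
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    # voxel (i,j,k) centre = lo + (idx + 0.5) * voxel
    origin = lo + 0.5 * voxel

    cross = np.zeros(tuple(shape), dtype=np.int16)
    tri = np.asarray(mesh.triangles)
    for t in tri:
        x, y, z = t[:, 0], t[:, 1], t[:, 2]
        det = (y[1] - y[2]) * (x[0] - x[2]) + (x[2] - x[1]) * (y[0] - y[2])
        if abs(det) < 1e-12:
            continue  # edge-on to the z axis; adjacent faces carry the crossing
        i0 = max(int(np.ceil((x.min() - origin[0]) / voxel[0])), 0)
        i1 = min(int(np.floor((x.max() - origin[0]) / voxel[0])), shape[0] - 1)
        j0 = max(int(np.ceil((y.min() - origin[1]) / voxel[1])), 0)
        j1 = min(int(np.floor((y.max() - origin[1]) / voxel[1])), shape[1] - 1)
        if i1 < i0 or j1 < j0:
            continue
        gx = origin[0] + np.arange(i0, i1 + 1) * voxel[0]
        gy = origin[1] + np.arange(j0, j1 + 1) * voxel[1]
        PX, PY = np.meshgrid(gx, gy, indexing="ij")
        l0 = ((y[1] - y[2]) * (PX - x[2]) + (x[2] - x[1]) * (PY - y[2])) / det
        l1 = ((y[2] - y[0]) * (PX - x[2]) + (x[0] - x[2]) * (PY - y[2])) / det
        l2 = 1.0 - l0 - l1
        inside2d = (l0 >= 0) & (l1 >= 0) & (l2 >= 0)
        if not inside2d.any():
            continue
        zc = l0 * z[0] + l1 * z[1] + l2 * z[2]
        ii, jj = np.nonzero(inside2d)
        kk = np.ceil((zc[ii, jj] - origin[2]) / voxel[2]).astype(int)
        valid = kk < shape[2]
        kk = np.clip(kk[valid], 0, shape[2] - 1)
        np.add.at(cross, (ii[valid] + i0, jj[valid] + j0, kk), 1)

    inside = (np.cumsum(cross[:, :, ::-1], axis=2)[:, :, ::-1] % 2) == 1
    data = np.where(inside, inside_value, outside_value).astype(np.float64)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel)
    affine[:3, 3] = origin
    return Volume(data, affine)


# ---------------------------------------------------------------------------
# Skin-shift deformation
# ---------------------------------------------------------------------------

@dataclass
class DeformationField:
    """Smooth displacement field: a sum of Gaussian radial-basis bumps times a
    smooth anterior→posterior ramp, clamped to ``max_magnitude_mm``.

    Models the skin shift caused by patient positioning, which is worse
    towards the back of the head.
    """

    centers: np.ndarray      # (k,3) bump centres
    directions: np.ndarray   # (k,3) unit displacement directions
    amplitudes: np.ndarray   # (k,) mm
    sigmas: np.ndarray       # (k,) mm
    max_magnitude_mm: float
    y_range: tuple = (-100.0, 100.0)        # anterior axis extent of the head
    region_weighting: tuple = (1.0, 1.0)    # (anterior weight, posterior weight)

    def ramp(self, y: np.ndarray) -> np.ndarray:
        y0, y1 = self.y_range  # y1 = anterior-most
        s = np.clip((y1 - y) / max(y1 - y0, 1e-9), 0.0, 1.0)
        s = s * s * (3.0 - 2.0 * s)  # smoothstep, 0 anterior -> 1 posterior
        wa, wp = self.region_weighting
        return wa + (wp - wa) * s

    def displacement(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        disp = np.zeros_like(p)
        for c, d, a, s in zip(self.centers, self.directions, self.amplitudes, self.sigmas):
            r2 = np.einsum("ij,ij->i", p - c, p - c)
            disp += (a * np.exp(-0.5 * r2 / s**2))[:, None] * d
        disp *= self.ramp(p[:, 1])[:, None]
        mag = np.linalg.norm(disp, axis=1)
        over = mag > self.max_magnitude_mm
        if over.any():
            disp[over] *= (self.max_magnitude_mm / mag[over])[:, None]
        return disp


def make_skin_shift_field(
    mesh: trimesh.Trimesh,
    max_magnitude_mm: float,
    seed: int = 0,
    n_bumps: int = 5,
    region_weighting: tuple = (0.3, 1.0),
) -> DeformationField:
    """Seeded skin-shift field over a head mesh.

    Bump centres are drawn uniformly over the mesh vertices; the posterior
    emphasis comes from the ramp, which multiplies the bump magnitudes along
    the anterior-posterior axis.
    """
    n_bumps = min(int(n_bumps), 5)
    rng = np.random.default_rng(seed)
    V = np.asarray(mesh.vertices)
    y0, y1 = float(V[:, 1].min()), float(V[:, 1].max())
    idx = rng.choice(len(V), size=n_bumps, replace=False)
    dirs = rng.normal(size=(n_bumps, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.uniform(0.6, 1.0, size=n_bumps) * max_magnitude_mm
    sigmas = rng.uniform(40.0, 70.0, size=n_bumps)
    return DeformationField(
        centers=V[idx].copy(), directions=dirs, amplitudes=amps, sigmas=sigmas,
        max_magnitude_mm=max_magnitude_mm, y_range=(y0, y1),
        region_weighting=region_weighting,
    )


def apply_skin_shift(mesh: trimesh.Trimesh, fld: DeformationField) -> trimesh.Trimesh:
    """Displace vertices by the field; connectivity is unchanged."""
    V = np.asarray(mesh.vertices)
    out = trimesh.Trimesh(
        vertices=V + fld.displacement(V),
        faces=np.asarray(mesh.faces).copy(),
        process=False,
    )
    out.metadata.update(getattr(mesh, "metadata", {}) or {})
    return out
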