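"""Preoperative surface processing: segmentation, smoothing, meshing, decimation.

The chain mirrors a typical skin-surface workflow on a volumetric head scan:

1. :func:`threshold_segment` — threshold + largest connected component,
2. :func:`median_smooth` — majority vote in a 3 mm cubic window,
3. :func:`extract_surface` — cavity filling ("solidify") + marching cubes,
4. :func:`decimate` — quadric-error-metric simplification to 100 k triangles,
5. :func:`crop_reference` — face-only or full-head reference model, eyes removed.

Masks live on the voxel grid; every mesh leaving this module is in world
millimetres via the volume's voxel-to-world affine.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

__all__ = [
    "Volume",
    "BinaryMask",
    "threshold_segment",
    "median_smooth",
    "extract_surface",
    "decimate",
    "crop_reference",
]


@dataclass
class Volume:
    """Scalar 3D image with a voxel-to-world affine (index order x, y, z)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3D")
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine not invertible")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class BinaryMask:
    """Boolean array aligned to a source volume's grid."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


class SegmentationError(ValueError):
    pass


def threshold_segment(vol: Volume, tau: float) -> BinaryMask:
    """Threshold at ``intensity >= tau`` and keep the largest 26-connected blob."""
    raw = vol.data >= tau
    if not raw.any():
        raise SegmentationError(f"threshold {tau} leaves an empty mask")
    labels, n = ndimage.label(raw, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        raw = labels == int(np.argmax(counts))
    return BinaryMask(raw, vol.affine)


def median_smooth(mask: BinaryMask, window_mm: float = 3.0) -> BinaryMask:
    """Per-voxel majority vote in a cubic window of the given physical edge.

    The window is converted to voxels per axis by rounding ``window_mm /
    spacing`` to the nearest odd integer (minimum 3), so the voxel count is
    odd and the vote can never tie.  Voxels outside the array count as False.
    """
    if window_mm <= 0:
        raise ValueError("window_mm must be positive")
    size = tuple(_round_to_odd(window_mm / s) for s in mask.spacing)
    frac = ndimage.uniform_filter(mask.mask.astype(np.float64), size=size, mode="constant", cval=0.0)
    return BinaryMask(frac > 0.5, mask.affine)


def _round_to_odd(x: float) -> int:
    k = int(round(x))
    if k % 2 == 0:
        # round to the *nearest* odd
        k = k + 1 if x >= k else k - 1
    return max(k, 3)


def extract_surface(mask: BinaryMask, smooth: bool = True) -> trimesh.Trimesh:
    """Marching-cubes skin surface of a binary mask, in world mm.

    Internal cavities are flood-filled first so the output bounds a solid
    region (the equivalent of solidifying the segmentation before export).
    With ``smooth`` the binary field is box-averaged (3-voxel window) before
    the 0.5 iso-level is extracted, which removes voxel staircasing.
    """
    m = mask.mask
    if not m.any() or m.all():
        raise SegmentationError("mask must contain both foreground and background")
    solid = ndimage.binary_fill_holes(m)
    f = solid.astype(np.float64)
    if smooth:
        f = ndimage.uniform_filter(f, size=3, mode="constant", cval=0.0)
    padded = np.pad(f, 1, mode="constant", constant_values=0.0)
    verts_ijk, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts_ijk -= 1.0  # undo pad
    world = verts_ijk @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=world, faces=faces, process=True)
    return mesh


# ---------------------------------------------------------------------------
# Quadric-error-metric decimation
# ---------------------------------------------------------------------------

def decimate(mesh: trimesh.Trimesh, target_faces: int = 100_000) -> trimesh.Trimesh:
    """Edge-collapse simplification with quadric error metrics.

    Meshes already at or below ``target_faces`` are returned unchanged.
    Collapses that would flip an incident face normal are rejected, which
    bounds the geometric deviation of the simplified surface.
    """
    if target_faces < 4:
        raise ValueError("target_faces must be >= 4")
    if len(mesh.faces) <= target_faces:
        return mesh

    V = np.asarray(mesh.vertices, dtype=np.float64).copy()
    F = np.asarray(mesh.faces, dtype=np.int64).copy()
    nf = len(F)

    # per-face plane quadrics, area weighted
    tri = V[F]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(n, axis=1)
    good = area2 > 1e-14
    nrm = np.zeros_like(n)
    nrm[good] = n[good] / area2[good, None]
    d = -np.einsum("ij,ij->i", nrm, tri[:, 0])
    planes = np.hstack([nrm, d[:, None]])  # (nf,4)
    Kf = planes[:, :, None] * planes[:, None, :] * (0.5 * area2)[:, None, None]

    Q = np.zeros((len(V), 4, 4))
    for k in range(3):
        np.add.at(Q, F[:, k], Kf)

    face_alive = np.ones(nf, dtype=bool)
    vert_faces: list[set] = [set() for _ in range(len(V))]
    for fi, (a, b, c) in enumerate(F):
        vert_faces[a].add(fi)
        vert_faces[b].add(fi)
        vert_faces[c].add(fi)

    version = np.zeros(len(V), dtype=np.int64)

    def edge_cost(u: int, v: int):
        Quv = Q[u] + Q[v]
        A = Quv[:3, :3]
        b = -Quv[:3, 3]
        try:
            pos = np.linalg.solve(A, b)
            if not np.all(np.isfinite(pos)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            pos = 0.5 * (V[u] + V[v])
        best = None
        for cand in (pos, 0.5 * (V[u] + V[v]), V[u], V[v]):
            h = np.append(cand, 1.0)
            c = float(h @ Quv @ h)
            if best is None or c < best[0]:
                best = (c, cand)
        return best

    def collect_edges():
        e = np.vstack([F[face_alive][:, [0, 1]], F[face_alive][:, [1, 2]], F[face_alive][:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    heap: list = []
    for u, v in collect_edges():
        c, pos = edge_cost(int(u), int(v))
        heapq.heappush(heap, (c, int(u), int(v), version[u], version[v], tuple(pos)))

    n_alive = int(face_alive.sum())
    while n_alive > target_faces and heap:
        c, u, v, ver_u, ver_v, pos = heapq.heappop(heap)
        if version[u] != ver_u or version[v] != ver_v:
            continue
        if u == v:
            continue
        pos = np.asarray(pos)
        # reject collapses that flip a surviving face normal
        flip = False
        for fi in (vert_faces[u] | vert_faces[v]):
            if not face_alive[fi]:
                continue
            a, b, cc = F[fi]
            if len({a, b, cc} & {u, v}) == 2:
                continue  # face will be removed
            p = [V[x] if x not in (u, v) else pos for x in (a, b, cc)]
            old = [V[x] for x in (a, b, cc)]
            n_new = np.cross(p[1] - p[0], p[2] - p[0])
            n_old = np.cross(old[1] - old[0], old[2] - old[0])
            if np.dot(n_new, n_old) <= 0:
                flip = True
                break
        if flip:
            continue

        # collapse v into u at pos
        V[u] = pos
        Q[u] = Q[u] + Q[v]
        for fi in list(vert_faces[v]):
            if not face_alive[fi]:
                continue
            fverts = F[fi]
            if u in fverts:
                face_alive[fi] = False
                n_alive -= 1
                for x in fverts:
                    vert_faces[x].discard(fi)
            else:
                F[fi] = np.where(fverts == v, u, fverts)
                vert_faces[u].add(fi)
        vert_faces[v] = set()
        version[u] += 1
        version[v] += 1

        # refresh costs of edges incident to u
        nbrs = set()
        for fi in vert_faces[u]:
            if face_alive[fi]:
                nbrs.update(int(x) for x in F[fi])
        nbrs.discard(u)
        for w in nbrs:
            a, b = (u, w) if u < w else (w, u)
            cc, p = edge_cost(a, b)
            heapq.heappush(heap, (cc, a, b, version[a], version[b], tuple(p)))

    out = trimesh.Trimesh(vertices=V, faces=F[face_alive], process=True)
    return out


# ---------------------------------------------------------------------------
# Reference-model cropping
# ---------------------------------------------------------------------------

def estimate_landmarks(mesh: trimesh.Trimesh) -> dict:
    """Nose tip, eye centers and coronal cut for a +y-facing head mesh.

    Uses landmarks stored by the phantom generator when available; otherwise
    falls back to simple heuristics (most anterior vertex as nose tip, eyes
    offset laterally and superiorly from it).
    """
    meta = getattr(mesh, "metadata", None) or {}
    if "landmarks" in meta:
        lm = meta["landmarks"]
        return {k: np.asarray(v, dtype=np.float64) for k, v in lm.items()}
    V = np.asarray(mesh.vertices)
    nose = V[int(np.argmax(V[:, 1]))]
    centroid = V.mean(axis=0)
    up = np.array([0.0, 0.0, 1.0])
    right = np.array([1.0, 0.0, 0.0])
    eye_l = nose - 32.0 * right + 30.0 * up - 12.0 * np.array([0, 1, 0])
    eye_r = nose + 32.0 * right + 30.0 * up - 12.0 * np.array([0, 1, 0])
    return {
        "nose_tip": nose,
        "eye_left": eye_l,
        "eye_right": eye_r,
        "ear_plane_y": np.array([centroid[1]]),
    }


def crop_reference(
    mesh: trimesh.Trimesh,
    mode: str = "face_only",
    landmarks: dict | None = None,
    eye_radius_mm: float = 15.0,
) -> trimesh.Trimesh:
    """Build a registration reference model.

    ``face_only`` keeps the surface anterior to a coronal plane through the
    ear landmarks; ``full_head`` keeps everything.  Both modes delete the
    surface inside two eye-exclusion spheres.
    """
    if mode not in ("face_only", "full_head"):
        raise ValueError(f"unknown mode {mode!r}")
    lm = landmarks if landmarks is not None else estimate_landmarks(mesh)
    V = np.asarray(mesh.vertices)
    keep = np.ones(len(V), dtype=bool)
    if mode == "face_only":
        y_cut = float(np.asarray(lm["ear_plane_y"]).ravel()[0])
        keep &= V[:, 1] >= y_cut
    for key in ("eye_left", "eye_right"):
        c = np.asarray(lm[key], dtype=np.float64)
        keep &= np.linalg.norm(V - c, axis=1) > eye_radius_mm
    face_mask = keep[np.asarray(mesh.faces)].all(axis=1)
    if not face_mask.any():
        raise SegmentationError("crop removed the entire mesh")
    out = mesh.submesh([np.nonzero(face_mask)[0]], append=True)
    return out


def sampled_hausdorff(a: trimesh.Trimesh, b: trimesh.Trimesh,
                      n_samples: int = 300, seed: int = 0) -> float:
    """Symmetric sampled Hausdorff distance between two surfaces (mm)."""
    from .depthsim import sample_surface
    from .geometry import MeshDistanceQuery

    rng = np.random.default_rng(seed)
    pa, _ = sample_surface(a, n_samples, rng)
    pb, _ = sample_surface(b, n_samples, rng)
    d_ab = MeshDistanceQuery(b).distances(pa).max()
    d_ba = MeshDistanceQuery(a).distances(pb).max()
    return float(max(d_ab, d_ba))
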