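"""File formats: meshes (PLY/STL/OBJ), point clouds (PLY/XYZ), NRRD volumes,
depth images (16-bit PNG or NPY), trajectory plans and transforms (JSON).

PLY is the canonical interchange format (binary little-endian on write);
NRRD carries volumes with their voxel-to-world affine.  Trajectory JSON
schema: ``{"label": str, "entry_mm": [x,y,z], "target_mm": [x,y,z]}``;
transforms are serialised as 4x4 row-major matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .geometry import PointCloud, RigidTransform, Trajectory
from .surface import Volume

__all__ = [
    "MeshIOError",
    "VolumeIOError",
    "read_mesh",
    "write_mesh",
    "read_pointcloud",
    "write_pointcloud",
    "read_volume",
    "write_volume",
    "read_trajectories",
    "write_trajectories",
    "read_transform",
    "write_transform",
    "read_depth_image",
    "write_depth_image",
]

_MESH_EXT = {".ply", ".stl", ".obj"}
_DEPTH_SCALE = 4.0  # 16-bit PNG stores mm * 4 fixed point


class MeshIOError(ValueError):
    pass


class VolumeIOError(ValueError):
    pass


def read_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXT:
        raise MeshIOError(f"unsupported mesh extension {path.suffix!r}")
    try:
        m = trimesh.load(path, force="mesh", process=False)
    except Exception as exc:
        raise MeshIOError(f"failed to read mesh {path}: {exc}") from exc
    if not isinstance(m, trimesh.Trimesh) or len(m.faces) == 0:
        raise MeshIOError(f"{path} contains no triangles")
    return m


def write_mesh(path, mesh: trimesh.Trimesh) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXT:
        raise MeshIOError(f"unsupported mesh extension {path.suffix!r}")
    mesh.export(path)


def read_pointcloud(path) -> PointCloud:
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        pts = np.loadtxt(path, dtype=np.float64).reshape(-1, 3)
        return PointCloud(pts)
    if path.suffix.lower() != ".ply":
        raise MeshIOError(f"unsupported point-cloud extension {path.suffix!r}")
    obj = trimesh.load(path, process=False)
    pts = np.asarray(obj.vertices, dtype=np.float64)
    if len(pts) == 0:
        raise MeshIOError(f"{path} contains no points")
    return PointCloud(pts)


def write_pointcloud(path, cloud: PointCloud) -> None:
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        np.savetxt(path, cloud.points, fmt="%.6f")
        return
    if path.suffix.lower() != ".ply":
        raise MeshIOError(f"unsupported point-cloud extension {path.suffix!r}")
    trimesh.PointCloud(cloud.points).export(path)


# ---------------------------------------------------------------------------
# NRRD volumes
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Read a 3D scalar NRRD; the affine is rebuilt from the space directions."""
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise VolumeIOError(f"failed to read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeIOError(f"{path} is not a 3D volume")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64)
    D = np.asarray(img.GetDirection(), dtype=np.float64).reshape(3, 3)
    spacing = np.asarray(img.GetSpacing(), dtype=np.float64)
    affine = np.eye(4)
    affine[:3, :3] = D @ np.diag(spacing)
    affine[:3, 3] = np.asarray(img.GetOrigin(), dtype=np.float64)
    return Volume(data, affine)


def write_volume(path, vol: Volume) -> None:
    import SimpleITK as sitk

    path = Path(path)
    if path.suffix.lower() not in (".nrrd", ".nhdr"):
        raise VolumeIOError(f"unsupported volume extension {path.suffix!r}")
    spacing = vol.spacing
    D = vol.affine[:3, :3] / spacing
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in vol.affine[:3, 3]))
    img.SetDirection(tuple(float(x) for x in D.ravel()))
    sitk.WriteImage(img, str(path), useCompression=False)


# ---------------------------------------------------------------------------
# Trajectories & transforms
# ---------------------------------------------------------------------------

def read_trajectories(path) -> list[Trajectory]:
    with open(path) as fh:
        data = json.load(fh)
    items = data if isinstance(data, list) else data.get("trajectories", [])
    out = []
    for it in items:
        out.append(Trajectory(entry=np.asarray(it["entry_mm"], dtype=np.float64),
                              target=np.asarray(it["target_mm"], dtype=np.float64),
                              label=str(it.get("label", ""))))
    return out


def write_trajectories(path, trajectories: list[Trajectory]) -> None:
    data = [
        {"label": t.label, "entry_mm": t.entry.tolist(), "target_mm": t.target.tolist()}
        for t in trajectories
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def read_transform(path) -> RigidTransform:
    with open(path) as fh:
        data = json.load(fh)
    M = data["matrix"] if isinstance(data, dict) else data
    return RigidTransform.from_matrix(np.asarray(M, dtype=np.float64))


def write_transform(path, T: RigidTransform, extra: dict | None = None) -> None:
    data = {"matrix": T.matrix().tolist()}
    if extra:
        data.update(extra)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


# ---------------------------------------------------------------------------
# Depth images
# ---------------------------------------------------------------------------

def write_depth_image(path, depth: np.ndarray) -> None:
    """16-bit PNG at mm x 4 fixed point, or raw float NPY."""
    path = Path(path)
    depth = np.asarray(depth, dtype=np.float64)
    if path.suffix.lower() == ".npy":
        np.save(path, depth)
        return
    if path.suffix.lower() != ".png":
        raise MeshIOError(f"unsupported depth-image extension {path.suffix!r}")
    from PIL import Image

    q = np.clip(np.round(depth * _DEPTH_SCALE), 0, 65535).astype(np.uint16)
    Image.fromarray(q).save(path)


def read_depth_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".npy":
        return np.load(path)
    from PIL import Image

    q = np.asarray(Image.open(path), dtype=np.uint16)
    return q.astype(np.float64) / _DEPTH_SCALE
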