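"""Markerless surface registration: robust global alignment plus ICP refinement.

The pipeline aligns a preoperative skin-surface reference model to a live
depth-sensor point cloud with no initial guess and no markers:

1. voxel downsampling of both clouds,
2. normal estimation from local covariance,
3. 33-bin FPFH descriptors,
4. mutual-nearest-neighbour correspondence matching,
5. a truncated-least-squares global estimator in the TEASER style —
   correspondence outliers are pruned by a maximal clique on the pairwise
   distance-compatibility graph, rotation is solved by graduated
   non-convexity over a truncated-least-squares cost on translation-invariant
   measurement pairs, and translation by per-component adaptive voting,
6. point-to-plane (default) or point-to-point ICP refinement,
7. a numeric success verdict (inlier RMSE and model-overlap thresholds) that
   replaces a human visual check of the overlay.

Scale is fixed at 1 throughout: same-patient rigid anatomy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .depthsim import sample_surface
from .geometry import PointCloud, RigidTransform

__all__ = [
    "FeatureSet",
    "CorrespondenceSet",
    "RegistrationResult",
    "RegistrationError",
    "PipelineConfig",
    "ICPParams",
    "downsample_voxel",
    "estimate_normals",
    "compute_fpfh",
    "match_correspondences",
    "global_register",
    "refine_icp",
    "register_pipeline",
]


class RegistrationError(RuntimeError):
    pass


@dataclass
class FeatureSet:
    """Keypoints with one fixed-length FPFH descriptor each."""

    keypoints: PointCloud
    descriptors: np.ndarray  # (n, 33), nonnegative
    valid: np.ndarray | None = None  # False where the descriptor is degenerate

    def __post_init__(self):
        self.descriptors = np.asarray(self.descriptors, dtype=np.float64)
        if self.descriptors.shape != (len(self.keypoints), 33):
            raise ValueError("descriptors must be (n_keypoints, 33)")
        if self.valid is None:
            self.valid = np.ones(len(self.keypoints), dtype=bool)


@dataclass
class CorrespondenceSet:
    """Index pairs between a source and a target keypoint cloud."""

    pairs: np.ndarray  # (m, 2) int
    source: PointCloud
    target: PointCloud

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if len(self.pairs) and (
            self.pairs[:, 0].max() >= len(self.source)
            or self.pairs[:, 1].max() >= len(self.target)
        ):
            raise ValueError("correspondence index out of range")
        if len(np.unique(self.pairs, axis=0)) != len(self.pairs):
            raise ValueError("duplicate correspondence pairs")

    @property
    def src_points(self) -> np.ndarray:
        return self.source.points[self.pairs[:, 0]]

    @property
    def dst_points(self) -> np.ndarray:
        return self.target.points[self.pairs[:, 1]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RegistrationResult:
    """Estimated transform plus residual diagnostics and a success verdict."""

    transform: RigidTransform
    inlier_count: int = 0
    inlier_rmse_mm: float = float("nan")
    overlap_fraction: float = float("nan")
    success: bool = False
    stage: str = "global"  # "global" | "refined"
    reason: str = ""
    rmse_history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def downsample_voxel(cloud: PointCloud, s_mm: float) -> PointCloud:
    """At most one point (the centroid) per occupied voxel of edge ``s_mm``.

    Output order is lexicographic in voxel index, so the result is
    deterministic regardless of input ordering.
    """
    if len(cloud) == 0:
        raise RegistrationError("cannot downsample an empty cloud")
    if s_mm <= 0:
        raise ValueError("voxel size must be positive")
    keys = np.floor(cloud.points / s_mm).astype(np.int64)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    pts = np.zeros((len(uniq), 3))
    np.add.at(pts, inv, cloud.points)
    counts = np.bincount(inv, minlength=len(uniq)).astype(np.float64)
    pts /= counts[:, None]
    normals = None
    if cloud.normals is not None:
        normals = np.zeros((len(uniq), 3))
        np.add.at(normals, inv, cloud.normals)
        n = np.linalg.norm(normals, axis=1)
        normals = normals / np.where(n > 1e-12, n, 1.0)[:, None]
    return PointCloud(pts, normals, view_origin=cloud.view_origin)


def estimate_normals(cloud: PointCloud, k_neighbors: int = 30,
                     viewpoint=None) -> PointCloud:
    """Unit normals from the smallest local-covariance eigenvector.

    Normals are oriented toward ``viewpoint`` (defaults to the cloud's
    ``view_origin``; failing that, away from the centroid).  Degenerate
    neighbourhoods (near-zero covariance spread) get NaN normals.
    """
    pts = cloud.points
    if len(pts) < k_neighbors:
        raise RegistrationError(f"need >= {k_neighbors} points for normal estimation")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k_neighbors)
    nbr = pts[idx]  # (n, k, 3)
    mu = nbr.mean(axis=1, keepdims=True)
    d = nbr - mu
    cov = np.einsum("nki,nkj->nij", d, d) / k_neighbors
    w, v = np.linalg.eigh(cov)
    normals = v[:, :, 0]  # eigenvector of the smallest eigenvalue
    degenerate = w[:, 1] < 1e-12  # rank < 2 neighbourhood
    if viewpoint is not None:
        ref = np.asarray(viewpoint, dtype=np.float64) - pts
    elif cloud.view_origin is not None:
        ref = cloud.view_origin - pts
    else:
        ref = pts - pts.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, ref) < 0
    normals[flip] *= -1
    normals[degenerate] = np.nan
    return PointCloud(pts, normals, view_origin=cloud.view_origin)


# ---------------------------------------------------------------------------
# FPFH descriptors
# ---------------------------------------------------------------------------

def _pair_features(p, np_, q, nq):
    """(alpha, phi, theta) Darboux-frame angles for point pairs, PCL ordering."""
    d = q - p
    dist = np.linalg.norm(d, axis=1)
    dist = np.where(dist > 1e-12, dist, 1.0)
    dhat = d / dist[:, None]
    # choose the source point as the one whose normal is less aligned with d
    a1 = np.einsum("ij,ij->i", np_, dhat)
    a2 = np.einsum("ij,ij->i", nq, -dhat)
    swap = np.abs(a1) < np.abs(a2)
    ps, ns = np.where(swap[:, None], q, p), np.where(swap[:, None], nq, np_)
    nt = np.where(swap[:, None], np_, nq)
    dhat = np.where(swap[:, None], -dhat, dhat)
    u = ns
    v = np.cross(dhat, u)
    vn = np.linalg.norm(v, axis=1)
    v = v / np.where(vn > 1e-12, vn, 1.0)[:, None]
    w = np.cross(u, v)
    alpha = np.einsum("ij,ij->i", v, nt)
    phi = np.einsum("ij,ij->i", u, dhat)
    theta = np.arctan2(np.einsum("ij,ij->i", w, nt), np.einsum("ij,ij->i", u, nt))
    return alpha, phi, theta


def _bin_triplet(alpha, phi, theta, nbins: int = 11) -> np.ndarray:
    h = np.zeros(3 * nbins)
    for off, vals, lo, hi in (
        (0, alpha, -1.0, 1.0),
        (nbins, phi, -1.0, 1.0),
        (2 * nbins, theta, -np.pi, np.pi),
    ):
        b = np.clip(((vals - lo) / (hi - lo) * nbins).astype(int), 0, nbins - 1)
        h[off:off + nbins] += np.bincount(b, minlength=nbins)
    return h


def compute_fpfh(cloud: PointCloud, radius_mm: float = 10.0) -> FeatureSet:
    """Fast point feature histograms (33 bins) for every point.

    SPFH histograms of the (alpha, phi, theta) angle triplets are accumulated
    per point over radius neighbours, then blended with inverse-distance
    weights into the final FPFH.  Each 11-bin block is normalised to sum 100.
    Isolated points (or points with invalid normals) get a zero histogram and
    are flagged invalid.
    """
    if cloud.normals is None:
        raise RegistrationError("FPFH needs normals; run estimate_normals first")
    pts, nrm = cloud.points, cloud.normals
    n = len(pts)
    finite = np.all(np.isfinite(nrm), axis=1)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_tree(tree, r=radius_mm)
    spfh = np.zeros((n, 33))
    nbr_lists: list[np.ndarray] = []
    for i in range(n):
        ids = np.array([j for j in neighbors[i] if j != i and finite[j]], dtype=np.int64)
        nbr_lists.append(ids)
        if not finite[i] or len(ids) == 0:
            continue
        a, f, t = _pair_features(
            np.broadcast_to(pts[i], (len(ids), 3)),
            np.broadcast_to(nrm[i], (len(ids), 3)),
            pts[ids], nrm[ids],
        )
        spfh[i] = _bin_triplet(a, f, t)

    fpfh = np.zeros((n, 33))
    valid = finite.copy()
    for i in range(n):
        ids = nbr_lists[i]
        if not finite[i] or len(ids) == 0:
            valid[i] = False
            continue
        d = np.linalg.norm(pts[ids] - pts[i], axis=1)
        wsum = (spfh[ids] / np.where(d > 1e-12, d, 1e-12)[:, None]).sum(axis=0)
        fpfh[i] = spfh[i] + wsum / len(ids)

    # normalise each 11-bin block to percentage mass
    for off in (0, 11, 22):
        block = fpfh[:, off:off + 11]
        s = block.sum(axis=1, keepdims=True)
        np.divide(block, s, out=block, where=s > 0)
        fpfh[:, off:off + 11] = block * 100.0
    return FeatureSet(cloud, fpfh, valid)


def match_correspondences(src: FeatureSet, dst: FeatureSet,
                          mutual: bool = True,
                          max_pairs: int | None = None) -> CorrespondenceSet:
    """Nearest-neighbour descriptor matching (mutual by default).

    Nearest-neighbour ties resolve to the lowest index.  With ``max_pairs``
    only the matches with the smallest descriptor distances are kept.
    """
    si = np.nonzero(src.valid)[0]
    di = np.nonzero(dst.valid)[0]
    if len(si) == 0 or len(di) == 0:
        raise RegistrationError("no valid descriptors to match")
    tree_d = cKDTree(dst.descriptors[di])
    dist_sd, nn_sd = tree_d.query(src.descriptors[si])
    if mutual:
        tree_s = cKDTree(src.descriptors[si])
        _, nn_ds = tree_s.query(dst.descriptors[di])
        keep = nn_ds[nn_sd] == np.arange(len(si))
    else:
        keep = np.ones(len(si), dtype=bool)
    pairs = np.column_stack([si[keep], di[nn_sd[keep]]])
    dists = dist_sd[keep]
    if len(pairs) == 0:
        raise RegistrationError("zero feature correspondences")
    if max_pairs is not None and len(pairs) > max_pairs:
        order = np.argsort(dists, kind="stable")[:max_pairs]
        pairs = pairs[np.sort(order)]
    return CorrespondenceSet(pairs, src.keypoints, dst.keypoints)


# ---------------------------------------------------------------------------
# Robust global estimator
# ---------------------------------------------------------------------------

def _weighted_rotation(A: np.ndarray, B: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rotation minimising sum w ||B - R A||^2 (no centroiding; closed form)."""
    H = (A * w[:, None]).T @ B
    U, _, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    if np.linalg.det(R) < 0:
        R = Vt.T @ np.diag([1.0, 1.0, -1.0]) @ U.T
    return R


def _gnc_tls_rotation(A: np.ndarray, B: np.ndarray, c_bar: float,
                      mu_factor: float = 1.4, max_outer: int = 100) -> np.ndarray:
    """GNC over a truncated-least-squares rotation cost on measurement pairs.

    The surrogate's control parameter starts near-convex (set from the
    largest initial residual) and is annealed by ``mu_factor`` per outer
    iteration until the inlier weights binarize.
    """
    w = np.ones(len(A))
    R = _weighted_rotation(A, B, w)
    res2 = np.einsum("ij,ij->i", B - A @ R.T, B - A @ R.T)
    r2max = res2.max()
    c2 = c_bar * c_bar
    if r2max <= c2:  # every residual already within the truncation bound
        return R
    mu = max(c2 / (2.0 * r2max - c2), 1e-8)
    for _ in range(max_outer):
        th1 = (mu / (mu + 1.0)) * c2
        th2 = ((mu + 1.0) / mu) * c2
        w = np.where(
            res2 <= th1, 1.0,
            np.where(res2 >= th2, 0.0, np.sqrt(c2 * mu * (mu + 1.0) / res2) - mu),
        )
        w = np.clip(w, 0.0, 1.0)
        if w.sum() < 1e-9:  # degenerate: everything truncated
            break
        R = _weighted_rotation(A, B, w)
        res2 = np.einsum("ij,ij->i", B - A @ R.T, B - A @ R.T)
        binary = np.all((w < 1e-3) | (w > 1 - 1e-3))
        mu *= mu_factor
        if binary and mu > 1e6:
            break
    return R


def _tls_translation_1d(vals: np.ndarray, beta: float) -> float:
    """Component-wise truncated-least-squares translation by adaptive voting:
    the mean of the largest consensus set among intervals [v - beta, v + beta].
    """
    order = np.argsort(vals, kind="stable")
    v = vals[order]
    # for each candidate interval centre, count members within +-beta
    left = np.searchsorted(v, v - beta, side="left")
    right = np.searchsorted(v, v + beta, side="right")
    counts = right - left
    best = int(np.argmax(counts))
    return float(v[left[best]:right[best]].mean())


def global_register(corr: CorrespondenceSet, noise_bound_mm: float,
                    max_exact_clique_nodes: int = 2000,
                    max_tims: int = 2000) -> RegistrationResult:
    """TEASER-style robust global registration from putative correspondences.

    Steps: (1) prune outliers by the maximum clique of the distance-
    compatibility graph (edge iff the source and target pairwise distances
    agree within ``2 * noise_bound_mm``); (2) solve rotation by GNC-TLS on
    translation-invariant measurement pairs; (3) solve translation per
    component by TLS adaptive voting.  Scale is fixed at 1.
    """
    if len(corr) < 3:
        raise RegistrationError(f"need >= 3 correspondences, got {len(corr)}")
    S = corr.src_points
    D = corr.dst_points
    n = len(corr)

    ds = np.linalg.norm(S[:, None, :] - S[None, :, :], axis=2)
    dd = np.linalg.norm(D[:, None, :] - D[None, :, :], axis=2)
    compat = np.abs(ds - dd) <= 2.0 * noise_bound_mm
    np.fill_diagonal(compat, False)

    clique = sorted(_max_clique(compat, exact=n <= max_exact_clique_nodes))
    if len(clique) < 3:
        raise RegistrationError(f"inlier clique too small ({len(clique)})")

    idx = np.asarray(clique)
    Sc, Dc = S[idx], D[idx]

    # translation-invariant measurement pairs (TIMs) within the clique
    pairs = list(itertools.combinations(range(len(idx)), 2))
    if len(pairs) > max_tims:
        pairs = pairs[:max_tims]
    pi = np.asarray(pairs)
    A = Sc[pi[:, 0]] - Sc[pi[:, 1]]
    B = Dc[pi[:, 0]] - Dc[pi[:, 1]]
    R = _gnc_tls_rotation(A, B, c_bar=2.0 * noise_bound_mm)

    t_comp = Dc - Sc @ R.T
    t = np.array([_tls_translation_1d(t_comp[:, k], noise_bound_mm) for k in range(3)])
    T = RigidTransform(R, t)

    res = np.linalg.norm(D - (S @ R.T + t), axis=1)
    inl = res <= noise_bound_mm
    rmse = float(np.sqrt(np.mean(res[inl] ** 2))) if inl.any() else float("nan")
    return RegistrationResult(
        transform=T, inlier_count=int(inl.sum()), inlier_rmse_mm=rmse,
        overlap_fraction=float(inl.mean()), success=True, stage="global",
    )


class _SearchBudget(Exception):
    pass


def _greedy_clique(adj: np.ndarray, seed_node: int) -> np.ndarray:
    """Grow a clique from one node, always adding the candidate with the
    largest degree inside the remaining candidate set."""
    clique = [seed_node]
    cand = adj[seed_node].copy()
    while cand.any():
        sub_deg = adj[:, cand].sum(axis=1)
        sub_deg[~cand] = -1
        v = int(np.argmax(sub_deg))
        clique.append(v)
        cand &= adj[v]
    return np.asarray(clique)


def _color_sort(adj: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy sequential coloring of the candidate subgraph; returns the
    candidates ordered by ascending color and their color numbers (the
    classic branch-and-bound pruning bound)."""
    sub = adj[np.ix_(P, P)]
    n = len(P)
    uncol = np.ones(n, dtype=bool)
    order = np.empty(n, dtype=np.int64)
    colors = np.empty(n, dtype=np.int64)
    pos = 0
    color = 0
    while pos < n:
        color += 1
        avail = uncol.copy()
        while True:
            i = int(np.argmax(avail))
            if not avail[i]:
                break
            order[pos] = P[i]
            colors[pos] = color
            pos += 1
            uncol[i] = False
            avail &= ~sub[i]
            avail[i] = False
    return order, colors


def _max_clique(adj: np.ndarray, exact: bool = True,
                budget: int = 500_000, large_enough: int = 60) -> np.ndarray:
    """Maximum clique of an undirected graph given as a boolean adjacency
    matrix.

    Branch and bound with a greedy-coloring bound after a multi-start greedy
    lower bound and k-core reduction.  The search is capped at ``budget``
    units of coloring work (and skipped entirely when ``exact`` is false);
    past the cap the best clique found so far is returned, which keeps
    worst-case runtime bounded on pathologically dense compatibility graphs.
    """
    n = len(adj)
    deg = adj.sum(axis=1)
    starts = np.argsort(deg)[::-1][:20]
    best = np.asarray([int(np.argmax(deg))])
    for s in starts:
        c = _greedy_clique(adj, int(s))
        if len(c) > len(best):
            best = c
    if not exact or len(best) >= large_enough:
        # a consensus set this large already pins the transform; the robust
        # rotation/translation stages tolerate the residual outliers
        return best

    # k-core reduction: a clique larger than |best| only uses nodes of
    # degree >= |best|
    keep = np.ones(n, dtype=bool)
    changed = True
    while changed:
        d = (adj & keep[None, :]).sum(axis=1)
        drop = keep & (d < len(best))
        changed = bool(drop.any())
        keep &= ~drop
    nodes = np.nonzero(keep)[0]
    if len(nodes) <= len(best):
        return best

    state = {"best": best, "count": 0}

    def expand(R: list[int], P: np.ndarray) -> None:
        state["count"] += len(P)
        if state["count"] > budget:
            raise _SearchBudget
        order, colors = _color_sort(adj, P)
        for i in range(len(order) - 1, -1, -1):
            if len(R) + colors[i] <= len(state["best"]):
                return
            v = int(order[i])
            R.append(v)
            P2 = order[:i][adj[v][order[:i]]]
            if len(P2):
                expand(R, P2)
            elif len(R) > len(state["best"]):
                state["best"] = np.asarray(R)
            R.pop()

    try:
        expand([], nodes)
    except _SearchBudget:
        pass
    return state["best"]


# ---------------------------------------------------------------------------
# ICP refinement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICPParams:
    d_max_mm: float = 10.0
    tol: float = 1e-6
    max_iter: int = 50
    method: str = "point_to_plane"  # or "point_to_point"


def _horn(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid alignment P -> Q (centroided SVD)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    if np.linalg.det(R) < 0:
        R = Vt.T @ np.diag([1.0, 1.0, -1.0]) @ U.T
    return RigidTransform(R, cq - R @ cp)


def _point_to_plane_step(P: np.ndarray, Q: np.ndarray, Nq: np.ndarray) -> RigidTransform:
    """Small-angle linearised solve of sum (n . (R p + t - q))^2."""
    c = np.cross(P, Nq)
    J = np.hstack([c, Nq])  # (m, 6)
    r = np.einsum("ij,ij->i", Q - P, Nq)
    x, *_ = np.linalg.lstsq(J, r, rcond=None)
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(x[:3]).as_matrix()
    return RigidTransform(R, x[3:])


def refine_icp(model: PointCloud, scene: PointCloud, init: RigidTransform,
               params: ICPParams = ICPParams()) -> RegistrationResult:
    """Iterative closest point from an initial transform.

    Each iteration matches every transformed model point to its nearest scene
    point within ``d_max_mm`` (ties break to the lowest scene index), then
    solves the least-squares update — point-to-plane by default (scene
    normals are estimated if missing), or point-to-point.  The recorded RMSE
    sequence is evaluated at the correspondence stage of each iteration; for
    point-to-point it is non-increasing.  A starting position with no
    correspondences in range yields a failure result, not an exception.
    """
    if len(model) == 0 or len(scene) == 0:
        raise RegistrationError("empty cloud passed to ICP")
    scene_pts = scene.points
    tree = cKDTree(scene_pts)
    scene_normals = scene.normals
    if params.method == "point_to_plane" and (
        scene_normals is None or not np.all(np.isfinite(scene_normals))
    ):
        k = min(30, len(scene_pts))
        est = estimate_normals(scene, k_neighbors=k)
        scene_normals = np.where(np.isfinite(est.normals), est.normals, 0.0)

    T = init
    history: list[float] = []
    prev = None
    for _ in range(params.max_iter):
        P = T.apply(model.points)
        dist, nn = tree.query(P, distance_upper_bound=params.d_max_mm)
        ok = np.isfinite(dist)
        if not ok.any():
            return RegistrationResult(
                transform=T, success=False, stage="refined",
                reason="no_correspondences", rmse_history=history,
            )
        rmse = float(np.sqrt(np.mean(dist[ok] ** 2)))
        history.append(rmse)
        if prev is not None and abs(prev - rmse) <= params.tol * max(prev, rmse, 1e-6):
            break
        prev = rmse
        Pm, Qm = P[ok], scene_pts[nn[ok]]
        if params.method == "point_to_point":
            dT = _horn(Pm, Qm)
        elif params.method == "point_to_plane":
            dT = _point_to_plane_step(Pm, Qm, scene_normals[nn[ok]])
        else:
            raise ValueError(f"unknown ICP method {params.method!r}")
        T = dT.compose(T)

    P = T.apply(model.points)
    dist, _ = tree.query(P, distance_upper_bound=params.d_max_mm)
    ok = np.isfinite(dist)
    rmse = float(np.sqrt(np.mean(dist[ok] ** 2))) if ok.any() else float("nan")
    return RegistrationResult(
        transform=T, inlier_count=int(ok.sum()), inlier_rmse_mm=rmse,
        overlap_fraction=float(ok.mean()), success=True, stage="refined",
        rmse_history=history,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end registration parameters (defaults sized for ~200 mm heads)."""

    model_samples: int = 8000
    coarse_voxel_mm: float = 4.0
    fine_voxel_mm: float = 2.0
    normal_k: int = 30
    fpfh_radius_mm: float = 20.0
    max_correspondences: int = 1200
    noise_bound_mm: float = 4.0
    icp: ICPParams = ICPParams()
    rmse_max_mm: float = 3.0
    min_overlap_fraction: float = 0.3
    seed: int = 0


def register_pipeline(reference: trimesh.Trimesh, scene: PointCloud,
                      config: PipelineConfig = PipelineConfig()) -> RegistrationResult:
    """Fully automatic alignment of a reference surface mesh to a live cloud.

    Success requires final inlier RMSE <= ``rmse_max_mm`` *and* model overlap
    >= ``min_overlap_fraction`` — the numeric stand-in for visually checking
    the virtual overlay against the real surface.  Upstream failures (no
    features, clique too small, ICP divergence) are reported as
    ``success=False`` with a reason code rather than raised.
    """
    rng = np.random.default_rng(config.seed)
    try:
        mpts, mnrm = sample_surface(reference, config.model_samples, rng)
        model_full = PointCloud(mpts, mnrm)
        if len(scene) == 0:
            raise RegistrationError("empty scene cloud")
        model_coarse = downsample_voxel(model_full, config.coarse_voxel_mm)
        scene_coarse = downsample_voxel(scene, config.coarse_voxel_mm)
        if len(scene_coarse) < config.normal_k or len(model_coarse) < config.normal_k:
            raise RegistrationError("too few points after downsampling")

        mc = estimate_normals(model_coarse, config.normal_k)
        # re-orient covariance normals with the carried outward face normals
        flip = np.einsum("ij,ij->i", np.where(np.isfinite(mc.normals), mc.normals, 0.0),
                         model_coarse.normals) < 0
        mc.normals[flip] *= -1
        sc = estimate_normals(scene_coarse, min(config.normal_k, len(scene_coarse)))

        f_model = compute_fpfh(mc, config.fpfh_radius_mm)
        f_scene = compute_fpfh(sc, config.fpfh_radius_mm)
        corr = match_correspondences(f_model, f_scene,
                                     max_pairs=config.max_correspondences)
        g = global_register(corr, config.noise_bound_mm)

        model_fine = downsample_voxel(model_full, config.fine_voxel_mm)
        scene_fine = estimate_normals(
            downsample_voxel(scene, config.fine_voxel_mm),
            min(config.normal_k, max(3, len(scene) - 1)),
        )
        r = refine_icp(model_fine, scene_fine, g.transform, config.icp)
        if not r.success:
            return r
        success = (r.inlier_rmse_mm <= config.rmse_max_mm
                   and r.overlap_fraction >= config.min_overlap_fraction)
        return replace(
            r, success=success,
            reason="" if success else "verdict_thresholds",
        )
    except RegistrationError as exc:
        return RegistrationResult(
            transform=RigidTransform.identity(), success=False,
            stage="global", reason=str(exc),
        )
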