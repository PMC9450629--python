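"""Canal segmentation and ordered centerline extraction.

Pipeline: threshold the volume, thin the binary canal to a 3D skeleton, prune
short spurs, build a 26-connected graph with Euclidean edge weights in world
mm, and return the minimal-cost path between the skeleton voxels nearest the
user-supplied vestibule and apex seed points — vestibule first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .errors import ConnectivityError, SeedError, SegmentationError
from .phantom import CenterlineCurve, Volume

__all__ = [
    "CanalMask",
    "SeedPair",
    "segment_canal",
    "extract_path",
    "resample_curve",
    "project_to_plane",
]


@dataclass
class CanalMask:
    """Binary canal mask sharing its source volume's grid geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)


@dataclass(frozen=True)
class SeedPair:
    """Vestibule-side and apex-side seed points in world mm."""

    vestibule_point: tuple[float, float, float]
    apex_point: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.vestibule_point, dtype=float)
        a = np.asarray(self.apex_point, dtype=float)
        if v.shape != (3,) or a.shape != (3,):
            raise ValueError("seed points must be 3-vectors")
        if np.allclose(v, a):
            raise ValueError("vestibule and apex seeds must be distinct")


def segment_canal(volume: Volume, threshold: float | str = "auto") -> CanalMask:
    """Threshold a volume into a canal mask.

    ``threshold="auto"`` picks the value by Otsu's bimodal-histogram
    criterion; otherwise voxels with intensity >= threshold are foreground.

    Raises
    ------
    SegmentationError
        If the resulting foreground is empty (carries the threshold used).
    """
    data = np.asarray(volume.data)
    if data.size == 0:
        raise ValueError("volume is empty")
    if threshold == "auto":
        thr = float(threshold_otsu(data))
    else:
        thr = float(threshold)
    fg = data >= thr
    if not fg.any():
        raise SegmentationError(thr)
    return CanalMask(data=fg, spacing=volume.spacing, origin=volume.origin)


# 13 positive half-space offsets covering 26-connectivity once per pair
_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
)


def _skeleton_graph(skel: np.ndarray, spacing: np.ndarray):
    """Sparse 26-connected graph over skeleton voxels, mm edge weights."""
    coords = np.argwhere(skel)
    ids = -np.ones(skel.shape, dtype=np.int64)
    ids[tuple(coords.T)] = np.arange(len(coords))
    rows, cols, weights = [], [], []
    shape = np.array(skel.shape)
    for off in _OFFSETS:
        nbr = coords + off
        ok = np.all((nbr >= 0) & (nbr < shape), axis=1)
        nbr_ids = ids[tuple(nbr[ok].T)]
        valid = nbr_ids >= 0
        src = np.arange(len(coords))[ok][valid]
        dst = nbr_ids[valid]
        w = float(np.linalg.norm(off * spacing))
        rows.append(src)
        cols.append(dst)
        weights.append(np.full(len(src), w))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    n = len(coords)
    graph = sparse.csr_matrix(
        (np.concatenate([weights, weights]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    )
    return coords, graph


def _prune_spurs(skel: np.ndarray, min_len: int) -> np.ndarray:
    """Remove endpoint branches shorter than ``min_len`` voxels."""
    if min_len <= 0:
        return skel
    skel = skel.copy()
    kernel = np.ones((3, 3, 3), dtype=np.uint8)
    kernel[1, 1, 1] = 0
    for _ in range(3):  # a few passes handle nested spurs
        nbrs = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")
        degree = np.where(skel, nbrs, 0)
        removed_any = False
        for tip in map(tuple, np.argwhere((degree == 1))):
            branch = [tip]
            prev = None
            cur = tip
            while len(branch) <= min_len:
                lo = np.maximum(np.array(cur) - 1, 0)
                hi = np.minimum(np.array(cur) + 2, skel.shape)
                nb = [
                    (i, j, k)
                    for i in range(lo[0], hi[0])
                    for j in range(lo[1], hi[1])
                    for k in range(lo[2], hi[2])
                    if skel[i, j, k] and (i, j, k) != cur and (i, j, k) != prev
                ]
                if len(nb) != 1:
                    # junction (or dead end): prune only if we hit a junction
                    if len(nb) > 1 and len(branch) < min_len:
                        for vox in branch:
                            skel[vox] = False
                        removed_any = True
                    break
                prev, cur = cur, nb[0]
                branch.append(cur)
        if not removed_any:
            break
    return skel


def _moving_average(points: np.ndarray, window: int, passes: int = 1) -> np.ndarray:
    """Endpoint-preserving moving average along the point sequence."""
    if window < 3 or len(points) < window:
        return points
    out = points
    half = window // 2
    for _ in range(passes):
        padded = np.concatenate(
            [np.repeat(out[:1], half, axis=0), out, np.repeat(out[-1:], half, axis=0)]
        )
        kernel = np.ones(window) / window
        sm = np.column_stack(
            [np.convolve(padded[:, k], kernel, mode="valid") for k in range(3)]
        )
        sm[0], sm[-1] = out[0], out[-1]
        out = sm
    return out


def extract_path(
    mask: CanalMask,
    seeds: SeedPair,
    *,
    snap_radius: float = 2.0,
    prune_len: int = 5,
    smooth_window: int = 3,
    smooth_passes: int = 2,
    include_seeds: bool = True,
) -> CenterlineCurve:
    """Extract the vestibule-to-apex centerline from a canal mask.

    Skeletonizes by 3D thinning, prunes spurs shorter than ``prune_len``
    voxels, finds the minimal-cost 26-connected path between the skeleton
    voxels nearest each seed (snapped within ``snap_radius`` mm), converts to
    world coordinates and lightly smooths.  ``include_seeds`` appends the
    exact seed points at the ends so the measurement truly starts at the
    vestibule point and ends at the apex point.

    Raises
    ------
    SeedError
        If a seed is farther than ``snap_radius`` from any skeleton voxel.
    ConnectivityError
        If the two snapped seeds lie in disconnected skeleton components.
    """
    if not mask.data.any():
        raise ValueError("mask has empty foreground")
    spacing = np.array(mask.spacing)
    origin = np.array(mask.origin)

    skel = skeletonize(mask.data)
    skel = _prune_spurs(skel, prune_len)
    if not skel.any():
        raise ValueError("skeletonization produced an empty skeleton")

    coords, graph = _skeleton_graph(skel, spacing)
    world = coords * spacing + origin
    tree = cKDTree(world)

    snapped = []
    for name, pt in (
        ("vestibule", seeds.vestibule_point),
        ("apex", seeds.apex_point),
    ):
        dist, idx = tree.query(np.asarray(pt, dtype=float))
        if dist > snap_radius:
            raise SeedError(
                f"{name} seed is {dist:.2f} mm from the nearest skeleton voxel "
                f"(snap radius {snap_radius} mm)"
            )
        snapped.append(int(idx))
    src, dst = snapped

    dist_matrix, predecessors = dijkstra(
        graph, directed=False, indices=src, return_predecessors=True
    )
    if not np.isfinite(dist_matrix[dst]):
        raise ConnectivityError(
            "vestibule and apex seeds lie in disconnected skeleton components"
        )
    path = [dst]
    while path[-1] != src:
        path.append(int(predecessors[path[-1]]))
    path.reverse()

    pts = world[path]
    pts = _moving_average(pts, smooth_window, smooth_passes)
    if include_seeds:
        v = np.asarray(seeds.vestibule_point, dtype=float)
        a = np.asarray(seeds.apex_point, dtype=float)
        if np.linalg.norm(pts[0] - v) > 1e-9:
            pts = np.vstack([v, pts])
        if np.linalg.norm(pts[-1] - a) > 1e-9:
            pts = np.vstack([pts, a])
    # drop accidental duplicate consecutive points after smoothing
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12]
    )
    return CenterlineCurve(pts[keep])


def resample_curve(curve: CenterlineCurve, step: float) -> CenterlineCurve:
    """Resample at uniform arc spacing <= step; endpoints preserved exactly."""
    if step <= 0:
        raise ValueError("step must be > 0")
    total = curve.total_length
    n_seg = max(1, int(np.ceil(total / step - 1e-12)))
    arcs = np.linspace(0.0, total, n_seg + 1)
    pts = curve.point_at(arcs)
    pts[0] = curve.points[0]
    pts[-1] = curve.points[-1]
    return CenterlineCurve(pts)


def project_to_plane(
    curve: CenterlineCurve, normal: np.ndarray | None = None
) -> CenterlineCurve:
    """Project the curve onto a plane (best-fit by default).

    Emulates measuring on a 2D projection of the 3D reconstruction.  With
    ``normal=None`` the plane is the least-squares best fit through the
    points (smallest singular vector of the centered point cloud).
    """
    pts = curve.points
    centroid = pts.mean(axis=0)
    if normal is None:
        _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
        normal = vt[-1]
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    offsets = (pts - centroid) @ normal
    projected = pts - offsets[:, None] * normal
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(projected, axis=0), axis=1) > 1e-12]
    )
    return CenterlineCurve(projected[keep])
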