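"""Synthetic cochlear-spiral phantoms with analytically known arc length.

The phantom is an exponentially tapering helico-spiral

    C(theta) = (r(theta) cos(theta), r(theta) sin(theta), h * theta / theta_end)
    r(theta) = basal_radius * exp(-taper_rate * theta),   theta in [0, theta_end]

with theta_end = 2*pi*turns and h the total axial rise.  The canal is a tube
around this centerline whose radius tapers linearly in theta from
``canal_radius_basal`` to ``canal_radius_apical``.  Because the curve is given
in closed form, its true arc length is available by adaptive quadrature of
``||C'(theta)||`` — the ground truth that cadaver imaging cannot provide.

World coordinates are in millimetres, right-handed; voxel indices are 0-based
and map to world space as ``origin + index * spacing``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import integrate, ndimage
from scipy.spatial import cKDTree

__all__ = [
    "PhantomSpec",
    "CenterlineCurve",
    "Volume",
    "COCHLEA25",
    "generate_centerline",
    "arc_length",
    "true_arc_length",
    "rasterize_canal",
    "load_volume",
    "save_volume",
    "read_centerline_csv",
    "write_centerline_csv",
    "write_truth_json",
]

# Default taper: apical spiral radius = basal/4 after 2.5 turns.
_DEFAULT_TAPER = math.log(4.0) / (2.0 * math.pi * 2.5)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric definition of a helico-spiral canal phantom.

    Defaults give a cochlea-like shape: basal spiral radius 4 mm tapering to
    1 mm over 2.5 turns, 5 mm axial rise, true arc length ~34.5 mm.  The
    axial pitch keeps adjacent turns separated by more than one voxel at the
    coarsest supported spacing (0.4 mm) so the rasterized canal stays
    resolvable.
    """

    basal_radius: float = 4.0
    taper_rate: float = _DEFAULT_TAPER
    turns: float = 2.5
    height_rise: float = 5.0
    canal_radius_basal: float = 0.8
    canal_radius_apical: float = 0.45
    voxel_spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)
    volume_margin: float = 1.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = (
            self.basal_radius,
            self.taper_rate,
            self.turns,
            self.height_rise,
            self.canal_radius_basal,
            self.canal_radius_apical,
            *self.voxel_spacing,
            self.volume_margin,
            self.blur_sigma,
            self.noise_sd,
        )
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("PhantomSpec fields must be finite")
        if self.basal_radius <= 0:
            raise ValueError("basal_radius must be > 0")
        if self.turns <= 0:
            raise ValueError("turns must be > 0")
        if not (self.canal_radius_basal >= self.canal_radius_apical > 0):
            raise ValueError(
                "require canal_radius_basal >= canal_radius_apical > 0"
            )
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive values")
        if self.taper_rate < 0:
            raise ValueError("taper_rate must be >= 0")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be >= 0")

    @property
    def theta_end(self) -> float:
        return 2.0 * math.pi * self.turns

    def spiral_radius(self, theta):
        return self.basal_radius * np.exp(-self.taper_rate * np.asarray(theta))

    def canal_radius(self, theta):
        """Tube radius, linear in theta from basal to apical value."""
        t = np.asarray(theta) / self.theta_end
        return self.canal_radius_basal + t * (
            self.canal_radius_apical - self.canal_radius_basal
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_spacing"] = list(self.voxel_spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["voxel_spacing"] = tuple(d["voxel_spacing"])
        return cls(**d)


#: Default cochlea-like preset (2.5 turns, ~34 mm true arc length).
COCHLEA25 = PhantomSpec()


class CenterlineCurve:
    """Ordered 3D polyline in world mm, vestibule-first.

    Parameters
    ----------
    points : (n, 3) array_like
        Ordered world coordinates; consecutive points must be distinct.

    Attributes
    ----------
    points : (n, 3) ndarray
    cumulative_arc : (n,) ndarray
        Cumulative polyline arc length; ``cumulative_arc[0] == 0``.
    """

    def __init__(self, points):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if pts.shape[0] < 2:
            raise ValueError("a centerline needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive points must be distinct")
        self.points = pts
        self.cumulative_arc = np.concatenate(([0.0], np.cumsum(steps)))

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def total_length(self) -> float:
        """Total polyline arc length in mm."""
        return float(self.cumulative_arc[-1])

    def point_at(self, arc):
        """Linearly interpolated point(s) at arc-length position(s) ``arc``."""
        s = np.asarray(arc, dtype=float)
        if np.any(s < -1e-12) or np.any(s > self.total_length + 1e-12):
            raise ValueError("arc position out of range")
        coords = [np.interp(s, self.cumulative_arc, self.points[:, k]) for k in range(3)]
        return np.stack(coords, axis=-1)

    def reversed(self) -> "CenterlineCurve":
        return CenterlineCurve(self.points[::-1])


def generate_centerline(spec: PhantomSpec, n_samples: int) -> CenterlineCurve:
    """Sample the helico-spiral at ``n_samples`` uniform theta values.

    The first point is the basal (vestibule-side) end.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    theta = np.linspace(0.0, spec.theta_end, n_samples)
    r = spec.spiral_radius(theta)
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    z = spec.height_rise * theta / spec.theta_end
    return CenterlineCurve(np.column_stack([x, y, z]))


def arc_length(curve: CenterlineCurve, from_arc: float, to_arc: float) -> float:
    """Arc length between two positions on the polyline."""
    total = curve.total_length
    if not (0.0 <= from_arc <= to_arc <= total + 1e-12):
        raise ValueError(
            f"require 0 <= from_arc <= to_arc <= {total}; "
            f"got ({from_arc}, {to_arc})"
        )
    return float(min(to_arc, total) - from_arc)


def true_arc_length(spec: PhantomSpec) -> float:
    """Ground-truth arc length by adaptive quadrature of ||C'(theta)||."""
    b = spec.taper_rate
    c = spec.height_rise / spec.theta_end

    def speed(theta: float) -> float:
        r = spec.basal_radius * math.exp(-b * theta)
        return math.sqrt(r * r * (1.0 + b * b) + c * c)

    value, _ = integrate.quad(speed, 0.0, spec.theta_end, epsabs=1e-12, epsrel=1e-12)
    return value


@dataclass
class Volume:
    """3D scalar grid with world geometry.

    World coordinate of voxel index (i, j, k) is ``origin + index * spacing``
    (0-based indices, axis-aligned grid).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, idx):
        return np.asarray(idx, dtype=float) * np.array(self.spacing) + np.array(
            self.origin
        )

    def world_to_index(self, xyz):
        return (np.asarray(xyz, dtype=float) - np.array(self.origin)) / np.array(
            self.spacing
        )


def _densify(points: np.ndarray, radii: np.ndarray, step: float):
    """Subdivide polyline segments to <= step, carrying per-point radii."""
    out_p = [points[0]]
    out_r = [radii[0]]
    for a, b, ra, rb in zip(points[:-1], points[1:], radii[:-1], radii[1:]):
        seg = float(np.linalg.norm(b - a))
        n = max(1, int(math.ceil(seg / step)))
        t = np.arange(1, n + 1) / n
        out_p.append(a + t[:, None] * (b - a))
        out_r.append(ra + t * (rb - ra))
    return np.vstack([np.atleast_2d(p) for p in out_p]), np.concatenate(
        [np.atleast_1d(r) for r in out_r]
    )


def rasterize_canal(curve: CenterlineCurve, spec: PhantomSpec) -> Volume:
    """Rasterize the tube around ``curve`` into a voxel volume.

    Foreground (1.0) where the distance to the centerline is within the local
    canal radius, background (0.0) elsewhere; then optional Gaussian blur
    (``blur_sigma``, in mm) and additive Gaussian noise (``noise_sd``, seeded).
    With ``noise_sd == 0`` the output is bit-identical across runs.
    """
    if len(curve) < 2:
        raise ValueError("curve must be non-degenerate")
    spacing = np.array(spec.voxel_spacing, dtype=float)
    if spec.canal_radius_apical < max(spacing) / 2.0:
        warnings.warn(
            "canal radius smaller than half the largest voxel spacing; "
            "the rasterized canal may disconnect",
            stacklevel=2,
        )

    # Tube radius varies linearly in the curve's parameter (theta for
    # generated curves, where samples are theta-uniform).
    n = len(curve)
    radii = spec.canal_radius_basal + np.linspace(0.0, 1.0, n) * (
        spec.canal_radius_apical - spec.canal_radius_basal
    )
    dense_pts, dense_r = _densify(curve.points, radii, float(min(spacing)) / 2.0)

    pad = spec.canal_radius_basal + spec.volume_margin
    lo = dense_pts.min(axis=0) - pad
    hi = dense_pts.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo

    tree = cKDTree(dense_pts)
    ii = [origin[k] + spacing[k] * np.arange(shape[k]) for k in range(3)]
    data = np.empty(tuple(shape), dtype=np.float32)
    yy, zz = np.meshgrid(ii[1], ii[2], indexing="ij")
    plane = np.column_stack(
        [np.empty(yy.size), yy.ravel(), zz.ravel()]
    )
    for i, xw in enumerate(ii[0]):  # slice-wise to bound memory
        plane[:, 0] = xw
        dist, idx = tree.query(plane)
        inside = dist <= dense_r[idx]
        data[i] = inside.reshape(shape[1], shape[2]).astype(np.float32)

    if spec.blur_sigma > 0:
        ndimage.gaussian_filter(
            data, sigma=spec.blur_sigma / spacing, output=data
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape).astype(
            np.float32
        )
    return Volume(data=data, spacing=tuple(spacing), origin=tuple(origin))


# ---------------------------------------------------------------------------
# I/O: NIfTI volumes, centerline CSV, truth sidecar JSON
# ---------------------------------------------------------------------------

def save_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz), axis-aligned affine."""
    import nibabel as nib

    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine), str(path))


def load_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; the affine must be axis-aligned."""
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-8):
        raise ValueError("only axis-aligned volumes are supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError("volume has non-positive spacing on some axis")
    return Volume(
        data=np.asarray(img.dataobj, dtype=np.float32),
        spacing=tuple(spacing),
        origin=tuple(affine[:3, 3]),
    )


_CSV_HEADER = "index,x_mm,y_mm,z_mm,cum_arc_mm"


def write_centerline_csv(curve: CenterlineCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER + "\n")
        for i, (p, s) in enumerate(zip(curve.points, curve.cumulative_arc)):
            fh.write(f"{i},{p[0]:.9f},{p[1]:.9f},{p[2]:.9f},{s:.9f}\n")


def read_centerline_csv(path: str | Path) -> CenterlineCurve:
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    required = {"x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"centerline CSV must have columns {sorted(required)}")
    return CenterlineCurve(df[["x_mm", "y_mm", "z_mm"]].to_numpy())


def write_truth_json(spec: PhantomSpec, path: str | Path) -> None:
    """Sidecar with the phantom parameters and true arc length."""
    payload = {
        "phantom_spec": spec.to_dict(),
        "true_arc_length_mm": true_arc_length(spec),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
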