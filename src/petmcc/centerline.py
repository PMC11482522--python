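"""Airway centerline extraction and perpendicular-disk / cylinder sampling.

The main-airway centerline is the longest path through the 3-D skeleton of
the airway mask, starting from a user-designated proximal seed.  A smoothing
cubic B-spline is fitted to the path and parameterized by arclength; the
curve is extended as a straight ray along the terminal tangent until it
crosses the lung boundary ("extrapolation to the pleura").  PET signal is
sampled either in thin disks perpendicular to the curve or in a cylinder of
fixed diameter around its distal portion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as _sk_skeletonize

from .volume import LabelVolume3D, ScalarVolume3D

__all__ = [
    "Centerline",
    "DiskSample",
    "skeletonize_path",
    "fit_centerline_spline",
    "extrapolate_to_pleura",
    "resolvable_anchor",
    "sample_disks",
    "cylinder_roi",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Centerline:
    """Arclength-parameterized cubic-spline curve with optional straight
    pleural extension.

    ``point_at`` / ``tangent_at`` accept arclength in mm on
    [0, total_length]; beyond ``extension_start`` the curve is the straight
    segment along the terminal tangent of the spline.
    """

    control_points: np.ndarray          # (n, 3) input path, mm
    arclength: np.ndarray               # (n,) cumulative mm at control points
    tck: tuple                          # splprep representation
    _u_grid: np.ndarray = field(repr=False)
    _s_grid: np.ndarray = field(repr=False)
    extension_start: float | None = None   # arclength where extrapolation begins
    _ext_point: np.ndarray | None = field(default=None, repr=False)
    _ext_dir: np.ndarray | None = field(default=None, repr=False)
    _ext_length: float = 0.0

    @property
    def spline_length(self) -> float:
        return float(self._s_grid[-1])

    @property
    def total_length(self) -> float:
        return self.spline_length + self._ext_length

    @property
    def extension_length(self) -> float:
        return self._ext_length

    def _u_of_s(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self._s_grid, self._u_grid)

    def point_at(self, s) -> np.ndarray:
        """Curve point(s) at arclength s (mm); (3,) or (n, 3)."""
        s = np.asarray(s, dtype=float)
        scalar = s.ndim == 0
        s = np.atleast_1d(s)
        out = np.empty((s.size, 3))
        on_spline = s <= self.spline_length
        if on_spline.any():
            u = self._u_of_s(np.clip(s[on_spline], 0, self.spline_length))
            out[on_spline] = np.array(splev(u, self.tck)).T
        if (~on_spline).any():
            if self._ext_point is None:
                raise ValueError("arclength beyond spline but no extension fitted")
            ds = s[~on_spline] - self.spline_length
            out[~on_spline] = self._ext_point + ds[:, None] * self._ext_dir
        return out[0] if scalar else out

    def tangent_at(self, s) -> np.ndarray:
        """Unit tangent(s) at arclength s."""
        s = np.asarray(s, dtype=float)
        scalar = s.ndim == 0
        s = np.atleast_1d(s)
        out = np.empty((s.size, 3))
        on_spline = s <= self.spline_length
        if on_spline.any():
            u = self._u_of_s(np.clip(s[on_spline], 0, self.spline_length))
            d = np.array(splev(u, self.tck, der=1)).T
            out[on_spline] = d / np.linalg.norm(d, axis=1, keepdims=True)
        if (~on_spline).any():
            if self._ext_dir is None:
                raise ValueError("arclength beyond spline but no extension fitted")
            out[~on_spline] = self._ext_dir
        return out[0] if scalar else out

    def dense_samples(self, ds: float) -> tuple[np.ndarray, np.ndarray]:
        """(s_values, points) sampled every ``ds`` mm over the full curve."""
        n = max(int(np.ceil(self.total_length / ds)) + 1, 2)
        s = np.linspace(0.0, self.total_length, n)
        return s, self.point_at(s)

    def to_dataframe(self, ds: float = 0.5):
        """Centerline samples as a DataFrame (x/y/z/arclength/is_extension)."""
        import pandas as pd

        s, pts = self.dense_samples(ds)
        return pd.DataFrame(
            {
                "x_mm": pts[:, 0],
                "y_mm": pts[:, 1],
                "z_mm": pts[:, 2],
                "arclength_mm": s,
                "is_extension": s > self.spline_length + 1e-9,
            }
        )


@dataclass
class DiskSample:
    """PET activity in one thin disk perpendicular to the centerline."""

    center: np.ndarray
    normal: np.ndarray
    thickness_mm: float
    radius_mm: float
    activity_uci: float
    distance_to_pleura_mm: float

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("normal must be a unit vector")
        if self.activity_uci < 0:
            raise ValueError("activity must be non-negative")


# ---------------------------------------------------------------------------
# Skeleton path

def skeletonize_path(
    airway_mask: LabelVolume3D, proximal_seed: tuple[int, int, int]
) -> np.ndarray:
    """Ordered voxel indices of the longest skeleton path from the proximal end.

    The mask is homotopically thinned to a 1-voxel-wide 26-connected
    skeleton; the returned path runs from the skeleton voxel nearest the
    proximal seed to the graph-farthest skeleton voxel (ties broken by
    lexicographically smallest terminal voxel), with side branches pruned.
    """
    arr = airway_mask.as_bool()
    if not arr.any():
        raise ValueError("empty airway mask")
    _, n_comp = ndimage.label(arr, structure=_CONN26)
    if n_comp != 1:
        raise ValueError(f"airway mask has {n_comp} connected components, expected 1")

    skel = _sk_skeletonize(arr)
    vox = np.argwhere(skel)
    if len(vox) == 0:
        raise ValueError("skeletonization produced an empty skeleton")
    spacing = np.asarray(airway_mask.spacing)

    g = nx.Graph()
    g.add_nodes_from(map(tuple, vox))
    tree = cKDTree(vox * spacing)
    pairs = tree.query_pairs(r=float(np.linalg.norm(spacing)) + 1e-9)
    for i, j in pairs:
        a, b = vox[i], vox[j]
        if np.max(np.abs(a - b)) <= 1:  # 26-neighbours only
            g.add_edge(tuple(a), tuple(b), weight=float(np.linalg.norm((a - b) * spacing)))

    seed_mm = np.asarray(proximal_seed) * spacing
    d_seed = np.linalg.norm(vox * spacing - seed_mm, axis=1)
    # deterministic: among equally-near voxels pick the lexicographically smallest
    near = np.isclose(d_seed, d_seed.min())
    start = sorted(map(tuple, vox[near]))[0]

    dist = nx.single_source_dijkstra_path_length(g, start)
    dmax = max(dist.values())
    terminals = sorted(v for v, d in dist.items() if np.isclose(d, dmax))
    end = terminals[0]
    path = nx.dijkstra_path(g, start, end)
    return np.array(path, dtype=int)


# ---------------------------------------------------------------------------
# Spline fit

def fit_centerline_spline(
    path: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    max_residual_mm: float | None = None,
) -> Centerline:
    """Fit an arclength-parameterized smoothing cubic spline to a voxel path.

    ``path`` is (n, 3) voxel indices (converted to world mm via
    spacing/origin) or already-world coordinates if spacing is 1 and origin
    0.  Smoothing is relaxed-to-tightened until the RMS residual at the
    input points is at most one voxel spacing (or ``max_residual_mm``).
    """
    pts = np.asarray(path, dtype=float) * np.asarray(spacing) + np.asarray(origin)
    # drop consecutive duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    if len(pts) < 4:
        raise ValueError(f"need at least 4 distinct path points, got {len(pts)}")

    tol = float(max_residual_mm if max_residual_mm is not None else min(spacing))
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    u_in = chord / chord[-1]

    s_try = len(pts) * tol**2
    tck = u = None
    for _ in range(20):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tck, u = splprep(pts.T, u=u_in, s=s_try, k=3)
        fitted = np.array(splev(u, tck)).T
        rms = float(np.sqrt(np.mean(np.sum((fitted - pts) ** 2, axis=1))))
        if rms <= tol:
            break
        s_try /= 4.0
    # arclength table from dense sampling
    u_grid = np.linspace(0, 1, max(20 * len(pts), 200))
    dense = np.array(splev(u_grid, tck)).T
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s_grid = np.concatenate([[0.0], np.cumsum(seg)])
    return Centerline(
        control_points=pts,
        arclength=np.interp(u_in, u_grid, s_grid),
        tck=tck,
        _u_grid=u_grid,
        _s_grid=s_grid,
    )


# ---------------------------------------------------------------------------
# Extrapolation to the pleura

def extrapolate_to_pleura(
    centerline: Centerline, lung_mask: LabelVolume3D
) -> Centerline:
    """Extend the curve along its terminal tangent to the lung boundary.

    The extension is a straight segment from the spline end to the first
    crossing of the lung-mask boundary (nearest-voxel membership test,
    refined by bisection).  ``extension_start`` records the arclength where
    extrapolation begins.
    """
    end_pt = centerline.point_at(centerline.spline_length)
    direction = centerline.tangent_at(centerline.spline_length)
    spacing = np.asarray(lung_mask.spacing)

    def inside(p: np.ndarray) -> bool:
        idx = lung_mask.voxel_index(p)[0]
        if not lung_mask.contains_index(idx)[0]:
            return False
        return bool(lung_mask.labels[tuple(idx)])

    extent_mm = np.asarray(lung_mask.shape) * spacing
    t_max = 10.0 * float(np.linalg.norm(extent_mm))
    ext_len = 0.0
    if inside(end_pt):
        h = float(spacing.min()) / 4.0
        t = h
        while t <= t_max:
            if not inside(end_pt + t * direction):
                break
            t += h
        else:
            raise RuntimeError(
                "terminal tangent never exits the lung mask (pathological geometry)"
            )
        lo, hi = t - h, t
        for _ in range(20):
            mid = (lo + hi) / 2.0
            if inside(end_pt + mid * direction):
                lo = mid
            else:
                hi = mid
        ext_len = (lo + hi) / 2.0

    return Centerline(
        control_points=centerline.control_points,
        arclength=centerline.arclength,
        tck=centerline.tck,
        _u_grid=centerline._u_grid,
        _s_grid=centerline._s_grid,
        extension_start=centerline.spline_length,
        _ext_point=end_pt,
        _ext_dir=direction,
        _ext_length=ext_len,
    )


# ---------------------------------------------------------------------------
# Sampling

def _assign_voxels_to_curve(
    centerline: Centerline,
    volume: ScalarVolume3D | LabelVolume3D,
    radius_mm: float,
    s_min: float = 0.0,
    s_max: float | None = None,
):
    """Nearest-curve-point assignment of voxel centers within radius.

    Returns (indices (n,3), s_along_curve (n,), radial_distance (n,)).
    """
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    ds = float(min(spacing)) / 4.0
    s_dense, pts_dense = centerline.dense_samples(ds)
    if s_max is None:
        s_max = centerline.total_length

    lo = pts_dense.min(axis=0) - radius_mm
    hi = pts_dense.max(axis=0) + radius_mm
    i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, volume.shape)
    if np.any(i0 >= i1):
        return np.empty((0, 3), int), np.empty(0), np.empty(0)

    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(i0, i1)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    centers = origin + idx * spacing

    tree = cKDTree(pts_dense)
    r, nearest = tree.query(centers, workers=-1)
    s_vox = s_dense[nearest]
    # chord-sampling tolerance: discrete samples overestimate the radial
    # distance of a voxel at exactly `radius` by up to (ds/2)^2 / (2 r)
    tol = (ds / 2.0) ** 2 / (2.0 * max(radius_mm, ds)) + 1e-9
    sel = (r <= radius_mm + tol) & (s_vox >= s_min) & (s_vox <= s_max)
    return idx[sel], s_vox[sel], r[sel]


def resolvable_anchor(
    centerline: Centerline,
    airway_mask: LabelVolume3D,
    diameter_mm: float = 2.0,
) -> float:
    """Arclength where the airway caliber falls below ``diameter_mm``.

    Caliber along the path is estimated as twice the inward distance to the
    airway wall at each control point.  Returns the arclength of the first
    point beyond which the caliber stays below the limit (the last
    "resolvable" airway point); falls back to the start of the pleural
    extension if the caliber never drops below the limit.
    """
    edt = ndimage.distance_transform_edt(
        airway_mask.as_bool(), sampling=airway_mask.spacing
    )
    pts = centerline.control_points
    idx = airway_mask.voxel_index(pts)
    ok = airway_mask.contains_index(idx)
    diam = np.zeros(len(pts))
    sel = idx[ok]
    # EDT measures to the background voxel center, half a voxel beyond the
    # wall on each side: subtract one spacing from the caliber estimate
    diam[ok] = 2.0 * edt[sel[:, 0], sel[:, 1], sel[:, 2]] - min(airway_mask.spacing)
    below = diam < diameter_mm
    for i in range(len(pts)):
        if below[i:].all():
            return float(centerline.arclength[i])
    if centerline.extension_start is not None:
        return float(centerline.extension_start)
    return float(centerline.arclength[-1])


def sample_disks(
    centerline: Centerline,
    pet_frame: ScalarVolume3D,
    spacing_mm: float,
    radius_mm: float,
    thickness_mm: float | None = None,
) -> list[DiskSample]:
    """Partition the swept cylinder into contiguous perpendicular disks.

    Disk planes are uniformly spaced by arclength; each PET voxel within
    ``radius_mm`` of the curve is assigned to exactly one disk by half-open
    arclength bins, so the summed disk activity equals the activity of the
    swept cylinder.  ``distance_to_pleura_mm`` is measured from the disk
    center to the distal end of the curve.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    if radius_mm < min(pet_frame.spacing):
        warnings.warn(
            "disk radius below voxel size: sampling degenerates to the "
            "nearest-voxel tube",
            stacklevel=2,
        )
        radius_mm = max(radius_mm, float(np.linalg.norm(pet_frame.spacing)) / 2.0)
    thickness = float(thickness_mm if thickness_mm is not None else spacing_mm)

    idx, s_vox, _ = _assign_voxels_to_curve(centerline, pet_frame, radius_mm)
    total = centerline.total_length
    n_disks = max(int(np.ceil(total / spacing_mm)), 1)
    disk_of = np.minimum((s_vox / spacing_mm).astype(int), n_disks - 1)

    vals = pet_frame.values[idx[:, 0], idx[:, 1], idx[:, 2]] if len(idx) else np.empty(0)
    disks = []
    for d in range(n_disks):
        s_center = min((d + 0.5) * spacing_mm, total)
        disks.append(
            DiskSample(
                center=centerline.point_at(s_center),
                normal=centerline.tangent_at(s_center),
                thickness_mm=thickness,
                radius_mm=radius_mm,
                activity_uci=float(vals[disk_of == d].sum()) if len(idx) else 0.0,
                distance_to_pleura_mm=float(total - s_center),
            )
        )
    return disks


def cylinder_roi(
    centerline: Centerline,
    lung_mask: LabelVolume3D,
    diameter_mm: float = 2.0,
    start_arclength_mm: float | None = None,
) -> LabelVolume3D:
    """Binary mask of the distal cylinder around the (extended) centerline.

    Voxels whose centers lie within ``diameter_mm / 2`` of the curve, from
    ``start_arclength_mm`` (default: where the pleural extension begins,
    i.e. the last resolvable airway point) to the pleura, clipped to the
    lung mask.
    """
    if centerline.extension_start is None:
        raise ValueError("centerline must be extrapolated to the pleura first")
    radius = diameter_mm / 2.0
    if diameter_mm < min(lung_mask.spacing):
        warnings.warn(
            "cylinder diameter below voxel size: degenerating to a "
            "nearest-voxel tube",
            stacklevel=2,
        )
        radius = float(np.linalg.norm(lung_mask.spacing)) / 2.0
    s_min = (
        float(start_arclength_mm)
        if start_arclength_mm is not None
        else float(centerline.extension_start)
    )
    idx, _, _ = _assign_voxels_to_curve(centerline, lung_mask, radius, s_min=s_min)
    out = np.zeros(lung_mask.shape, dtype=np.uint8)
    if len(idx):
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    out &= (lung_mask.labels > 0).astype(np.uint8)
    if not out.any():
        raise ValueError("cylinder ROI is empty after clipping to the lung mask")
    return LabelVolume3D(out, lung_mask.spacing, lung_mask.origin)
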