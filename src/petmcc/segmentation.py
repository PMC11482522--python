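"""CT segmentation and peripheral-shell geometry.

Airways and lung parenchyma are segmented from CT by region-growing
thresholding (HU < −700 for airway lumen, HU < −200 for parenchyma).  The
peripheral region of interest is a "hollow shell": the rind of the closed
lung mask within a fixed physical depth of the pleural surface, defined via
a Euclidean distance transform so that its thickness is independent of
voxel spacing.  The same inward distance map supports the micro-CT-scale
question of how deep a shell must be to enclose most of the small
(<200 µm diameter) airways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .volume import LabelVolume3D, ScalarVolume3D

__all__ = [
    "SegmentationParams",
    "threshold_region_grow",
    "close_mask",
    "hollow_shell",
    "depth_from_pleura",
    "shell_depth_enclosing",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Thresholds and geometric parameters for airway/lung segmentation.

    hu_airway / hu_parenchyma : upper HU bounds for region growing.
    closing_radius_mm : ball radius for morphological closing of the lung.
    shell_thickness_mm : physical depth of the peripheral shell.
    small_airway_diameter_um : diameter below which an airway counts as small.
    enclosure_fraction : fraction of small-airway voxels a shell must enclose.
    """

    hu_airway: float = -700.0
    hu_parenchyma: float = -200.0
    closing_radius_mm: float = 2.0
    shell_thickness_mm: float = 1.5
    small_airway_diameter_um: float = 200.0
    enclosure_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not self.hu_airway < self.hu_parenchyma:
            raise ValueError("hu_airway must be below hu_parenchyma")
        if self.shell_thickness_mm <= 0:
            raise ValueError("shell_thickness_mm must be positive")
        if not 0 < self.enclosure_fraction <= 1:
            raise ValueError("enclosure_fraction must be in (0, 1]")


def _require_binary(mask: LabelVolume3D) -> np.ndarray:
    arr = mask.labels
    if arr.max(initial=0) > 1:
        raise ValueError("mask must be binary (labels 0/1)")
    return arr > 0


def threshold_region_grow(
    ct: ScalarVolume3D, seed: tuple[int, int, int], hu_max: float
) -> LabelVolume3D:
    """26-connected component of {HU < hu_max} containing ``seed``."""
    seed = tuple(int(s) for s in seed)
    if not ct.contains_index(np.array(seed))[0]:
        raise IndexError(f"seed {seed} outside volume grid {ct.shape}")
    if not ct.values[seed] < hu_max:
        raise ValueError(
            f"seed voxel value {ct.values[seed]:g} not below threshold {hu_max:g}"
        )
    below = ct.values < hu_max
    comp, _ = ndimage.label(below, structure=_CONN26)
    grown = comp == comp[seed]
    return LabelVolume3D(grown.astype(np.uint8), ct.spacing, ct.origin)


def _ball_element(radius_mm: float, spacing) -> np.ndarray:
    """Ellipsoidal structuring element = physical ball of radius_mm."""
    half = [max(1, int(np.floor(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    return sum(g**2 for g in grids) <= radius_mm**2 + 1e-9


def close_mask(mask: LabelVolume3D, radius_mm: float) -> LabelVolume3D:
    """Morphological closing with a physical ball, then cavity filling.

    Closing bridges gaps up to ~2×radius; filling removes background
    cavities fully enclosed by the mask (6-connectivity, complementary to
    the 26-connectivity used for foreground growing).  Result is a superset
    of the input.
    """
    arr = _require_binary(mask)
    elem = _ball_element(radius_mm, mask.spacing)
    # pad so dilation at the grid edge is not clipped by the border
    pad = [s // 2 for s in elem.shape]
    padded = np.pad(arr, [(p, p) for p in pad])
    closed = ndimage.binary_closing(padded, structure=elem)
    closed = closed[tuple(slice(p, -p if p else None) for p in pad)]
    filled = ndimage.binary_fill_holes(closed, structure=ndimage.generate_binary_structure(3, 1))
    out = filled | arr
    return LabelVolume3D(out.astype(np.uint8), mask.spacing, mask.origin)


def depth_from_pleura(lung_mask: LabelVolume3D) -> ScalarVolume3D:
    """Per-voxel Euclidean distance (mm) to the nearest voxel center outside
    the mask; zero outside.  The grid boundary counts as outside."""
    arr = _require_binary(lung_mask)
    if not arr.any():
        warnings.warn("empty lung mask: depth map is all zero", stacklevel=2)
        return ScalarVolume3D(
            np.zeros(arr.shape, dtype=float), lung_mask.spacing, lung_mask.origin
        )
    padded = np.pad(arr, 1)
    d = ndimage.distance_transform_edt(padded, sampling=lung_mask.spacing)
    d = d[1:-1, 1:-1, 1:-1]
    return ScalarVolume3D(d, lung_mask.spacing, lung_mask.origin)


def hollow_shell(lung_mask: LabelVolume3D, thickness_mm: float) -> LabelVolume3D:
    """Peripheral rind of the mask: voxels with 0 < depth <= thickness_mm.

    The shell and the remaining "core" partition the mask.
    """
    if thickness_mm <= 0:
        raise ValueError("thickness_mm must be positive")
    arr = _require_binary(lung_mask)
    if not arr.any():
        warnings.warn("empty lung mask: shell is empty", stacklevel=2)
        return LabelVolume3D(
            np.zeros(arr.shape, dtype=np.uint8), lung_mask.spacing, lung_mask.origin
        )
    d = depth_from_pleura(lung_mask).values
    shell = arr & (d <= thickness_mm)
    return LabelVolume3D(shell.astype(np.uint8), lung_mask.spacing, lung_mask.origin)


def shell_depth_enclosing(
    airway_mask: LabelVolume3D,
    lung_mask: LabelVolume3D,
    params: SegmentationParams | None = None,
) -> float:
    """Minimal shell depth (mm) enclosing most small airways.

    Local airway diameter is estimated at skeleton voxels as twice the
    inward distance to the airway wall.  Skeleton voxels whose diameter is
    below ``small_airway_diameter_um`` are classified as small airways; the
    returned depth D is the smallest pleural depth such that at least
    ``enclosure_fraction`` of those voxels lie within D of the pleura.
    """
    params = params or SegmentationParams()
    a = _require_binary(airway_mask)
    l = _require_binary(lung_mask)
    if np.any(a & ~l):
        raise ValueError("airway mask must be contained in lung mask")

    skel = _sk_skeletonize(a)
    if not skel.any():
        raise ValueError("airway mask produced an empty skeleton")
    # radius at the skeleton = inward EDT of the airway mask
    radius_mm = ndimage.distance_transform_edt(a, sampling=airway_mask.spacing)
    diameter_um = 2.0 * radius_mm[skel] * 1000.0
    small = diameter_um < params.small_airway_diameter_um
    if not small.any():
        raise ValueError(
            "no small airways resolved: no skeleton voxel below "
            f"{params.small_airway_diameter_um:g} µm diameter"
        )
    depths = depth_from_pleura(lung_mask).values[skel][small]
    depths = np.sort(depths)
    k = int(np.ceil(params.enclosure_fraction * depths.size)) - 1
    return float(depths[max(k, 0)])
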