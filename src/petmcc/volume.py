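"""Volumes, dynamic series and event binning.

Geometry convention used throughout the package: voxel indices are 0-based,
axis-aligned, and the world coordinate of a voxel center is
``origin + index * spacing`` (millimetres).  Volumes are stored as NIfTI-1
with a diagonal affine; no oblique orientations are supported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ScalarVolume3D",
    "LabelVolume3D",
    "DynamicSeries",
    "EventList",
    "AcquisitionSpec",
    "VolumeFormatError",
    "read_volume",
    "read_label_volume",
    "write_volume",
    "read_series",
    "write_series",
    "read_events_csv",
    "write_events_csv",
    "bin_events",
    "counts_to_activity",
    "KBQ_PER_UCI",
]

#: 1 µCi = 37 kBq (exact, by definition of the curie).
KBQ_PER_UCI = 37.0


class VolumeFormatError(IOError):
    """Raised when a volume file cannot be read as valid NIfTI."""


def _check_geometry(values: np.ndarray, spacing, origin) -> tuple[tuple, tuple]:
    values = np.asarray(values)
    if values.ndim != 3 or min(values.shape) < 1:
        raise ValueError(f"expected a 3-D array, got shape {values.shape}")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must have 3 components")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing, origin


@dataclass
class ScalarVolume3D:
    """3-D scalar grid (HU or µCi per voxel) with physical spacing/origin."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing, self.origin = _check_geometry(self.values, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "ScalarVolume3D | LabelVolume3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel centers for an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index for an (n, 3) array of world points."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = np.rint((pts - np.asarray(self.origin)) / np.asarray(self.spacing))
        return idx.astype(int)

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx))
        shape = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=1)


@dataclass
class LabelVolume3D:
    """Integer label map sharing geometry with the volume it annotates.

    Label 0 is background.  Canonical codes for exported segmentations:
    0 background, 1 parenchyma, 2 airway, 3 shell.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.spacing, self.origin = _check_geometry(self.labels, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    same_geometry = ScalarVolume3D.same_geometry
    world_coords = ScalarVolume3D.world_coords
    voxel_index = ScalarVolume3D.voxel_index
    contains_index = ScalarVolume3D.contains_index

    def as_bool(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class DynamicSeries:
    """Time-ordered activity frames sharing one geometry.

    ``frame_times`` holds (start_s, end_s) per frame; intervals must be
    non-overlapping and strictly increasing.
    """

    frames: list[ScalarVolume3D]
    frame_times: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.frame_times):
            raise ValueError("frames and frame_times must have equal length")
        if not self.frames:
            raise ValueError("series must contain at least one frame")
        g0 = self.frames[0]
        for fr in self.frames[1:]:
            if not g0.same_geometry(fr):
                raise ValueError("all frames must share one geometry")
        prev_end = -np.inf
        times = []
        for start, end in self.frame_times:
            start, end = float(start), float(end)
            if end <= start:
                raise ValueError(f"frame interval ({start}, {end}) has end <= start")
            if start < prev_end:
                raise ValueError("frame intervals overlap or are out of order")
            prev_end = end
            times.append((start, end))
        self.frame_times = times

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def geometry(self) -> ScalarVolume3D:
        return self.frames[0]

    @property
    def midpoints_s(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.frame_times])

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.midpoints_s / 60.0

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([b - a for a, b in self.frame_times])

    def stack(self) -> np.ndarray:
        """(nx, ny, nz, nt) array of frame values."""
        return np.stack([f.values for f in self.frames], axis=-1)


@dataclass
class EventList:
    """Timestamped coincidence events at voxel positions (list-mode data)."""

    timestamps_s: np.ndarray
    positions: np.ndarray  # (n, 3) voxel indices

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=int))
        if self.timestamps_s.size == 0:
            self.positions = self.positions.reshape(0, 3)
        if self.positions.shape != (self.timestamps_s.size, 3):
            raise ValueError("positions must be (n, 3) matching timestamps")
        if self.timestamps_s.size and self.timestamps_s.min() < 0:
            raise ValueError("timestamps must be non-negative")

    def __len__(self) -> int:
        return int(self.timestamps_s.size)


@dataclass
class AcquisitionSpec:
    """Scanner and acquisition constants.

    Defaults reproduce a 15-min list-mode acquisition binned into 10-s
    frames of a Ga-68 tracer (half-life 68 min) on a digital PET/CT with
    sensitivity 7.3 cps/kBq and PSF FWHM 5.5/4.5/6 mm
    (radial/tangential/axial).
    """

    frame_duration_s: float = 10.0
    total_duration_min: float = 15.0
    half_life_min: float = 68.0
    sensitivity_cps_per_kbq: float = 7.3
    psf_fwhm_mm: tuple[float, float, float] = (5.5, 4.5, 6.0)

    def __post_init__(self) -> None:
        self.psf_fwhm_mm = tuple(float(f) for f in self.psf_fwhm_mm)
        vals = (
            self.frame_duration_s,
            self.total_duration_min,
            self.half_life_min,
            self.sensitivity_cps_per_kbq,
            *self.psf_fwhm_mm,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all acquisition parameters must be positive")

    @property
    def total_duration_s(self) -> float:
        return self.total_duration_min * 60.0

    def frame_edges(self) -> list[tuple[float, float]]:
        """Half-open frame intervals covering the acquisition.

        A trailing partial frame is kept with its true duration.
        """
        edges = []
        t = 0.0
        while t < self.total_duration_s - 1e-9:
            end = min(t + self.frame_duration_s, self.total_duration_s)
            edges.append((t, end))
            t = end
        return edges


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _load_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeFormatError(f"cannot read NIfTI volume from {path!s}: {exc}") from exc
    return img, data


def read_volume(path) -> ScalarVolume3D:
    """Read a 3-D NIfTI volume; raises :class:`VolumeFormatError` if invalid."""
    img, data = _load_nifti(path)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path!s}: expected 3-D data, got shape {data.shape}")
    aff = img.affine
    spacing = tuple(np.linalg.norm(aff[:3, i]) for i in range(3))
    origin = tuple(aff[:3, 3])
    return ScalarVolume3D(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(volume: ScalarVolume3D | LabelVolume3D, path) -> None:
    data = volume.labels if isinstance(volume, LabelVolume3D) else volume.values
    img = nib.Nifti1Image(np.asarray(data), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_label_volume(path) -> LabelVolume3D:
    vol = read_volume(path)
    return LabelVolume3D(np.rint(vol.values).astype(np.int32), vol.spacing, vol.origin)


def _sidecar(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return p.with_name(name + ".frametimes.json")


def write_series(series: DynamicSeries, path) -> None:
    """Write a dynamic series as 4-D NIfTI plus a frame-times JSON sidecar."""
    data = series.stack()
    g = series.geometry
    nib.save(nib.Nifti1Image(data, _affine(g.spacing, g.origin)), str(path))
    _sidecar(path).write_text(
        json.dumps({"frame_times_s": [list(t) for t in series.frame_times]})
    )


def read_series(path) -> DynamicSeries:
    img, data = _load_nifti(path)
    if data.ndim != 4:
        raise VolumeFormatError(f"{path!s}: expected 4-D data, got shape {data.shape}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise VolumeFormatError(f"missing frame-times sidecar {sidecar!s}")
    times = [tuple(t) for t in json.loads(sidecar.read_text())["frame_times_s"]]
    aff = img.affine
    spacing = tuple(np.linalg.norm(aff[:3, i]) for i in range(3))
    origin = tuple(aff[:3, 3])
    frames = [
        ScalarVolume3D(np.asarray(data[..., k], dtype=np.float64), spacing, origin)
        for k in range(data.shape[3])
    ]
    return DynamicSeries(frames, times)


def write_events_csv(events: EventList, path) -> None:
    pd.DataFrame(
        {
            "t_s": events.timestamps_s,
            "i": events.positions[:, 0],
            "j": events.positions[:, 1],
            "k": events.positions[:, 2],
        }
    ).to_csv(path, index=False)


def read_events_csv(path) -> EventList:
    df = pd.read_csv(path)
    return EventList(df["t_s"].to_numpy(), df[["i", "j", "k"]].to_numpy())


# ---------------------------------------------------------------------------
# Event binning

def bin_events(
    events: EventList,
    spec: AcquisitionSpec,
    geometry: ScalarVolume3D | LabelVolume3D,
) -> DynamicSeries:
    """Bin list-mode events into fixed-duration frames of counts.

    Frames are half-open ``[start, start + dt)``: an event exactly on a
    boundary belongs to the later frame.  Events at or beyond the total
    acquisition duration are rejected with a warning reporting their count.
    Frame values are raw counts; see :func:`counts_to_activity`.
    """
    edges = spec.frame_edges()
    n_frames = len(edges)
    shape = geometry.shape

    t = events.timestamps_s
    pos = events.positions
    if len(events) and not np.all(geometry.contains_index(pos)):
        raise ValueError("event positions outside the volume grid")

    keep = t < spec.total_duration_s
    n_rej = int((~keep).sum())
    if n_rej:
        warnings.warn(
            f"rejected {n_rej} events at/beyond total duration "
            f"{spec.total_duration_s:g} s",
            stacklevel=2,
        )
    t, pos = t[keep], pos[keep]

    frame_idx = np.minimum(
        (t / spec.frame_duration_s).astype(int), n_frames - 1
    )
    counts = np.zeros((n_frames,) + shape, dtype=np.float64)
    if len(t):
        flat_vox = np.ravel_multi_index((pos[:, 0], pos[:, 1], pos[:, 2]), shape)
        flat = frame_idx * int(np.prod(shape)) + flat_vox
        np.add.at(counts.reshape(-1), flat, 1.0)

    frames = [
        ScalarVolume3D(counts[k], geometry.spacing, geometry.origin)
        for k in range(n_frames)
    ]
    return DynamicSeries(frames, edges)


def counts_to_activity(series: DynamicSeries, spec: AcquisitionSpec) -> DynamicSeries:
    """Convert count frames to activity (µCi): counts / (duration × sensitivity × 37)."""
    durations = series.durations_s
    frames = []
    for fr, dur in zip(series.frames, durations):
        kbq = fr.values / (dur * spec.sensitivity_cps_per_kbq)
        frames.append(ScalarVolume3D(kbq / KBQ_PER_UCI, fr.spacing, fr.origin))
    return DynamicSeries(frames, list(series.frame_times))
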