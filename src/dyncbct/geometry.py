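"""Shared coordinate conventions and data containers.

Conventions (fixed once, used by every module):

* World frame: origin at the scanner isocenter, right-handed axes with
  ``x`` lateral, ``y`` anterior-posterior and ``z`` superior-inferior (SI).
* Voxel indexing is 0-based; the world coordinate of voxel ``(i, j, k)`` is
  ``origin + index * spacing``.  Volume arrays are indexed ``[ix, iy, iz]``.
* Gantry angles are degrees externally, radians internally.  At angle 0 the
  source sits at ``(0, -sad, 0)`` and the beam points along ``+y``.  The
  detector ``u`` axis is the in-plane lateral direction and the ``v`` axis is
  aligned with world ``z`` (SI), which the Amsterdam-Shroud trace relies on.
* Projection values are line integrals (post-log attenuation, mm^-1 * mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanGeometry",
    "VolumeGrid",
    "Volume",
    "ProjectionSet",
    "DisplacementField",
    "make_circular_trajectory",
]


@dataclass
class ScanGeometry:
    """Circular cone-beam acquisition description.

    Parameters
    ----------
    sad, sdd:
        Source-to-axis and source-to-detector distances in mm.
    n_u, n_v:
        Detector pixel counts (width, height).
    pixel_u, pixel_v:
        Detector pixel pitch in mm.
    fan_mode:
        ``"full"`` (centred detector) or ``"half"`` (laterally offset
        detector for an enlarged field of view).
    detector_offset_u:
        Lateral detector shift in mm; must be 0 in full-fan mode.
    angles, times:
        Per-projection gantry angles (degrees) and acquisition times
        (seconds, strictly increasing).
    """

    sad: float
    sdd: float
    n_u: int
    n_v: int
    pixel_u: float
    pixel_v: float
    fan_mode: str = "full"
    detector_offset_u: float = 0.0
    angles: np.ndarray = field(default_factory=lambda: np.zeros(0))
    times: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if not (self.sdd > self.sad > 0):
            raise ValueError(f"require sdd > sad > 0, got sad={self.sad}, sdd={self.sdd}")
        if self.fan_mode not in ("full", "half"):
            raise ValueError(f"fan_mode must be 'full' or 'half', got {self.fan_mode!r}")
        if self.fan_mode == "full" and self.detector_offset_u != 0.0:
            raise ValueError("detector_offset_u must be 0 in full-fan mode")
        if len(self.angles) != len(self.times):
            raise ValueError("angles and times must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_views(self) -> int:
        return len(self.angles)

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    def source_position(self, angle_index: int) -> np.ndarray:
        """World position of the X-ray source for one view."""
        th = np.deg2rad(self.angles[angle_index])
        return np.array([-self.sad * np.sin(th), -self.sad * np.cos(th), 0.0])

    def view_matrix(self, angle_index: int) -> np.ndarray:
        """Rows are the detector u axis, v axis and beam direction.

        Camera coordinates of a world point ``x`` are
        ``t = view_matrix @ (x - source_position)`` with ``t2`` the distance
        along the beam axis from the source.
        """
        th = np.deg2rad(self.angles[angle_index])
        u_axis = np.array([np.cos(th), -np.sin(th), 0.0])
        v_axis = np.array([0.0, 0.0, 1.0])
        beam = np.array([np.sin(th), np.cos(th), 0.0])
        return np.stack([u_axis, v_axis, beam])

    def detector_u_mm(self) -> np.ndarray:
        """Physical u coordinate of each pixel column, from the piercing point."""
        return (np.arange(self.n_u) - (self.n_u - 1) / 2.0) * self.pixel_u + self.detector_offset_u

    def detector_v_mm(self) -> np.ndarray:
        return (np.arange(self.n_v) - (self.n_v - 1) / 2.0) * self.pixel_v

    def to_dict(self) -> dict:
        return {
            "sad": self.sad,
            "sdd": self.sdd,
            "n_u": self.n_u,
            "n_v": self.n_v,
            "pixel_u": self.pixel_u,
            "pixel_v": self.pixel_v,
            "fan_mode": self.fan_mode,
            "detector_offset_u": self.detector_offset_u,
            "angles": self.angles.tolist(),
            "times": self.times.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            sad=d["sad"], sdd=d["sdd"], n_u=int(d["n_u"]), n_v=int(d["n_v"]),
            pixel_u=d["pixel_u"], pixel_v=d["pixel_v"],
            fan_mode=d.get("fan_mode", "full"),
            detector_offset_u=d.get("detector_offset_u", 0.0),
            angles=np.asarray(d["angles"], dtype=np.float64),
            times=np.asarray(d["times"], dtype=np.float64),
        )


@dataclass
class VolumeGrid:
    """Regular voxel grid; world coordinate of voxel i is origin + i*spacing."""

    n_x: int
    n_y: int
    n_z: int
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")

    @classmethod
    def centered(cls, shape: tuple[int, int, int], spacing) -> "VolumeGrid":
        """Grid whose voxel-center cloud is centred on the isocenter."""
        spacing = tuple(float(s) for s in np.broadcast_to(spacing, 3))
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return cls(shape[0], shape[1], shape[2], spacing, origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_x, self.n_y, self.n_z)

    @property
    def n_voxels(self) -> int:
        return self.n_x * self.n_y * self.n_z

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points (N, 3)."""
        return (np.asarray(points) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def same_as(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Volume:
    """Scalar field over a grid; values are line attenuation per mm."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")


@dataclass
class ProjectionSet:
    """Stack of line-integral frames, one per gantry angle."""

    geometry: ScanGeometry
    frames: np.ndarray  # (n_views, n_v, n_u)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_views, n_v, n_u) stack")
        if self.frames.shape[0] != self.geometry.n_views:
            raise ValueError(
                f"frame count {self.frames.shape[0]} != angle count {self.geometry.n_views}"
            )
        if self.frames.shape[1:] != (self.geometry.n_v, self.geometry.n_u):
            raise ValueError("frame shape does not match detector size")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("projection values must be finite")


@dataclass
class DisplacementField:
    """Backward (pull) displacement field in mm.

    ``vectors[..., k]`` is the k-th Cartesian component; the deformed image
    samples the reference at ``x + d(x)``.
    """

    grid: VolumeGrid
    vectors: np.ndarray  # (n_x, n_y, n_z, 3)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValueError("vectors must have shape grid.shape + (3,)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement values must be finite")

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.vectors**2).sum(axis=-1)).max())


def make_circular_trajectory(
    start_deg: float, arc_deg: float, duration_s: float, fps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-speed circular gantry trajectory.

    Returns ``round(duration_s * fps)`` samples uniformly spaced in time with
    the gantry angle linear in time; e.g. a 60 s scan at 11 fps over 360 deg
    yields 660 views at 6 deg/s, the last strictly below ``start + arc``.
    """
    if arc_deg <= 0 or fps <= 0 or duration_s <= 0:
        raise ValueError("arc_deg, duration_s and fps must all be positive")
    n = int(round(duration_s * fps))
    times = np.arange(n) / fps
    angles = start_deg + arc_deg * times / duration_s
    return angles, times
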