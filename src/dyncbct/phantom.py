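"""Programmatic 4D thorax phantom with analytic ground-truth motion.

An ellipsoid-composited thorax (body, two lungs, diaphragm domes, spine with
vertebrae, spherical lung tumor) stands in for a licensed anthropomorphic
phantom: voxelization, tumor size and motion statistics are matched, not the
anatomy.  Breathing is a single spatial mode scaled by a scalar trace, so
every frame is *defined* as a backward warp of the reference anatomy,

    frame_a(x) = ref(x + d_a(x)),      d_a(x) = a * u(x),

with ``u`` a smooth unit displacement field that equals -1 (SI) on a plateau
covering the tumor and diaphragm dome, decays to zero toward the lung apex
and the body surface, is exactly zero on the (dilated) spine column — a hard
sliding discontinuity — and carries a small anterior-posterior component in
the abdomen.  Positive trace therefore moves the tumor superiorly by the
trace value, and the ground-truth DVF is exact by construction, not the
by-product of a resampling step.

Seven breathing scenarios (S1..S7) emulate a 60 s free-breathing CBCT
acquisition: quasi-periodic ~5 s cycles with 13 mm peak-to-trough excursion
and variations thereof (baseline shift, amplitude/baseline drift, increasing
period, one slow cycle, combined irregularity, 20 mm extended range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DisplacementField,
    ProjectionSet,
    ScanGeometry,
    Volume,
    VolumeGrid,
)
from .projector import forward_project

__all__ = [
    "PhantomSpec",
    "BreathingTrace",
    "PhantomFrame",
    "make_trace",
    "analytic_dvf",
    "render_frame",
    "simulate_scan",
]

SCENARIOS = ("S1", "S2", "S3", "S4", "S5", "S6", "S7")

# tissue attenuation in mm^-1 (~ water 0.02 at CBCT energies)
MU_SOFT = 0.02
MU_LUNG = 0.004
MU_BONE = 0.04
MU_DISC = 0.03
MU_TUMOR = 0.024


@dataclass
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    mu: float

    def inside(self, x, y, z):
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    def quad(self, x, y, z):
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2


@dataclass
class PhantomSpec:
    """Geometric description of the analytic thorax; lengths in mm.

    The default anatomy scales with the grid extent so the same phantom
    works at full size and at reduced desk-test size, while the tumor
    diameter and motion amplitudes stay absolute (they are protocol values).
    """

    grid: VolumeGrid
    body: Ellipsoid
    lungs: tuple[Ellipsoid, Ellipsoid]
    dome_apex_z: float
    dome_curvature: float  # mm^-1; dome height drop = curvature * r^2
    spine_center_y: float
    spine_radius: float
    vertebra_period: float
    tumor_center: tuple[float, float, float]
    tumor_diameter: float = 30.0
    motion_plateau_z: float = 30.0  # SI plateau top: full motion below this
    ap_fraction: float = 0.2
    ap_start_z: float = -35.0  # AP motion confined below this height (abdomen)

    @classmethod
    def default(cls, grid: VolumeGrid | None = None) -> "PhantomSpec":
        if grid is None:
            grid = VolumeGrid.centered((200, 200, 100), 2.0)
        ex, ey, ez = grid.extent_mm
        body = Ellipsoid((0.0, 10.0, 0.0), (0.45 * ex, 0.40 * ey, 1.2 * ez), MU_SOFT)
        lung_dx = 0.22 * ex
        lungs = (
            Ellipsoid((-lung_dx, -0.03 * ey, 0.10 * ez), (0.16 * ex, 0.24 * ey, 0.36 * ez), MU_LUNG),
            Ellipsoid((lung_dx, -0.03 * ey, 0.10 * ez), (0.16 * ex, 0.24 * ey, 0.36 * ez), MU_LUNG),
        )
        tumor_center = (lung_dx, -0.03 * ey, -0.05 * ez)
        return cls(
            grid=grid,
            body=body,
            lungs=lungs,
            dome_apex_z=-0.15 * ez,
            dome_curvature=0.10 / (0.25 * ex),
            spine_center_y=0.28 * ey,
            spine_radius=0.075 * ex,
            vertebra_period=0.24 * ez,
            tumor_center=tumor_center,
            motion_plateau_z=0.30 * ez,
            ap_start_z=-0.35 * ez,
        )


@dataclass
class BreathingTrace:
    """SI displacement trace in mm; positive values move the tumor superiorly."""

    times: np.ndarray
    values: np.ndarray
    scenario: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PhantomFrame:
    """One motion state: volume, exact tumor mask and ground-truth DVF."""

    volume: Volume
    tumor_mask: np.ndarray
    trace_value: float
    _unit_dvf: np.ndarray = field(repr=False, default=None)

    @property
    def gt_dvf(self) -> DisplacementField:
        return DisplacementField(
            self.volume.grid, (self.trace_value * self._unit_dvf).astype(np.float64)
        )


def _cycle_phase(duration_s, fps, periods, rng) -> np.ndarray:
    """Accumulated phase (one cycle = 1.0) for a time-varying period."""
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    dt = 1.0 / fps
    inst = np.interp(t, np.linspace(0, duration_s, len(periods)), periods)
    return np.cumsum(dt / inst) - dt / inst[0]


def make_trace(scenario: str, duration_s: float, fps: float, seed: int = 0) -> BreathingTrace:
    """Generate one of the seven breathing scenarios (deterministic per seed)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    amp = 13.0

    def quasi_periodic(amplitude, period_jitter=0.15):
        n_cyc = int(np.ceil(duration_s / 4.0)) + 2
        periods = np.clip(5.0 + period_jitter * 5.0 * rng.standard_normal(n_cyc), 3.5, 7.0)
        phase = _cycle_phase(duration_s, fps, periods, rng)
        return amplitude * np.cos(np.pi * phase) ** 4

    if scenario == "S1":
        values = quasi_periodic(amp)
    elif scenario == "S2":
        values = quasi_periodic(amp)
        values = values + np.where(t >= duration_s / 2.0, 5.0, 0.0)
    elif scenario == "S3":
        n_cyc = int(np.ceil(duration_s / 4.0)) + 2
        periods = np.clip(5.0 + 0.75 * rng.standard_normal(n_cyc), 3.5, 7.0)
        phase = _cycle_phase(duration_s, fps, periods, rng)
        cyc_amp = np.clip(amp * (1.0 + 0.2 * rng.standard_normal(n_cyc)), 6.0, 20.0)
        amp_t = np.interp(phase, np.arange(n_cyc, dtype=float), cyc_amp)
        drift = 3.0 * np.sin(2 * np.pi * t / duration_s)
        values = amp_t * np.cos(np.pi * phase) ** 4 + drift
    elif scenario == "S4":
        inst = 4.0 + 3.0 * t / duration_s
        phase = np.cumsum((1.0 / fps) / inst)
        phase -= phase[0]
        values = amp * np.cos(np.pi * phase) ** 4
    elif scenario == "S5":
        values = amp * np.sin(np.pi * t / duration_s) ** 4
    elif scenario == "S6":
        n_cyc = int(np.ceil(duration_s / 4.0)) + 2
        periods = np.clip(5.0 + 1.0 * rng.standard_normal(n_cyc), 3.0, 8.0)
        phase = _cycle_phase(duration_s, fps, periods, rng)
        cyc_amp = np.clip(amp * (1.0 + 0.25 * rng.standard_normal(n_cyc)), 5.0, 22.0)
        amp_t = np.interp(phase, np.arange(n_cyc, dtype=float), cyc_amp)
        base = 2.5 * np.sin(2 * np.pi * t / (0.7 * duration_s)) + np.where(
            t >= 0.6 * duration_s, 3.0, 0.0
        )
        values = amp_t * np.cos(np.pi * phase) ** 4 + base
    else:  # S7: extended range
        values = quasi_periodic(20.0)
    return BreathingTrace(t, values, scenario)


def _spine_mask(spec: PhantomSpec, x, y, margin: float = 0.0):
    r2 = x**2 + (y - spec.spine_center_y) ** 2
    return r2 <= (spec.spine_radius + margin) ** 2


def _unit_displacement(spec: PhantomSpec) -> np.ndarray:
    """Unit-trace backward displacement field u(x) on the phantom grid."""
    x, y, z = spec.grid.meshgrid()
    # SI weight: plateau below motion_plateau_z, linear decay to the lung apex
    lung_top = max(l.center[2] + l.semi_axes[2] for l in spec.lungs)
    s_z = np.clip((lung_top - z) / max(lung_top - spec.motion_plateau_z, 1e-6), 0.0, 1.0)
    # fade toward the body surface
    q = spec.body.quad(x, y, z)
    s_body = np.clip((1.0 - q) / 0.3, 0.0, 1.0)
    s = s_z * s_body
    s[_spine_mask(spec, x, y, margin=4.0)] = 0.0
    u = np.zeros(spec.grid.shape + (3,), dtype=np.float64)
    u[..., 2] = -s  # positive trace shifts anatomy superiorly
    # small AP component confined to the abdomen, below the moving tumor
    ap = np.clip((spec.ap_start_z - z) / 20.0, 0.0, 1.0)
    u[..., 1] = -spec.ap_fraction * s * ap
    return u


def analytic_dvf(spec: PhantomSpec, trace_value: float) -> DisplacementField:
    """Exact backward DVF for one trace value (clamped to +-30 mm)."""
    a = float(np.clip(trace_value, -30.0, 30.0))
    return DisplacementField(spec.grid, a * _unit_displacement(spec))


def _soft_step(signed_mm: np.ndarray, edge_mm: float) -> np.ndarray:
    """0..1 indicator with a linear transition of width ``edge_mm``.

    Anti-aliases shape boundaries over about one voxel (partial volume), so
    warping the discretized reference reproduces the analytically rendered
    frames up to smooth interpolation error instead of edge aliasing.
    """
    return np.clip(signed_mm / edge_mm + 0.5, 0.0, 1.0)


def _soft_ellipsoid(e: Ellipsoid, x, y, z, edge_mm: float) -> np.ndarray:
    q = e.quad(x, y, z)
    r_geo = float(np.prod(e.semi_axes)) ** (1.0 / 3.0)
    return _soft_step((1.0 - np.sqrt(q)) * r_geo, edge_mm)


def _reference_density(spec: PhantomSpec, x, y, z, edge_mm: float = 2.0) -> np.ndarray:
    """Analytic reference anatomy evaluated at arbitrary world points."""
    vals = MU_SOFT * _soft_ellipsoid(spec.body, x, y, z, edge_mm)
    for lung in spec.lungs:
        dome = spec.dome_apex_z - spec.dome_curvature * (
            (x - lung.center[0]) ** 2 + (y - lung.center[1]) ** 2
        )
        air = _soft_ellipsoid(lung, x, y, z, edge_mm) * _soft_step(z - dome, edge_mm)
        vals = vals * (1 - air) + MU_LUNG * air
    body = _soft_ellipsoid(spec.body, x, y, z, edge_mm)
    r_sp = np.sqrt(x**2 + (y - spec.spine_center_y) ** 2)
    spine = _soft_step(spec.spine_radius - r_sp, edge_mm) * body
    vertebra = (np.mod(z + 1e9, spec.vertebra_period) / spec.vertebra_period) < 0.7
    mu_spine = np.where(vertebra, MU_BONE, MU_DISC)
    vals = vals * (1 - spine) + mu_spine * spine
    cx, cy, cz = spec.tumor_center
    r = spec.tumor_diameter / 2.0
    dist = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
    tumor = _soft_step(r - dist, edge_mm)
    vals = vals * (1 - tumor) + MU_TUMOR * tumor
    return vals


def render_frame(
    spec: PhantomSpec, trace_value: float, unit_dvf: np.ndarray | None = None
) -> PhantomFrame:
    """Anatomy at one motion state, evaluated analytically (no resampling blur)."""
    a = float(np.clip(trace_value, -30.0, 30.0))
    if unit_dvf is None:
        unit_dvf = _unit_displacement(spec)
    x, y, z = spec.grid.meshgrid()
    xw = x + a * unit_dvf[..., 0]
    yw = y + a * unit_dvf[..., 1]
    zw = z + a * unit_dvf[..., 2]
    vals = _reference_density(spec, xw, yw, zw).astype(np.float32)
    # exact shifted tumor sphere (the plateau makes d = -a e_z there)
    cx, cy, cz = spec.tumor_center
    r = spec.tumor_diameter / 2.0
    mask = (x - cx) ** 2 + (y - cy) ** 2 + (z - (cz + a)) ** 2 <= r**2
    return PhantomFrame(
        Volume(spec.grid, vals), mask, a,
        _unit_dvf=np.asarray(unit_dvf, dtype=np.float32),
    )


def simulate_scan(
    spec: PhantomSpec,
    trace: BreathingTrace,
    geometry: ScanGeometry,
    noise_i0: float | None = None,
    seed: int = 0,
    keep_frames: bool = True,
) -> tuple[ProjectionSet, list[PhantomFrame]]:
    """Forward-project the moving phantom along the scan trajectory.

    Optional Poisson noise is applied in the intensity domain
    (``I = I0 * exp(-p)``) and converted back to line integrals.
    """
    if len(trace) != geometry.n_views:
        raise ValueError(
            f"trace length {len(trace)} != number of views {geometry.n_views}"
        )
    unit_dvf = _unit_displacement(spec).astype(np.float32)
    rng = np.random.default_rng(seed)
    frames = np.empty((geometry.n_views, geometry.n_v, geometry.n_u), dtype=np.float64)
    gt_frames: list[PhantomFrame] = []
    for k in range(geometry.n_views):
        pf = render_frame(spec, trace.values[k], unit_dvf=unit_dvf)
        frames[k] = forward_project(pf.volume, geometry, k)
        if keep_frames:
            gt_frames.append(pf)
    if noise_i0 is not None:
        intensity = noise_i0 * np.exp(-frames)
        noisy = rng.poisson(intensity).astype(np.float64)
        frames = -np.log(np.maximum(noisy, 0.5) / noise_i0)
    return ProjectionSet(geometry, frames), gt_frames
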