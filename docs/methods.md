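# Methods

`dyncbct` reconstructs a *time-resolved* dynamic CBCT sequence — one volume
per acquired projection — from a single, ordinary cone-beam scan, with no
prior anatomical model, no motion model from an earlier session, and no
phase sorting.  This note records the model, the numerical choices, and what
the synthetic test bed does and does not establish.

## Problem decomposition

A dynamic sequence `I(x, p)` (one volume per projection `p`) is far too
underdetermined to solve directly from one 2D projection each.  The package
therefore solves a motion-compensated factorization:

* a **reference-frame volume** `I_ref(x)`, represented by a dense set of 3D
  Gaussian kernels (position, signed amplitude, scale vector + unit
  quaternion ⇒ covariance PSD by construction);
* a **low-rank motion model**: nine motion-basis components (MBCs)
  `e_{i,k}(x)` — three coarse-to-fine spatial levels × three Cartesian
  directions — each a signed scalar field represented by its own Gaussian
  set and voxelized with a *negative-permitting* voxelizer;
* a **CNN motion encoder** mapping each projection image to nine
  coefficients `w_{i,k}(p)`.

The frame for projection `p` is `I(x, p) = I_ref(x + d(x, p))` with
`d_k(x, p) = Σ_i w_{i,k}(p) · e_{i,k}(x)` (backward/pull warping).  Because
`(w, e) → (−w, −e)` leaves every DVF unchanged, solved traces carry a global
sign gauge; evaluation utilities compare traces after a logged sign flip.

## Rendering mathematics

Two differentiable render paths exist, per the training stage:

* **Splatting** (Stage 1): each 3D kernel is carried to ray space by the
  view transform `W` and the local affine approximation `J` of the
  projective map at the kernel mean; marginalizing the ray coordinate gives
  a 2D detector Gaussian with amplitude
  `ρ̂ = ρ · sqrt(2π · det(Σ̃) / det(Σ̂))` — the closed-form line integral of
  an unnormalized Gaussian.  Unit tests pin this constant against numeric
  ray integration; the local-affine error itself is ~0.2% (90th percentile)
  for kernels within ±25 mm of the axis at SAD 1000 mm.
* **Voxelize → warp → project** (Stages 2–3): the reference set is
  voxelized, deformed by the composed DVF, and forward-projected with a
  Joseph-style stepping projector (trilinear samples, step = min voxel
  spacing).  The backprojector is the *exact discrete adjoint* (identical
  traversal and weights), so `⟨Px, y⟩ = ⟨x, Pᵀy⟩` holds to rounding error
  and gradients through DRR generation are exact.

All gradients (voxelizer, splatter, warp, losses, encoder) are hand-derived
vector-Jacobian products in numpy/numba, verified against finite differences
to ≤1e-3 relative error.  No autodiff framework is used.

**Truncation.** Kernels are cut off where the Gaussian falls below 1e-3 of
its amplitude (Mahalanobis radius √(2·ln 1000) ≈ 3.72, <0.4% of the mass
outside).  This radius is what makes the "voxelize equals direct summation
to 1e-3·|ρ|" contract hold exactly; a plain 3σ cutoff would leave
e^{−4.5} ≈ 1.1e-2 tails.

## Training

Stage 1 fits the reference set alone (splatting path, one random projection
per step) under `L1 + 0.25·D-SSIM` plus `0.05 ·` mean anisotropic total
variation of a random 32³ voxelized subvolume.  D-SSIM uses an 11×11
Gaussian window (σ = 1.5), dynamic range from the measured frame.  Adaptive
density control runs every 100 steps between steps 500 and 4000 (reference
set only): kernels with |amplitude| < 2e-4 are pruned; kernels whose mean
positional-gradient norm exceeds a threshold are cloned (if their largest
scale < 8 mm; offset one descent step) or split (scales /1.6, ±0.5σ along
the largest principal axis); amplitudes are halved on densification so the
represented field changes smoothly.  Adam moments restart when the kernel
set is rebuilt.

Stages 2–3 optimize reference, MBCs and encoder jointly through the
voxelize→warp→project chain: Stage 2 at half volume resolution (and
half detector resolution, an efficiency choice of this implementation),
Stage 3 at full resolution — the classic coarse-to-fine registration
schedule.  Batches of 32 (Stage 2) / 8 (Stage 3) projections are drawn
without replacement per epoch cycle; the loss adds the MBC normality term
`(1/9) Σ_{i,k} (mean(e_{i,k}²) − 1)²` (weight 1) to fix the `w·e` scale
gauge, with the norm read as the *voxel mean* square so it is
grid-size-independent.  Optimization flows continuously across stages —
one optimizer state, no reinitialization.

Initialization: FDK (Ram-Lak, optional Hann; Parker or smooth overscan
weighting for short arcs; sinusoidal offset-detector weighting for
half-fan) produces a motion-averaged volume, clamped at zero; reference
kernels start on a ≈M-point lattice with the local FDK intensity as
amplitude (air below 1e-3 mm⁻¹ dropped) and isotropic scales of half the
lattice pitch.  MBC kernels start on uniform lattices (counts M1<M2<M3)
with zero amplitude and scales equal to their lattice pitch (enough overlap
for smooth fields without grid-spanning footprints).  The encoder
(six 3×3 stride-2 conv layers, channels 2–32, BN+ReLU, linear head to 9)
uses He initialization; its nonzero initial outputs are what break the
`w·e = 0` saddle at the start of Stage 2.  Encoder inputs are area-averaged
to 128×96 and standardized per frame; batch statistics are used during
training and running averages at inference, so final coefficients are
deterministic.

Learning rates (Adam): positions 3e-4×scene-extent decayed 10× within each
stage, amplitudes 2e-4 (≈1% of soft tissue per step), scales 5e-3 *in log
space* (multiplicative size updates are far better conditioned than
additive ones), rotations 1e-3, MBC channels 1e-2, encoder 1e-3.  Reference
amplitudes are projected to ≥0 after each step; scales are clipped to
[0.5 mm, lattice pitch] — the upper cap bounds the 3.7σ footprints that
dominate voxelization cost while a pitch-sized kernel can still cover its
lattice cell.  Densification triggers on the top decile of per-kernel
positional-gradient norms (growth-capped), which is robust to the loss
normalization, unlike an absolute threshold.

**Gauge centering.**  The factorization `w·e` determines the DVFs only up
to a static deformation shared by every frame (the reference plus a
constant warp is an equivalent solution, and joint optimization happily
parks part of the anatomy correction there).  At final assembly the
temporal-mean DVF `d̄ = compose(mean_k w_k)` is absorbed into the exported
reference (one warp) and subtracted from the coefficients (and the encoder
head bias), so the reference corresponds to the scan's mean motion state
and per-frame DVFs carry only actual motion — the standard mean-field
centering of low-rank respiratory models.  Frames are still materialized
from the raw reference voxelization with the full deformation
`compose(w_k + w̄)`, which is algebraically identical to the uncentered
frames (the composition is linear in `w`), so centering costs no extra
interpolation in the dynamic volumes; only the exported reference is warped
once.  Without centering, a zero-amplitude scan can show a solved "DVF" of
~2 mm that is purely this static gauge component; with centering it drops
below 1 mm of genuine temporal wobble.

## Synthetic test bed

The phantom is an analytic ellipsoid thorax (body, two lungs, diaphragm
domes, spine cylinder with vertebra/disc modulation, 30 mm spherical tumor
in the right lower lung) with attenuations 0.02/0.004/0.04/0.024 mm⁻¹.
Shape edges are anti-aliased over ~2 mm (partial volume).  Breathing is a
single spatial mode scaled by a scalar trace; each frame is *defined* as a
backward warp of the reference by `a·u(x)`, where `u` is −1 (SI) on a
plateau covering tumor and diaphragm, decays to zero at the lung apex and
body surface, is exactly zero on the dilated spine column (a hard sliding
discontinuity), and has a 0.2-weight AP component in the abdomen.  The
ground-truth DVF is therefore exact by construction, the tumor mask is an
exactly shifted sphere, and warping the reference frame with the
ground-truth DVF reproduces each rendered frame to RE < 0.025
(interpolation only).

Scenario waveforms use `cos⁴` cycles (realistic exhale dwell): S1
quasi-periodic ~5 s / 13 mm; S2 adds a 5 mm mid-scan baseline step; S3
amplitude jitter + drifting baseline; S4 period increasing 4→7 s; S5 a
single `sin⁴` cycle over the whole scan; S6 combined irregularity; S7
20 mm range.  Default scans: 60 s, 360° at 6°/s, full fan, SAD/SDD
1000/1500 mm, noiseless line integrals (optional Poisson model with
configurable I0).

What passing these tests does *not* show: the phantom is rank-1 in motion
with piecewise-smooth anatomy, noiseless projections and a perfectly known
geometry.  Real scans add scatter, beam hardening, lag, multi-mode and
hysteretic motion, and gantry flex; results here bound discretization and
optimization behaviour, not clinical performance.

## Problem sizes

Three presets ship in `ReconConfig.profile`:

* `full`: 200×200×100 voxels at 2 mm, M = 50,000, MBC lattices
  20³/22³/24³, 660 projections (256×192 detector), epochs 5000/1000/1000
  (Stage 2 doubled for half-fan) — the full protocol.
* `desk`: 100×100×50 at 2 mm, M = 8,000 (adaptive growth capped at 12k),
  lattices 6³/8³/10³, 200 projections (128×96 detector), epochs
  800/220/150 — the scale used by `scripts/acceptance.py`, chosen so a
  complete two-scenario evaluation (simulation, reconstruction and
  frame-by-frame scoring) runs in well under half an hour on one CPU core.
* test fixtures are smaller still (see `tests/`), sized for suite turnaround.

## Known limitations

* No diffeomorphic/invertibility constraint on the DVFs (none is imposed by
  the model); folding is possible in principle.
* Uniform regions of the Gaussian reference can show mild intensity
  inhomogeneity — a known property of splatting-type representations.
* The FDK half-fan weighting assumes the overlap band is detector-centered
  after the lateral offset; exotic asymmetric detectors are untested.
* Single-threaded by design for bit-reproducibility; wall-clock numbers
  scale accordingly.
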