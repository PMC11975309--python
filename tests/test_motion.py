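"""Motion model: basis voxelization, DVF composition, warping, normality."""

import numpy as np
import pytest

from dyncbct.geometry import DisplacementField, Volume, VolumeGrid
from dyncbct.motion import (
    MBCLevel,
    MBCModel,
    compose_dvf,
    normality_loss,
    upsample_basis,
    voxelize_mbcs,
    warp,
)


def small_mbc(grid, n=(2, 3, 4)):
    return MBCModel.initialize(grid, n)


@pytest.fixture
def mbc_grid():
    return VolumeGrid.centered((9, 9, 9), 4.0)


class TestVoxelizeMBCs:
    def test_zero_densities_zero_fields(self, mbc_grid):
        basis = voxelize_mbcs(small_mbc(mbc_grid))
        assert basis.shape == (3, 3, 9, 9, 9)
        assert np.all(basis == 0)

    def test_single_channel_kernel(self, mbc_grid):
        model = small_mbc(mbc_grid)
        lv = model.levels[0]
        lv.positions[0] = [0.0, 0.0, 0.0]
        lv.channels[0] = [2.0, 0.0, 0.0]
        basis = voxelize_mbcs(model)
        assert basis[0, 0][4, 4, 4] == pytest.approx(2.0)
        assert np.all(basis[0, 1] == 0) and np.all(basis[0, 2] == 0)

    def test_negative_density_survives(self, mbc_grid):
        model = small_mbc(mbc_grid)
        model.levels[0].channels[:, 2] = -1.0
        basis = voxelize_mbcs(model)
        assert basis[0, 2].min() < -0.5

    def test_level_counts_must_increase(self, mbc_grid):
        levels = small_mbc(mbc_grid).levels
        with pytest.raises(ValueError):
            MBCModel([levels[2], levels[1], levels[0]], mbc_grid)


class TestComposeDVF:
    def test_zero_coefficients(self, mbc_grid, rng):
        basis = rng.standard_normal((3, 3, 9, 9, 9))
        d = compose_dvf(basis, np.zeros(9), mbc_grid, mbc_grid)
        assert np.all(d.vectors == 0)

    def test_basis_selection(self, mbc_grid, rng):
        basis = rng.standard_normal((3, 3, 9, 9, 9))
        w = np.zeros(9)
        w[0] = 1.0  # level 1, x direction
        d = compose_dvf(basis, w, mbc_grid, mbc_grid)
        np.testing.assert_array_equal(d.vectors[..., 0], basis[0, 0])
        assert np.all(d.vectors[..., 1] == 0) and np.all(d.vectors[..., 2] == 0)

    def test_exact_linearity(self, mbc_grid, rng):
        basis = rng.standard_normal((3, 3, 9, 9, 9))
        out_grid = VolumeGrid.centered((17, 17, 17), 2.0)
        w = rng.standard_normal(9)
        d1 = compose_dvf(basis, w, mbc_grid, out_grid).vectors
        d2 = compose_dvf(basis, 2 * w, mbc_grid, out_grid).vectors
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-14)

    def test_sign_gauge_invariance(self, mbc_grid, rng):
        basis = rng.standard_normal((3, 3, 9, 9, 9))
        w = rng.standard_normal(9)
        d1 = compose_dvf(basis, w, mbc_grid, mbc_grid).vectors
        d2 = compose_dvf(-basis, -w, mbc_grid, mbc_grid).vectors
        np.testing.assert_allclose(d1, d2, atol=1e-14)


class TestWarp:
    def test_identity_on_zero_dvf(self, rng):
        grid = VolumeGrid.centered((12, 10, 8), 2.0)
        vol = Volume(grid, rng.random(grid.shape))
        out = warp(vol, DisplacementField(grid, np.zeros(grid.shape + (3,))))
        np.testing.assert_array_equal(out.values, vol.values)

    def test_constant_shift_on_ramp(self):
        grid = VolumeGrid.centered((20, 10, 8), 1.0)
        x, _, _ = grid.meshgrid()
        vol = Volume(grid, x.copy())
        vec = np.zeros(grid.shape + (3,))
        vec[..., 0] = 2.0
        out = warp(vol, DisplacementField(grid, vec))
        interior = slice(2, -3)
        np.testing.assert_allclose(
            out.values[interior], vol.values[interior] + 2.0, atol=1e-12
        )

    def test_smooth_field_rms_error(self, rng):
        # analytic smooth test field displaced by a smooth DVF (<= 10 mm)
        grid = VolumeGrid.centered((30, 30, 20), 2.0)
        x, y, z = grid.meshgrid()

        def f(px, py, pz):
            return np.sin(px / 17.0) * np.cos(py / 23.0) + 0.1 * pz / 20.0

        vec = np.stack([
            5 * np.sin(y / 30.0), 4 * np.cos(x / 25.0), 3 * np.sin((x + y) / 40.0)
        ], axis=-1)
        vol = Volume(grid, f(x, y, z))
        out = warp(vol, DisplacementField(grid, vec))
        exact = f(x + vec[..., 0], y + vec[..., 1], z + vec[..., 2])
        b = 3  # ignore the edge-clamped border
        err = out.values[b:-b, b:-b, b:-b] - exact[b:-b, b:-b, b:-b]
        rms = np.sqrt((err**2).mean()) / np.sqrt((exact[b:-b, b:-b, b:-b] ** 2).mean())
        assert rms < 0.01

    def test_grid_mismatch(self, rng):
        g1 = VolumeGrid.centered((8, 8, 8), 2.0)
        g2 = VolumeGrid.centered((8, 8, 8), 3.0)
        with pytest.raises(ValueError):
            warp(Volume(g1, np.zeros(g1.shape)),
                 DisplacementField(g2, np.zeros(g2.shape + (3,))))

    def test_phantom_ground_truth_consistency(self):
        from dyncbct.metrics import relative_error
        from dyncbct.phantom import PhantomSpec, render_frame

        grid = VolumeGrid.centered((64, 64, 32), 3.0)
        spec = PhantomSpec.default(grid)
        ref = render_frame(spec, 0.0)
        moved = render_frame(spec, 10.0)
        warped = warp(Volume(grid, ref.volume.values.astype(np.float64)), moved.gt_dvf)
        re = relative_error([warped], [Volume(grid, moved.volume.values.astype(np.float64))])
        assert re < 0.05


class TestNormalityLoss:
    def test_unit_mean_square_is_zero(self):
        basis = np.ones((3, 3, 4, 4, 4))
        assert normality_loss(basis) == pytest.approx(0.0)

    def test_all_zero_bases(self):
        assert normality_loss(np.zeros((3, 3, 4, 4, 4))) == pytest.approx(1.0)

    def test_one_basis_off(self):
        basis = np.ones((3, 3, 4, 4, 4))
        basis[0, 0] = np.sqrt(2.0)  # mean square 2 for one of the nine
        assert normality_loss(basis) == pytest.approx(1.0 / 9.0)
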