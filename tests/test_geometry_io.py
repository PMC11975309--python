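"""Containers, trajectory construction and file round trips."""

import numpy as np
import pytest

from dyncbct.geometry import (
    ProjectionSet,
    ScanGeometry,
    Volume,
    VolumeGrid,
    make_circular_trajectory,
)
from dyncbct.io import read_projections, read_volume, write_projections, write_volume


class TestTrajectory:
    def test_clinical_protocol_sampling(self):
        # 60 s at 11 fps over 360 degrees -> 660 views at 6 deg/s
        angles, times = make_circular_trajectory(0, 360, 60, 11)
        assert len(angles) == 660
        assert angles[-1] < 360
        assert np.allclose(np.diff(times), 1 / 11)
        assert np.allclose(np.diff(angles), 360 / 60 / 11)

    def test_single_sample(self):
        angles, times = make_circular_trajectory(0, 360, 1, 1)
        assert len(angles) == 1 and angles[0] == 0

    def test_fractional_fps(self):
        angles, _ = make_circular_trajectory(0, 200, 300, 5.5)
        assert len(angles) == 1650
        assert angles[-1] < 200

    @pytest.mark.parametrize("bad", [(0, -1, 60, 11), (0, 360, 0, 11), (0, 360, 60, 0)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            make_circular_trajectory(*bad)


class TestScanGeometry:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ScanGeometry(sad=1500, sdd=1000, n_u=4, n_v=4, pixel_u=1, pixel_v=1,
                         angles=[0], times=[0])
        with pytest.raises(ValueError):
            ScanGeometry(sad=1000, sdd=1500, n_u=4, n_v=4, pixel_u=1, pixel_v=1,
                         fan_mode="full", detector_offset_u=10.0, angles=[0], times=[0])
        with pytest.raises(ValueError):
            ScanGeometry(sad=1000, sdd=1500, n_u=4, n_v=4, pixel_u=1, pixel_v=1,
                         angles=[0, 1], times=[1.0, 0.5])

    def test_detector_v_axis_is_si(self):
        geo = ScanGeometry(sad=1000, sdd=1500, n_u=4, n_v=4, pixel_u=1, pixel_v=1,
                           angles=[0.0, 90.0], times=[0.0, 1.0])
        for k in range(2):
            assert np.allclose(geo.view_matrix(k)[1], [0, 0, 1])


class TestVolumeIO:
    @pytest.mark.parametrize("suffix", [".mha", ".nii.gz"])
    def test_round_trip(self, tmp_path, rng, suffix):
        grid = VolumeGrid(5, 4, 3, spacing=(1, 1, 3), origin=(-2, 0, 1))
        vol = Volume(grid, rng.integers(0, 100, grid.shape).astype(np.float64))
        path = tmp_path / ("vol" + suffix)
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.values, vol.values)
        assert np.allclose(back.grid.spacing, (1, 1, 3))
        assert np.allclose(back.grid.origin, (-2, 0, 1))

    def test_simple_content(self, tmp_path):
        grid = VolumeGrid(2, 2, 2, spacing=(2, 2, 2), origin=(0, 0, 0))
        write_volume(Volume(grid, np.ones((2, 2, 2))), tmp_path / "ones.mha")
        back = read_volume(tmp_path / "ones.mha")
        assert back.values.sum() == 8
        assert back.grid.spacing == (2.0, 2.0, 2.0)

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.mha"
        path.write_bytes(b"")
        with pytest.raises(ValueError):
            read_volume(path)

    def test_unsupported_format(self, tmp_path):
        with pytest.raises(ValueError, match="unsupported"):
            read_volume(tmp_path / "vol.xyz")

    def test_nan_refused(self, tmp_path):
        grid = VolumeGrid(2, 2, 2, spacing=(1, 1, 1), origin=(0, 0, 0))
        vol = Volume(grid, np.ones((2, 2, 2)))
        vol.values[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            write_volume(vol, tmp_path / "bad.mha")


class TestProjectionIO:
    def test_round_trip(self, tmp_path, rng):
        geo = ScanGeometry(sad=1000, sdd=1500, n_u=6, n_v=5, pixel_u=2, pixel_v=2,
                           angles=[0.0, 10.0, 20.0], times=[0.0, 1.0, 2.0])
        pset = ProjectionSet(geo, rng.random((3, 5, 6)).astype(np.float32))
        path = tmp_path / "proj.tif"
        write_projections(pset, path)
        back = read_projections(path)
        np.testing.assert_array_equal(back.frames, pset.frames)
        np.testing.assert_allclose(back.geometry.angles, geo.angles)
        np.testing.assert_allclose(back.geometry.times, geo.times)

    def test_count_mismatch(self):
        geo = ScanGeometry(sad=1000, sdd=1500, n_u=4, n_v=4, pixel_u=1, pixel_v=1,
                           angles=np.arange(5.0), times=np.arange(5.0))
        with pytest.raises(ValueError):
            ProjectionSet(geo, np.zeros((4, 4, 4)))


def test_point_location_consistency():
    """A point object is located at the same world position by the voxelizer,
    the phantom grid mapping and the warper (shared coordinate convention)."""
    from dyncbct.gaussians import GaussianSet, voxelize
    from dyncbct.motion import warp
    from dyncbct.geometry import DisplacementField

    grid = VolumeGrid.centered((11, 11, 11), 2.0)
    target_world = np.array([4.0, -2.0, 6.0])
    idx = grid.world_to_index(target_world)
    assert np.allclose(grid.index_to_world(idx), target_world, atol=1e-9)
    gset = GaussianSet([target_world], [1.0], [[1.5, 1.5, 1.5]], [[1, 0, 0, 0]])
    vol = voxelize(gset, grid)
    peak = np.unravel_index(np.argmax(vol.values), vol.values.shape)
    assert np.allclose(grid.index_to_world(peak), target_world, atol=1e-9)
    # warping by an exact multiple of the spacing relocates the peak exactly
    shift = DisplacementField(grid, np.tile([2.0, 0.0, 0.0], grid.shape + (1,)))
    moved = warp(vol, shift)
    peak2 = np.unravel_index(np.argmax(moved.values), moved.values.shape)
    assert np.allclose(grid.index_to_world(peak2), target_world - [2, 0, 0], atol=1e-9)


def test_gaussian_set_npz_round_trip(tmp_path, rng):
    from dyncbct.gaussians import GaussianSet
    from dyncbct.io import load_gaussians, save_gaussians

    gset = GaussianSet(
        rng.standard_normal((5, 3)), rng.standard_normal(5),
        rng.uniform(1, 3, (5, 3)), rng.standard_normal((5, 4)),
    )
    path = tmp_path / "kernels.npz"
    save_gaussians(gset, path)
    back = load_gaussians(path)
    np.testing.assert_array_equal(back.positions, gset.positions)
    np.testing.assert_array_equal(back.densities, gset.densities)
    np.testing.assert_array_equal(back.scales, gset.scales)
    np.testing.assert_array_equal(back.quaternions, gset.quaternions)
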