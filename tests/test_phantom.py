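"""Synthetic 4D thorax phantom: traces, analytic DVFs, rendering, simulation."""

import numpy as np
import pytest

from dyncbct.geometry import Volume, VolumeGrid
from dyncbct.metrics import relative_error
from dyncbct.motion import warp
from dyncbct.phantom import (
    PhantomSpec,
    analytic_dvf,
    make_trace,
    render_frame,
    simulate_scan,
)

from conftest import make_scan_geometry


@pytest.fixture(scope="module")
def spec():
    return PhantomSpec.default(VolumeGrid.centered((64, 64, 32), 3.0))


class TestTraces:
    def test_s1_protocol(self):
        tr = make_trace("S1", 60, 11, seed=0)
        assert len(tr) == 660
        assert tr.values.max() - tr.values.min() == pytest.approx(13.0, abs=1.0)

    def test_s2_baseline_shift(self):
        tr = make_trace("S2", 60, 11, seed=0)
        n = len(tr) // 2
        shift = tr.values[n:].mean() - tr.values[:n].mean()
        assert shift == pytest.approx(5.0, abs=1.5)

    def test_s5_single_cycle(self):
        tr = make_trace("S5", 60, 11, seed=0)
        from scipy.ndimage import uniform_filter1d

        smooth = uniform_filter1d(tr.values, 11)
        interior = smooth[5:-5]
        peaks = (interior[1:-1] > interior[:-2]) & (interior[1:-1] > interior[2:])
        assert peaks.sum() == 1

    def test_s7_extended_range(self):
        tr = make_trace("S7", 60, 11, seed=0)
        assert tr.values.max() - tr.values.min() == pytest.approx(20.0, abs=1.5)

    def test_s4_period_increases(self):
        tr = make_trace("S4", 60, 11, seed=0)
        v = tr.values
        peaks = np.where((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]) & (v[1:-1] > 8))[0]
        gaps = np.diff(peaks) / 11.0
        assert gaps[-1] > gaps[0]

    @pytest.mark.parametrize("scenario", [f"S{i}" for i in range(1, 8)])
    def test_deterministic(self, scenario):
        a = make_trace(scenario, 30, 5, seed=7)
        b = make_trace(scenario, 30, 5, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            make_trace("S9", 60, 11, seed=0)


class TestAnalyticDVF:
    def test_zero_trace_zero_field(self, spec):
        d = analytic_dvf(spec, 0.0)
        assert np.all(d.vectors == 0)

    def test_magnitudes_at_landmarks(self, spec):
        d = analytic_dvf(spec, 10.0)
        grid = spec.grid
        ci = np.round(grid.world_to_index(np.array(spec.tumor_center))).astype(int)
        assert abs(d.vectors[tuple(ci) + (2,)]) == pytest.approx(10.0)
        si = np.round(grid.world_to_index([0.0, spec.spine_center_y, 0.0])).astype(int)
        assert np.all(d.vectors[tuple(si)] == 0.0)

    def test_linearity(self, spec):
        d1 = analytic_dvf(spec, 4.0).vectors
        d2 = analytic_dvf(spec, 8.0).vectors
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-12)

    def test_zero_outside_body(self, spec):
        d = analytic_dvf(spec, 13.0)
        x, y, z = spec.grid.meshgrid()
        outside = ~spec.body.inside(x, y, z)
        assert np.all(d.vectors[outside] == 0)


class TestRenderFrame:
    def test_reference_at_zero(self, spec):
        f = render_frame(spec, 0.0)
        idx = np.argwhere(f.tumor_mask)
        com = np.asarray(spec.grid.origin) + idx.mean(0) * np.asarray(spec.grid.spacing)
        np.testing.assert_allclose(com, spec.tumor_center, atol=1.0)

    def test_tumor_mask_tracks_trace(self, spec):
        f0 = render_frame(spec, 0.0)
        f10 = render_frame(spec, 10.0)

        def com(mask):
            idx = np.argwhere(mask)
            return np.asarray(spec.grid.origin) + idx.mean(0) * np.asarray(spec.grid.spacing)

        shift = com(f10.tumor_mask) - com(f0.tumor_mask)
        assert shift[2] == pytest.approx(10.0, abs=0.5 * spec.grid.spacing[2])
        assert abs(shift[0]) < 0.5 and abs(shift[1]) < 0.5

    def test_attenuation_range(self, spec):
        f = render_frame(spec, 7.0)
        assert f.volume.values.min() >= 0.0
        assert f.volume.values.max() <= 0.05

    def test_warp_consistency(self, spec):
        ref = render_frame(spec, 0.0)
        for a in (7.0, 15.0):
            fr = render_frame(spec, a)
            warped = warp(Volume(spec.grid, ref.volume.values.astype(np.float64)), fr.gt_dvf)
            re = relative_error([warped], [Volume(spec.grid, fr.volume.values.astype(np.float64))])
            assert re < 0.05, a


class TestSimulateScan:
    def test_projection_count_and_determinism(self, spec):
        geo = make_scan_geometry(n_views=12, n_u=64, n_v=48, pixel=6.4)
        tr = make_trace("S1", 60, 12 / 60, seed=0)
        p1, frames = simulate_scan(spec, tr, geo, seed=0)
        p2, _ = simulate_scan(spec, tr, geo, seed=0, keep_frames=False)
        assert p1.frames.shape[0] == 12
        assert len(frames) == 12
        np.testing.assert_array_equal(p1.frames, p2.frames)

    def test_zero_amplitude_static(self, spec):
        geo = make_scan_geometry(n_views=6, n_u=64, n_v=48, pixel=6.4)
        from dyncbct.phantom import BreathingTrace

        tr = BreathingTrace(geo.times, np.zeros(6), "S1")
        _, frames = simulate_scan(spec, tr, geo, seed=0)
        for f in frames[1:]:
            np.testing.assert_array_equal(f.volume.values, frames[0].volume.values)

    def test_length_mismatch(self, spec):
        geo = make_scan_geometry(n_views=6, n_u=64, n_v=48, pixel=6.4)
        tr = make_trace("S1", 60, 11, seed=0)
        with pytest.raises(ValueError):
            simulate_scan(spec, tr, geo)

    def test_poisson_noise_changes_but_preserves_signal(self, spec):
        geo = make_scan_geometry(n_views=4, n_u=64, n_v=48, pixel=6.4)
        from dyncbct.phantom import BreathingTrace

        tr = BreathingTrace(geo.times, np.zeros(4), "S1")
        clean, _ = simulate_scan(spec, tr, geo, seed=0, keep_frames=False)
        noisy, _ = simulate_scan(spec, tr, geo, noise_i0=1e5, seed=0, keep_frames=False)
        assert not np.array_equal(clean.frames, noisy.frames)
        assert np.abs(noisy.frames - clean.frames).mean() < 0.05

    def test_tumor_com_trace_matches_input(self, spec):
        geo = make_scan_geometry(n_views=16, n_u=64, n_v=48, pixel=6.4)
        tr = make_trace("S1", 60, 16 / 60, seed=0)
        _, frames = simulate_scan(spec, tr, geo, seed=0)
        si = []
        for f in frames:
            idx = np.argwhere(f.tumor_mask)
            si.append((np.asarray(spec.grid.origin) + idx.mean(0) * np.asarray(spec.grid.spacing))[2])
        si = np.array(si)
        ref_si = si[np.argmin(np.abs(tr.values))]
        err = np.abs((si - ref_si) - (tr.values - tr.values.min()))
        assert err.max() <= 0.5 * spec.grid.spacing[2] + 1e-9
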