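import numpy as np
import pytest

from dyncbct.geometry import ScanGeometry, VolumeGrid, make_circular_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return VolumeGrid.centered((16, 16, 12), 2.0)


@pytest.fixture
def single_view_geometry():
    return ScanGeometry(
        sad=1000.0, sdd=1500.0, n_u=32, n_v=32, pixel_u=2.0, pixel_v=2.0,
        angles=[20.0], times=[0.0],
    )


def make_scan_geometry(n_views=60, arc=360.0, n_u=128, n_v=96, pixel=3.2, duration=60.0):
    angles, times = make_circular_trajectory(0.0, arc, duration, n_views / duration)
    return ScanGeometry(
        sad=1000.0, sdd=1500.0, n_u=n_u, n_v=n_v, pixel_u=pixel, pixel_v=pixel,
        angles=angles, times=times,
    )
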