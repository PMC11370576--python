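import numpy as np
import pytest

from motiflux import Track, TrackPoint


@pytest.fixture
def l_track() -> Track:
    """An L-shaped 3-4-5 track: steps of 3 and 4 μm, 10 s apart."""
    return Track(
        fov_id="fov0",
        track_id="t0",
        points=(
            TrackPoint(0.0, 0.0, 0.0),
            TrackPoint(10.0, 3.0, 0.0),
            TrackPoint(20.0, 3.0, 4.0),
        ),
    )


def random_track(rng: np.random.Generator, n_points: int = 12) -> Track:
    """A random strictly-timed planar track for property tests."""
    t = np.cumsum(rng.uniform(1.0, 10.0, size=n_points))
    xy = np.cumsum(rng.normal(0, 3.0, size=(n_points, 2)), axis=0) + 100
    pts = tuple(TrackPoint(float(ti), float(x), float(y)) for ti, (x, y) in zip(t, xy))
    return Track(fov_id="f", track_id="r", points=pts)
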