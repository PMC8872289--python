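import numpy as np
import pytest

from divtrack.tracks import Track, TrackSet


def make_track(track_id, coords, frames=None, **kw):
    coords = np.asarray(coords, dtype=float)
    if frames is None:
        frames = np.arange(len(coords))
    return Track(track_id=track_id, frames=frames, xy=coords, **kw)


@pytest.fixture
def simple_trackset():
    """Three short tracks with known displacements at 24 ms framing."""
    tracks = [
        make_track(0, [(0, 0), (0.3, 0.4), (1.0, 1.0)]),            # SQD 0.25 then dummy end
        make_track(1, [(0, 0), (0, 0), (0, 0), (0, 0)]),            # stationary
        make_track(2, [(0, 0), (0.1, 0), (0.2, 0)], frames=[0, 1, 4]),  # gap
    ]
    return TrackSet(tracks=tracks, frame_interval=0.024, condition="test")
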