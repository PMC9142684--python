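import numpy as np
import pytest

from neurotrack import simulator
from neurotrack.io import SessionExtraction


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def point_session(centers, fov=(20, 20), traces=None, session_id=""):
    """Session whose footprints are 3x3 blobs at the given (row, col) centers."""
    d = fov[0] * fov[1]
    fps = []
    for r, c in centers:
        img = np.zeros(fov)
        img[r - 1: r + 2, c - 1: c + 2] = 0.5
        img[r, c] = 1.0
        fps.append(img.ravel())
    footprints = np.stack(fps, axis=1)
    if traces is None:
        traces = np.abs(np.random.default_rng(0).normal(size=(len(centers), 50)))
    return SessionExtraction(
        footprints=footprints, traces=np.asarray(traces, float),
        fov_shape=fov, session_id=session_id,
    )


@pytest.fixture
def tiny_dataset():
    """Small noiseless shifted two-session dataset with links and truth."""
    cfg = simulator.style_config(
        "individual_shift", n_neurons=15, frames_per_session=600, seed=7
    )
    sessions, links, truth, _ = simulator.make_dataset("individual_shift", cfg)
    return sessions, links, truth
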