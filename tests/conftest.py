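"""Shared fixtures: seeded RNGs and random-but-valid landmark data."""

import numpy as np
import pytest

from prefdyn.types import N_LANDMARKS, LandmarkFrame, LandmarkVideo
from prefdyn.synth import make_template_face


@pytest.fixture
def rng():
    return np.random.default_rng(20240204)


def random_frame(rng, index=0, jitter=5.0):
    """A valid 66-point frame: the template plus Gaussian perturbation.

    Using the template guarantees well-separated eye clusters, so the
    frame is always normalizable.
    """
    pts = make_template_face().points + rng.normal(0, jitter, (N_LANDMARKS, 2))
    return LandmarkFrame(index=index, points=pts)


def random_video(rng, n_frames=10, jitter=5.0, **meta):
    meta = {
        "fps": 24.0,
        "domain": "people",
        "target_id": 1,
        "pair_id": 1,
        "slot": 1,
        **meta,
    }
    frames = tuple(random_frame(rng, index=i, jitter=jitter) for i in range(n_frames))
    return LandmarkVideo(frames=frames, **meta)


@pytest.fixture
def frame_factory(rng):
    return lambda **kw: random_frame(rng, **kw)


@pytest.fixture
def video_factory(rng):
    return lambda **kw: random_video(rng, **kw)
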