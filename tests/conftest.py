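"""Shared fixtures: cached scenario renders and tracking runs.

Rendering and (especially) tracking are the expensive steps, so both are
memoized per parameter tuple and shared across test modules.
"""

from functools import lru_cache

import numpy as np
import pytest

from wormtrack.fixtures import NoiseBlob, ScenarioSpec, render_sequence
from wormtrack.tracker import track_sequence


@lru_cache(maxsize=None)
def _render(event: str, n_worms: int, seed: int, n_frames: int = 30,
            noise: bool = False):
    blobs = (NoiseBlob(center=(60.0, 140.0)),) if noise else ()
    spec = ScenarioSpec(n_worms=n_worms, n_frames=n_frames, event=event,
                        seed=seed, noise_blobs=blobs)
    return render_sequence(spec)


@lru_cache(maxsize=None)
def _track(event: str, n_worms: int, seed: int, config: str = "OCpCl",
           n_frames: int = 30):
    seq, truth = _render(event, n_worms, seed, n_frames)
    return track_sequence(seq, config), truth, seq


@pytest.fixture(scope="session")
def render():
    return _render


@pytest.fixture(scope="session")
def track():
    return _track


@pytest.fixture(scope="session")
def one_worm():
    """A single separated worm, 30 frames."""
    return _render("none", 1, 1)


@pytest.fixture(scope="session")
def two_worms_apart():
    """Two worms that never touch."""
    return _render("none", 2, 3)


@pytest.fixture(scope="session")
def crossing():
    """Two worms crossing mid-sequence."""
    return _render("cross", 2, 7)


@pytest.fixture(scope="session")
def parallel():
    """Two worms aggregating side by side mid-sequence."""
    return _render("parallel_bodies", 2, 2)


def straight_tube(length: int = 20, halfwidth: int = 1, gray: int = 20,
                  shape=(40, 60), origin=(18, 10)):
    """A horizontal constant-gray tube mask + frame, for unit tests."""
    frame = np.full(shape, 120, np.uint8)
    mask = np.zeros(shape, bool)
    r0, c0 = origin
    mask[r0 - halfwidth:r0 + halfwidth + 1, c0:c0 + length] = True
    frame[mask] = gray
    return frame, mask
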