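"""Shared fixtures and helpers for the pouchtrack test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pouchtrack import Track


def random_track(rng: np.random.Generator, n_points: int = 10,
                 track_id: str = "t0", group: str = "g") -> Track:
    """A track with iid-normal displacements, for oracle comparisons."""
    t = np.arange(n_points) * 10.0
    x = np.cumsum(rng.normal(0.0, 3.0, n_points))
    y = np.cumsum(rng.normal(0.0, 3.0, n_points))
    return Track(track_id, group, t, x, y)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
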