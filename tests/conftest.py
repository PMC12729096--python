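"""Shared fixtures: screen geometry and programmatic gaze-stream builders."""

from __future__ import annotations

import numpy as np
import pytest

from atcgaze.geometry import ScreenGeometry
from atcgaze.io import GazeStream

PERIOD_MS = 1000.0 / 30.0


@pytest.fixture
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


def make_stream(x_cm, y_cm, valid=None, pupil=3.4, geometry=None,
                left_valid=None, right_valid=None) -> GazeStream:
    """Build a 30 Hz stream from position arrays; invalid samples get NaNs."""
    x = np.asarray(x_cm, dtype=float)
    y = np.asarray(y_cm, dtype=float)
    n = x.size
    if valid is None:
        valid = np.ones(n, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    lv = valid if left_valid is None else np.asarray(left_valid, bool)
    rv = valid if right_valid is None else np.asarray(right_valid, bool)
    pupil = np.broadcast_to(np.asarray(pupil, float), (n,)).copy()
    return GazeStream(
        t_ms=np.arange(n) * PERIOD_MS,
        left_valid=lv, right_valid=rv,
        x_cm=x.copy(), y_cm=y.copy(),
        pupil_left_mm=pupil.copy(), pupil_right_mm=pupil.copy(),
        geometry=geometry or ScreenGeometry(),
    )


def random_walk_stream(rng: np.random.Generator, n: int = 500,
                       p_invalid: float = 0.05, step_cm: float = 0.45,
                       jump_p: float = 0.06) -> GazeStream:
    """Jittered random-walk gaze with occasional large saccadic jumps."""
    steps = rng.normal(0, step_cm, size=(n, 2))
    jumps = rng.uniform(-8, 8, size=(n, 2)) * (rng.uniform(size=(n, 1)) < jump_p)
    pos = np.clip(np.cumsum(steps + jumps, axis=0) + np.array([30.0, 17.0]),
                  0.5, 33.0)
    valid = rng.uniform(size=n) > p_invalid
    return make_stream(pos[:, 0], pos[:, 1], valid=valid)
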