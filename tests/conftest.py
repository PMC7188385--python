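import numpy as np
import pytest

import gridlink as gl


@pytest.fixture(scope="session")
def puzzle_4444():
    """A fixed seeded (4, 4, 4, 4) puzzle with its reference solution."""
    return gl.generate_puzzle(gl.DifficultyLevel(4, 4, 4, 4), gl.GenerationConfig(seed=11))


@pytest.fixture(scope="session")
def puzzle_5555():
    return gl.generate_puzzle(gl.DifficultyLevel(5, 5, 5, 5), gl.GenerationConfig(seed=11))


@pytest.fixture()
def geometry(puzzle_4444):
    return gl.default_geometry(puzzle_4444)


@pytest.fixture()
def perfect_profile():
    """No noise, no pauses, no errors: every metric is predictable."""
    return gl.PlayerProfile(drag_speed=1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def turn_scan_oracle(cells):
    """Independent direction-difference scan used as the turn oracle."""
    dirs = [
        (b.col - a.col, b.row - a.row) for a, b in zip(cells, cells[1:])
    ]
    return sum(1 for d1, d2 in zip(dirs, dirs[1:]) if d1 != d2)
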