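import numpy as np
import pytest

from camsim import Domain, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def disc():
    return Domain(kind="disc", R=5.0)


@pytest.fixture
def annulus():
    return Domain(kind="annulus", R=5.0, R_in=3.5)


def triangular_lattice(radius: float, spacing: float = 1.0) -> np.ndarray:
    """Points of a triangular lattice inside a disc of the given radius."""
    pts = []
    rows = int(np.ceil(radius / (spacing * np.sqrt(3) / 2))) + 1
    cols = int(np.ceil(radius / spacing)) + 1
    for row in range(-rows, rows + 1):
        y = row * spacing * np.sqrt(3) / 2
        off = spacing / 2 if row % 2 else 0.0
        for col in range(-cols, cols + 1):
            x = col * spacing + off
            if x * x + y * y <= radius * radius:
                pts.append((x, y))
    return np.array(pts)


@pytest.fixture
def lattice():
    return triangular_lattice
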