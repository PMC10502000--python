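"""Shared fixtures: tiny grids, annotations, and a cached small phantom."""

from __future__ import annotations

import numpy as np
import pytest

from gutgaze.annotation import ScanAnnotation, VisualSegment
from gutgaze.phantom import generate_phantom
from gutgaze.reconstruction import VolumeGrid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_grid():
    return VolumeGrid((9, 9, 5), (1.0, 1.0, 1.0))


@pytest.fixture()
def straight_annotation():
    """One straight 3 mm segment along z through the center of a 9x9x5 grid."""
    seg = VisualSegment.from_arrays(
        np.array([[4.0, 4.0, 0.0], [4.0, 4.0, 4.0]]), 3.0, label=4
    )
    return ScanAnnotation("straight", 1, (seg,))


def random_annotation(rng: np.random.Generator, max_segments=4, max_points=10):
    segments = []
    for _ in range(rng.integers(1, max_segments + 1)):
        n = int(rng.integers(1, max_points + 1))
        pos = rng.uniform(-5.0, 30.0, (n, 3))
        diam = rng.uniform(1.0, 15.0, n)
        segments.append(VisualSegment.from_arrays(pos, diam, int(rng.integers(1, 14))))
    return ScanAnnotation("random", 1, tuple(segments))


def random_grid(rng: np.random.Generator, max_side=24):
    return VolumeGrid(
        tuple(int(n) for n in rng.integers(4, max_side + 1, 3)),
        tuple(rng.uniform(0.5, 3.0, 3)),
        tuple(rng.uniform(-5.0, 5.0, 3)),
    )


@pytest.fixture(scope="session")
def small_phantom():
    """A 64^3, 1 mm phantom with two modest tubes; shared across tests."""
    grid = VolumeGrid((64, 64, 64), (1.0, 1.0, 1.0))
    return generate_phantom(
        n_tubes=2, grid=grid, seed=7, diameter_range=(10.0, 20.0), noise_sd=10.0
    )
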