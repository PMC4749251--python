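import dataclasses

import numpy as np
import pytest

from octmac.phantom import PhantomSpec


@pytest.fixture(scope="session")
def small_spec():
    """A quick phantom for unit tests (not the acceptance-scale volume)."""
    return PhantomSpec(shape=(32, 8, 64))


@pytest.fixture(scope="session")
def clean_small_spec(small_spec):
    """Same geometry, no noise, no blur, constant per-layer intensities."""
    return dataclasses.replace(small_spec, speckle_shape=0.0, floor_sd=0.0,
                               axial_blur_sigma=0.0, modulate=False)


def dp_oracle_two_rows(cost: np.ndarray, dx: int, dy: int) -> int:
    """Exact minimum over all feasible surfaces of a (X, 2, D) cost volume.

    Independent oracle for the graph solver: exhaustive dynamic programming
    over x with the joint state (z at y=0, z at y=1); exact because a 2-row
    grid's constraint graph is a chain of column pairs.
    """
    X, Y, D = cost.shape
    assert Y == 2
    states = [(a, b) for a in range(D) for b in range(D) if abs(a - b) <= dy]
    prev = {st: cost[0, 0, st[0]] + cost[0, 1, st[1]] for st in states}
    for x in range(1, X):
        cur = {}
        for st in states:
            best = min(prev[pt] for pt in states
                       if abs(st[0] - pt[0]) <= dx and abs(st[1] - pt[1]) <= dx)
            cur[st] = best + cost[x, 0, st[0]] + cost[x, 1, st[1]]
        prev = cur
    return min(prev.values())


def surface_total_cost(cost: np.ndarray, z: np.ndarray) -> int:
    X, Y, _ = cost.shape
    return int(cost[np.arange(X)[:, None], np.arange(Y)[None, :], z].sum())
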