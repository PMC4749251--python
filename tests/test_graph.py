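import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octmac.graph import InfeasibleError, banded_optimal_surface, dp_surface, \
    find_optimal_surface, propagate_bounds
from .conftest import dp_oracle_two_rows, surface_total_cost


def test_single_column_is_argmin():
    cost = np.array([[[5, 1, 3, 2, 9, 0]]])
    z = find_optimal_surface(cost, dx=1, dy=1)
    assert z[0, 0] == 5


def test_flat_surface_under_zero_smoothness():
    """dx = dy = 0 forces a flat surface at the depth minimizing the summed cost."""
    rng = np.random.default_rng(0)
    cost = rng.integers(0, 100, (6, 3, 12))
    z = find_optimal_surface(cost, dx=0, dy=0)
    assert (z == z[0, 0]).all()
    best_flat = cost.sum(axis=(0, 1)).argmin()
    assert z[0, 0] == best_flat


def test_exhaustive_enumeration_tiny_instance():
    """Full itertools enumeration on a 2x2x4 instance (belt-and-braces oracle)."""
    rng = np.random.default_rng(1)
    cost = rng.integers(0, 10, (2, 2, 4))
    z = find_optimal_surface(cost, dx=1, dy=1)
    got = surface_total_cost(cost, z)
    best = min(
        sum(cost[i % 2, i // 2, zz[i]] for i in range(4))
        for zz in itertools.product(range(4), repeat=4)
        if abs(zz[0] - zz[1]) <= 1 and abs(zz[2] - zz[3]) <= 1
        and abs(zz[0] - zz[2]) <= 1 and abs(zz[1] - zz[3]) <= 1)
    assert got == best


@pytest.mark.parametrize("dx,dy", [(1, 1), (0, 0), (2, 1), (1, 3)])
def test_solver_matches_dp_oracle(dx, dy):
    rng = np.random.default_rng(20 * dx + dy)
    for _ in range(20):
        cost = rng.integers(0, 10, (4, 2, 6))
        z = find_optimal_surface(cost, dx=dx, dy=dy)
        assert surface_total_cost(cost, z) == dp_oracle_two_rows(cost, dx, dy)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(0, 2), st.integers(0, 2),
       st.integers(2, 5), st.integers(3, 7))
def test_solver_exactness_property(seed, dx, dy, ncols, ndepth):
    """The min-cut construction equals the exhaustive DP optimum."""
    rng = np.random.default_rng(seed)
    cost = rng.integers(0, 50, (ncols, 2, ndepth))
    z = find_optimal_surface(cost, dx=dx, dy=dy)
    assert np.abs(np.diff(z, axis=0)).max(initial=0) <= dx
    assert np.abs(np.diff(z, axis=1)).max(initial=0) <= dy
    assert surface_total_cost(cost, z) == dp_oracle_two_rows(cost, dx, dy)


def test_relaxing_smoothness_never_increases_cost():
    rng = np.random.default_rng(5)
    cost = rng.integers(0, 100, (5, 2, 8))
    prev = None
    for d in (0, 1, 2, 3):
        z = find_optimal_surface(cost, dx=d, dy=d)
        total = surface_total_cost(cost, z)
        if prev is not None:
            assert total <= prev
        prev = total


def test_float_costs_quantized_consistently():
    rng = np.random.default_rng(6)
    icost = rng.integers(0, 1000, (4, 2, 6))
    fcost = icost / 1000.0
    zi = find_optimal_surface(icost, dx=1, dy=1)
    zf = find_optimal_surface(fcost, dx=1, dy=1, scale=1000)
    assert surface_total_cost(icost, zi) == surface_total_cost(icost, zf)


def test_zrange_respected_and_infeasible_errors():
    rng = np.random.default_rng(7)
    cost = rng.integers(0, 10, (4, 2, 8))
    lo = np.full((4, 2), 2)
    hi = np.full((4, 2), 5)
    z = find_optimal_surface(cost, dx=1, dy=1, zrange=(lo, hi))
    assert (z >= 2).all() and (z <= 5).all()
    lo2 = lo.copy()
    hi2 = hi.copy()
    lo2[0, 0], hi2[0, 0] = 7, 7
    lo2[3, 1], hi2[3, 1] = 0, 0  # incompatible with |dz| <= 1 across the grid
    with pytest.raises(InfeasibleError):
        find_optimal_surface(cost, dx=1, dy=1, zrange=(lo2, hi2))


def test_propagate_bounds_tightens_to_consistency():
    lo = np.zeros((5, 1), dtype=int)
    hi = np.full((5, 1), 20, dtype=int)
    hi[2, 0] = 3
    lo2, hi2 = propagate_bounds(lo, hi, dx=2, dy=1)
    assert hi2[0, 0] == 7 and hi2[4, 0] == 7  # 3 + 2*|x - 2|


def test_dp_surface_matches_solver_per_bscan():
    rng = np.random.default_rng(8)
    cost = rng.integers(0, 50, (6, 1, 9))
    z_dp = dp_surface(cost, dx=1)
    z = find_optimal_surface(cost, dx=1, dy=1)
    assert surface_total_cost(cost, z_dp) == surface_total_cost(cost, z)


def test_banded_solver_agrees_with_full_solver():
    rng = np.random.default_rng(9)
    X, Y, D = 12, 4, 40
    cost = rng.normal(0.5, 0.1, (X, Y, D))
    edge = 20 + (3 * np.sin(np.arange(X) / 3)[:, None]).astype(int) \
        + (np.arange(Y) % 2)[None, :]
    cost[np.arange(X)[:, None], np.arange(Y)[None, :], edge] -= 0.4
    z_full = find_optimal_surface(cost, dx=2, dy=2, scale=4096)
    z_band = banded_optimal_surface(cost, dx=2, dy=2, margin=4, scale=4096)
    assert surface_total_cost((cost * 4096).astype(int), z_band) <= \
        surface_total_cost((cost * 4096).astype(int), z_full) + X * Y  # quantization slack
    assert np.abs(z_band - z_full).max() <= 1
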