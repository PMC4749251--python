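"""Exact single-surface detection as a minimum closed set in a vertex-weighted graph.

A terrain-like surface z(x, y) over the A-scan grid, subject to hard smoothness
constraints |z(x, y) - z(x', y')| <= bound for 4-neighbors, minimizing the total
on-surface cost, is found exactly: voxels below the surface form a closed set
whose weight telescopes to the on-surface cost, and the minimum-weight closed
set is a minimum s-t cut (solved with scipy's Dinic max-flow). The construction
uses intra-column arcs to enforce closure and inter-column arcs to enforce the
smoothness bounds, so the returned surface is a certified global optimum of the
(integer-quantized) objective.

Per-A-scan depth ranges are supported by building each column only over its
feasible band; :func:`propagate_bounds` tightens user ranges to mutual
consistency with the smoothness bounds first, and raises if they admit no
surface at all.

For large full-depth problems :func:`banded_optimal_surface` narrows the graph
to a band around an exact per-B-scan dynamic-programming presolve and re-solves
with a wider band whenever the optimum touches the band edge.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.sparse import csr_array
from scipy.sparse.csgraph import breadth_first_order, maximum_flow


class InfeasibleError(ValueError):
    """The depth ranges and smoothness bounds admit no surface."""


_INT32_MAX = 2**31 - 1
_INF_CAP = np.int32(2**30)


def propagate_bounds(lo, hi, dx: int, dy: int):
    """Tighten per-column depth ranges to consistency with |dz| bounds.

    Under the constraints, a surface through column c at depth z forces every
    other column c' to lie within z +/- (dx*|Dx| + dy*|Dy|); the tightest
    consistent ranges are separable 1D relaxations along each axis. Raises
    :class:`InfeasibleError` if any column ends up empty.
    """
    lo = np.array(lo, dtype=np.int64, copy=True)
    hi = np.array(hi, dtype=np.int64, copy=True)
    for axis, d in ((0, dx), (1, dy)):
        hi = np.moveaxis(hi, axis, 0)
        lo = np.moveaxis(lo, axis, 0)
        for i in range(1, hi.shape[0]):
            np.minimum(hi[i], hi[i - 1] + d, out=hi[i])
            np.maximum(lo[i], lo[i - 1] - d, out=lo[i])
        for i in range(hi.shape[0] - 2, -1, -1):
            np.minimum(hi[i], hi[i + 1] + d, out=hi[i])
            np.maximum(lo[i], lo[i + 1] - d, out=lo[i])
        hi = np.moveaxis(hi, 0, axis)
        lo = np.moveaxis(lo, 0, axis)
    if (lo > hi).any():
        raise InfeasibleError(
            f"empty feasible band in {int((lo > hi).sum())} columns after propagation")
    return lo, hi


def _quantize(cost: np.ndarray, scale: int) -> np.ndarray:
    """Map costs to non-negative integers by a global affine transform.

    A global affine map preserves the argmin over surfaces (every surface has
    exactly one voxel per column), so the solver is exact for the quantized
    objective; integer inputs are used as-is.
    """
    if np.issubdtype(cost.dtype, np.integer):
        return cost.astype(np.int64)
    lo, hi = float(cost.min()), float(cost.max())
    if not np.isfinite([lo, hi]).all():
        raise ValueError("costs must be finite")
    if hi == lo:
        return np.zeros(cost.shape, dtype=np.int64)
    return np.rint((cost - lo) * (scale / (hi - lo))).astype(np.int64)


def find_optimal_surface(cost: np.ndarray, dx: int, dy: int, zrange=None,
                         scale: int = 1024) -> np.ndarray:
    """Globally optimal surface for a cost volume under hard smoothness bounds.

    Parameters
    ----------
    cost : ndarray (ncols, nbscans, ndepth)
        Finite per-voxel on-surface cost. Float costs are quantized to
        ``scale`` integer levels (argmin-preserving affine map).
    dx, dy : int
        Maximum |dz| between 4-neighbor columns along x and y.
    zrange : (lo, hi), optional
        Inclusive per-A-scan depth bounds (scalars or (ncols, nbscans)
        arrays). Tightened by :func:`propagate_bounds` first.

    Returns
    -------
    ndarray (ncols, nbscans) of int
        Surface depth per A-scan, minimizing the summed on-surface cost over
        all surfaces satisfying the constraints.
    """
    cost = np.asarray(cost)
    if cost.ndim != 3:
        raise ValueError("cost must be (ncols, nbscans, ndepth)")
    X, Y, D = cost.shape
    if zrange is None:
        lo = np.zeros((X, Y), dtype=np.int64)
        hi = np.full((X, Y), D - 1, dtype=np.int64)
    else:
        lo = np.broadcast_to(np.asarray(zrange[0], dtype=np.int64), (X, Y))
        hi = np.broadcast_to(np.asarray(zrange[1], dtype=np.int64), (X, Y))
        if (lo < 0).any() or (hi > D - 1).any():
            raise InfeasibleError("zrange outside the depth axis")
    lo, hi = propagate_bounds(lo, hi, dx, dy)

    q = _quantize(cost, scale).reshape(X * Y, D)
    C = X * Y
    col_lo = lo.ravel()
    sizes = (hi - lo + 1).ravel()
    starts = np.concatenate([[0], np.cumsum(sizes)])
    N = int(starts[-1])

    c_of = np.repeat(np.arange(C), sizes)
    z_of = col_lo[c_of] + (np.arange(N) - starts[:-1][c_of])
    node_cost = q[c_of, z_of]

    # closed-set node weights: telescoping differences down each column,
    # with a large bonus on every base node so the optimum is nonempty
    w = node_cost.astype(np.int64).copy()
    base = z_of == col_lo[c_of]
    w[~base] -= node_cost[np.flatnonzero(~base) - 1]
    total_pos = int(w[w > 0].sum())
    M = total_pos + 1
    w[base] -= M
    if M > _INT32_MAX or int(-w.min()) > _INT32_MAX:
        raise ValueError("cost scale too large for 32-bit capacities; reduce `scale`")

    rows = [np.flatnonzero(~base)]
    cols = [np.flatnonzero(~base) - 1]

    cgrid = np.arange(C).reshape(X, Y)
    for axis, d in ((0, dx), (1, dy)):
        nbmap = np.full(C, -1, dtype=np.int64)
        if axis == 0:
            for src, dst in ((cgrid[:-1], cgrid[1:]), (cgrid[1:], cgrid[:-1])):
                nbmap[:] = -1
                nbmap[src.ravel()] = dst.ravel()
                sel = np.flatnonzero(nbmap[c_of] >= 0)
                b = nbmap[c_of[sel]]
                z2 = np.maximum(z_of[sel] - d, col_lo[b])
                rows.append(sel)
                cols.append(starts[:-1][b] + z2 - col_lo[b])
        else:
            for src, dst in ((cgrid[:, :-1], cgrid[:, 1:]), (cgrid[:, 1:], cgrid[:, :-1])):
                nbmap[:] = -1
                nbmap[src.ravel()] = dst.ravel()
                sel = np.flatnonzero(nbmap[c_of] >= 0)
                b = nbmap[c_of[sel]]
                z2 = np.maximum(z_of[sel] - d, col_lo[b])
                rows.append(sel)
                cols.append(starts[:-1][b] + z2 - col_lo[b])
    caps = [np.full(r.size, _INF_CAP, dtype=np.int32) for r in rows]

    s, t = N, N + 1
    neg = np.flatnonzero(w < 0)
    pos = np.flatnonzero(w > 0)
    rows.append(np.full(neg.size, s))
    cols.append(neg)
    caps.append((-w[neg]).astype(np.int32))
    rows.append(pos)
    cols.append(np.full(pos.size, t))
    caps.append(w[pos].astype(np.int32))

    g = csr_array(
        (np.concatenate(caps), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N + 2, N + 2), dtype=np.int32)
    res = maximum_flow(g, s, t)

    # source side of the min cut = minimum closed set
    resid = g - res.flow
    resid.data = (resid.data > 0).astype(np.int32)
    back = res.flow.T.tocsr(copy=True)
    back.data = (back.data > 0).astype(np.int32)
    reach = breadth_first_order(resid + back, s, directed=True, return_predecessors=False)
    in_set = np.zeros(N + 2, dtype=bool)
    in_set[reach] = True
    counts = np.bincount(c_of[in_set[:N]], minlength=C)
    if (counts < 1).any():
        raise RuntimeError("internal error: empty column in the minimum closed set")
    return (col_lo + counts - 1).reshape(X, Y).astype(np.int64)


def dp_surface(cost: np.ndarray, dx: int, zrange=None) -> np.ndarray:
    """Exact per-B-scan surface by dynamic programming (no coupling across y).

    Used as a presolve to band the 3D graph; also the natural solver for a
    single B-scan.
    """
    cost = np.asarray(cost, dtype=np.float64)
    X, Y, D = cost.shape
    work = cost.copy()
    if zrange is not None:
        lo = np.broadcast_to(np.asarray(zrange[0]), (X, Y))
        hi = np.broadcast_to(np.asarray(zrange[1]), (X, Y))
        zline = np.arange(D)
        bad = (zline[None, None, :] < lo[:, :, None]) | (zline[None, None, :] > hi[:, :, None])
        big = np.abs(cost).max() * (X + 1) + 1.0
        work = np.where(bad, big, work)
    m = work[0].copy()  # (Y, D)
    arg = np.empty((X, Y, D), dtype=np.int32)
    size = 2 * dx + 1
    offs = np.arange(D)
    for x in range(1, X):
        if dx > 0:
            prev_min = minimum_filter1d(m, size=size, axis=1, mode="nearest")
        else:
            prev_min = m
        # recover a minimizing predecessor within the window
        lo_w = np.maximum(offs - dx, 0)
        hi_w = np.minimum(offs + dx, D - 1)
        # windowed argmin: scan the window once (size is small)
        amin = np.full((Y, D), -1, dtype=np.int32)
        for o in range(-dx, dx + 1):
            idx = np.clip(offs + o, 0, D - 1)
            cand = m[:, idx]
            hit = (cand == prev_min) & (amin < 0) & (idx >= lo_w) & (idx <= hi_w)
            amin[hit] = np.broadcast_to(idx, (Y, D))[hit]
        arg[x] = amin
        m = prev_min + work[x]
    z = np.empty((X, Y), dtype=np.int64)
    z[X - 1] = np.argmin(m, axis=1)
    for x in range(X - 1, 0, -1):
        z[x - 1] = arg[x][np.arange(Y), z[x]]
    return z


def banded_optimal_surface(cost: np.ndarray, dx: int, dy: int, zrange=None,
                           margin: int = 8, scale: int = 1024,
                           max_expand: int = 3) -> np.ndarray:
    """Optimal surface via a DP presolve band plus the exact graph solve.

    The band around the per-B-scan DP solution is widened (doubling the
    margin) whenever the graph optimum touches a band edge that is not a user
    bound, falling back to the full range after ``max_expand`` attempts.
    """
    cost = np.asarray(cost)
    X, Y, D = cost.shape
    if zrange is None:
        user_lo = np.zeros((X, Y), dtype=np.int64)
        user_hi = np.full((X, Y), D - 1, dtype=np.int64)
    else:
        user_lo = np.broadcast_to(np.asarray(zrange[0], dtype=np.int64), (X, Y)).copy()
        user_hi = np.broadcast_to(np.asarray(zrange[1], dtype=np.int64), (X, Y)).copy()
    user_lo, user_hi = propagate_bounds(user_lo, user_hi, dx, dy)

    zdp = dp_surface(cost, dx, zrange=(user_lo, user_hi))
    m = margin
    for _ in range(max_expand):
        lo = np.maximum(zdp - m, user_lo)
        hi = np.minimum(zdp + m, user_hi)
        try:
            lo, hi = propagate_bounds(lo, hi, dx, dy)
        except InfeasibleError:
            m *= 2
            continue
        z = find_optimal_surface(cost, dx, dy, zrange=(lo, hi), scale=scale)
        touches = ((z == lo) & (lo > user_lo)) | ((z == hi) & (hi < user_hi))
        if not touches.any():
            return z
        m *= 2
    return find_optimal_surface(cost, dx, dy, zrange=(user_lo, user_hi), scale=scale)
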