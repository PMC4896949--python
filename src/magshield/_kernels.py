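"""Compiled ray-tracing kernels for coaxial (z-aligned cylinder) geometries.

Most shield fixtures are stacks of z-aligned cylindrical shells; for those
the boundary search and innermost-component lookup run as numba kernels
over flat parameter arrays.  Geometries containing rotated boxes or
off-axis orientations fall back to the pure-Python shape methods.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap

_EPS = 1e-12


@njit(cache=True)
def next_boundary_z(cx, cy, cz, rin, rout, hl, x, y, z, dx, dy, dz, t_max):
    """Nearest crossing distance over z-aligned cylinder shells, capped."""
    t_best = t_max
    a = dx * dx + dy * dy
    n = cx.shape[0]
    for i in range(n):
        u = x - cx[i]
        v = y - cy[i]
        w = z - cz[i]
        h = hl[i]
        if a > _EPS:
            b = u * dx + v * dy
            c0 = u * u + v * v
            for r in (rin[i], rout[i]):
                if r <= 0.0:
                    continue
                disc = b * b - a * (c0 - r * r)
                if disc <= 0.0:
                    continue
                sq = math.sqrt(disc)
                t1 = (-b - sq) / a
                if _EPS < t1 < t_best and abs(w + t1 * dz) <= h + 1e-12:
                    t_best = t1
                    continue
                t2 = (-b + sq) / a
                if _EPS < t2 < t_best and abs(w + t2 * dz) <= h + 1e-12:
                    t_best = t2
        if abs(dz) > _EPS:
            for sgn in (-1.0, 1.0):
                tp = (sgn * h - w) / dz
                if _EPS < tp < t_best:
                    uu = u + tp * dx
                    vv = v + tp * dy
                    r2 = uu * uu + vv * vv
                    if (rin[i] * rin[i] - 1e-12 <= r2
                            <= rout[i] * rout[i] + 1e-12):
                        t_best = tp
    return t_best


@njit(cache=True)
def innermost_z(cx, cy, cz, rin, rout, hl, x, y, z):
    """Index of the innermost (last listed) containing shell, or -1."""
    n = cx.shape[0]
    for i in range(n - 1, -1, -1):
        w = z - cz[i]
        if abs(w) > hl[i]:
            continue
        u = x - cx[i]
        v = y - cy[i]
        r2 = u * u + v * v
        if rin[i] * rin[i] <= r2 <= rout[i] * rout[i]:
            return i
    return -1
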