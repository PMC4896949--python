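"""Region-wise magnetic field maps for toroidal and solenoidal shields.

Fields are described as a superposition of bounded regions: uniform axial
fields inside cylindrical volumes (solenoids) and azimuthal fields inside
annular volumes (toroids, uniform magnitude by default or a 1/r profile
normalized to the same radial chord integral).  The field is identically
zero outside every region; no fringe or return flux is modeled, matching
the confined-field idealization used for the shield evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import CylinderShell, Shape

_AXIS_VEC = {"x": (1.0, 0.0, 0.0), "y": (0.0, 1.0, 0.0), "z": (0.0, 0.0, 1.0)}


@dataclass(frozen=True)
class FieldRegion:
    """A bounded field region.

    law: "uniform_axial" (B0 along the shape axis) or "toroidal"
    (azimuthal about the shape axis; profile "uniform" or "inverse_r",
    the latter normalized so a radial chord integral matches
    B0 * (r_out - r_in)).  circulation = +1/-1 flips the azimuthal sense.
    """

    shape: CylinderShell
    law: str
    B0: float
    profile: str = "uniform"
    circulation: int = 1

    def field(self, x: float, y: float, z: float) -> tuple[float, float, float]:
        if not self.shape.contains(x, y, z):
            return (0.0, 0.0, 0.0)
        if self.law == "uniform_axial":
            ax = _AXIS_VEC[self.shape.axis]
            return (self.B0 * ax[0], self.B0 * ax[1], self.B0 * ax[2])
        if self.law == "toroidal":
            k = {"x": 0, "y": 1, "z": 2}[self.shape.axis]
            rel = (x - self.shape.center[0], y - self.shape.center[1],
                   z - self.shape.center[2])
            tr = [rel[i] for i in range(3) if i != k]
            r = math.hypot(tr[0], tr[1])
            if r < 1e-12:
                return (0.0, 0.0, 0.0)
            if self.profile == "uniform":
                mag = self.B0
            elif self.profile == "inverse_r":
                ri, ro = self.shape.r_in, self.shape.r_out
                # normalize: integral of mag dr over [ri, ro] = B0 (ro - ri)
                mag = self.B0 * (ro - ri) / (math.log(ro / ri) * r)
            else:
                raise ValueError(f"unknown profile {self.profile!r}")
            # azimuthal unit vector about the axis
            tu, tv = -tr[1] / r, tr[0] / r
            vec = [0.0, 0.0, 0.0]
            idx = [i for i in range(3) if i != k]
            vec[idx[0]] = mag * tu * self.circulation
            vec[idx[1]] = mag * tv * self.circulation
            return tuple(vec)
        raise ValueError(f"unknown field law {self.law!r}")


@dataclass
class FieldMap:
    regions: list[FieldRegion]
    nominal_BL: float = 0.0

    @property
    def is_zero(self) -> bool:
        return not self.regions or all(r.B0 == 0.0 for r in self.regions)

    def field_at(self, x: float, y: float, z: float) -> tuple[float, float, float]:
        bx = by = bz = 0.0
        for reg in self.regions:
            fx, fy, fz = reg.field(x, y, z)
            bx += fx
            by += fy
            bz += fz
        return (bx, by, bz)

    def scaled(self, k: float) -> "FieldMap":
        regs = [FieldRegion(r.shape, r.law, r.B0 * k, r.profile, r.circulation)
                for r in self.regions]
        return FieldMap(regs, self.nominal_BL * k)


def field_at(point, fmap: FieldMap) -> np.ndarray:
    return np.array(fmap.field_at(point[0], point[1], point[2]))


def _perp_magnitude(b, d) -> float:
    bd = b[0] * d[0] + b[1] * d[1] + b[2] * d[2]
    b2 = b[0] * b[0] + b[1] * b[1] + b[2] * b[2]
    return math.sqrt(max(0.0, b2 - bd * bd))


# 16-point Gauss-Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def field_integral_along(start, direction, fmap: FieldMap,
                         max_range: float = 200.0) -> float:
    """Line integral of |B_perp| (T*m) along a ray through the field map.

    The ray is segmented at region boundaries and each segment integrated
    with 16-point Gauss-Legendre quadrature (exact for uniform regions,
    accurate for the smooth 1/r profile).
    """
    d = np.asarray(direction, float)
    n = np.linalg.norm(d)
    if abs(n - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    p = np.asarray(start, float)
    cuts = {0.0, max_range}
    for reg in fmap.regions:
        for t in reg.shape.crossings(p[0], p[1], p[2], d[0], d[1], d[2]):
            if t < max_range:
                cuts.add(t)
    ts = sorted(cuts)
    total = 0.0
    for t0, t1 in zip(ts[:-1], ts[1:]):
        length = t1 - t0
        if length <= 0:
            continue
        mid = p + 0.5 * (t0 + t1) * d
        if fmap.field_at(*mid) == (0.0, 0.0, 0.0):
            # cheap skip for field-free segments (fields are region-bounded)
            continue
        acc = 0.0
        for xg, wg in zip(_GL_X, _GL_W):
            q = p + (t0 + xg * length) * d
            b = fmap.field_at(q[0], q[1], q[2])
            acc += wg * _perp_magnitude(b, d)
        total += acc * length
    return total


def average_solenoid_integral(D: float, B: float) -> float:
    """Mean field integral over parallel chords of a circle: B * (pi/4) * D.

    For a solenoid of diameter D with uniform transverse-projected field B,
    the chord length averaged over uniformly offset parallel chords is
    (pi/4) D, giving the quoted mean BL.
    """
    if D <= 0 or B < 0:
        raise ValueError("need D > 0 and B >= 0")
    return B * math.pi / 4.0 * D
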