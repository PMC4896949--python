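"""Constructive geometry: axis-aligned primitives, ray tracing, masses.

Shapes are meters-scale primitives (box, solid cylinder, cylindrical shell,
disk, annular prism) positioned inside a rectangular generation box.  A
geometry is an ordered component list (outer to inner); the material at a
point is that of the innermost (last listed) containing component, so
nested fixtures list enclosures before their contents.  Nesting must be
containment-or-disjoint; partial overlaps are rejected at construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .dosimetry import Phantom
from .materials import VACUUM, WATER, MaterialSpec

_EPS = 1e-12
_AXIS = {"x": 0, "y": 1, "z": 2}


class Shape:
    def contains(self, x: float, y: float, z: float) -> bool:
        raise NotImplementedError

    def crossings(self, x, y, z, dx, dy, dz) -> list[float]:
        """Positive ray parameters at which the surface is crossed."""
        raise NotImplementedError

    def volume(self) -> float:
        raise NotImplementedError

    def bounds(self) -> tuple[tuple[float, float], ...]:
        raise NotImplementedError


@dataclass(frozen=True)
class Box(Shape):
    center: tuple[float, float, float]
    half: tuple[float, float, float]
    yaw: float = 0.0  # rotation about z (rad)

    def _local(self, x, y, z):
        x -= self.center[0]
        y -= self.center[1]
        z -= self.center[2]
        if self.yaw:
            c, s = math.cos(-self.yaw), math.sin(-self.yaw)
            x, y = c * x - s * y, s * x + c * y
        return x, y, z

    def _local_dir(self, dx, dy, dz):
        if self.yaw:
            c, s = math.cos(-self.yaw), math.sin(-self.yaw)
            dx, dy = c * dx - s * dy, s * dx + c * dy
        return dx, dy, dz

    def contains(self, x, y, z):
        lx, ly, lz = self._local(x, y, z)
        hx, hy, hz = self.half
        return abs(lx) <= hx and abs(ly) <= hy and abs(lz) <= hz

    def crossings(self, x, y, z, dx, dy, dz):
        p = self._local(x, y, z)
        d = self._local_dir(dx, dy, dz)
        ts = []
        for i in range(3):
            if abs(d[i]) < _EPS:
                continue
            for sign in (-1.0, 1.0):
                t = (sign * self.half[i] - p[i]) / d[i]
                if t > _EPS:
                    ok = True
                    for j in range(3):
                        if j == i:
                            continue
                        if abs(p[j] + t * d[j]) > self.half[j] + 1e-12:
                            ok = False
                            break
                    if ok:
                        ts.append(t)
        ts.sort()
        return ts

    def exit_distance(self, x, y, z, dx, dy, dz) -> float:
        """Distance to leave the box from an interior point."""
        p = self._local(x, y, z)
        d = self._local_dir(dx, dy, dz)
        t_exit = math.inf
        for i in range(3):
            if abs(d[i]) < _EPS:
                continue
            t = ((self.half[i] if d[i] > 0 else -self.half[i]) - p[i]) / d[i]
            if t < t_exit:
                t_exit = t
        return max(t_exit, 0.0)

    def volume(self):
        return 8.0 * self.half[0] * self.half[1] * self.half[2]

    def bounds(self):
        if self.yaw:
            r = math.hypot(self.half[0], self.half[1])
            hx = hy = r
        else:
            hx, hy = self.half[0], self.half[1]
        c = self.center
        return ((c[0] - hx, c[0] + hx), (c[1] - hy, c[1] + hy),
                (c[2] - self.half[2], c[2] + self.half[2]))


@dataclass(frozen=True)
class CylinderShell(Shape):
    """Annular cylinder (r_in = 0 gives a solid cylinder)."""

    center: tuple[float, float, float]
    axis: str
    r_in: float
    r_out: float
    half_length: float

    def __post_init__(self):
        if not (0.0 <= self.r_in < self.r_out) or self.half_length <= 0:
            raise ValueError("need 0 <= r_in < r_out and half_length > 0")

    def _split(self, x, y, z):
        k = _AXIS[self.axis]
        rel = (x - self.center[0], y - self.center[1], z - self.center[2])
        tr = [rel[i] for i in range(3) if i != k]
        return tr[0], tr[1], rel[k]

    def contains(self, x, y, z):
        u, v, w = self._split(x, y, z)
        if abs(w) > self.half_length:
            return False
        r2 = u * u + v * v
        return self.r_in * self.r_in <= r2 <= self.r_out * self.r_out

    def crossings(self, x, y, z, dx, dy, dz):
        k = _AXIS[self.axis]
        u, v, w = self._split(x, y, z)
        d = (dx, dy, dz)
        dt = [d[i] for i in range(3) if i != k]
        du, dv, dw = dt[0], dt[1], d[k]
        ts = []
        a = du * du + dv * dv
        for r in ((self.r_in,) if self.r_in > 0 else ()) + (self.r_out,):
            if a < _EPS:
                continue
            b = u * du + v * dv
            c = u * u + v * v - r * r
            disc = b * b - a * c
            if disc <= 0:
                continue
            sq = math.sqrt(disc)
            for t in ((-b - sq) / a, (-b + sq) / a):
                if t > _EPS and abs(w + t * dw) <= self.half_length + 1e-12:
                    ts.append(t)
        if abs(dw) >= _EPS:
            for sign in (-1.0, 1.0):
                t = (sign * self.half_length - w) / dw
                if t > _EPS:
                    r2 = (u + t * du) ** 2 + (v + t * dv) ** 2
                    if self.r_in ** 2 - 1e-12 <= r2 <= self.r_out ** 2 + 1e-12:
                        ts.append(t)
        ts.sort()
        return ts

    def volume(self):
        return math.pi * (self.r_out ** 2 - self.r_in ** 2) * 2 * self.half_length

    def bounds(self):
        k = _AXIS[self.axis]
        lo, hi = [], []
        for i in range(3):
            h = self.half_length if i == k else self.r_out
            lo.append(self.center[i] - h)
            hi.append(self.center[i] + h)
        return tuple(zip(lo, hi))


def Cylinder(center, axis, radius, half_length) -> CylinderShell:
    """Solid cylinder."""
    return CylinderShell(center, axis, 0.0, radius, half_length)


def Disk(center, axis, radius, half_thickness) -> CylinderShell:
    """Thin solid disk (end cap)."""
    return CylinderShell(center, axis, 0.0, radius, half_thickness)


def AnnularDisk(center, axis, r_in, r_out, half_thickness) -> CylinderShell:
    return CylinderShell(center, axis, r_in, r_out, half_thickness)


# "annular prism" in fixture descriptions = extruded annulus
AnnularPrism = CylinderShell


@dataclass(frozen=True)
class Component:
    shape: Shape
    material: MaterialSpec
    label: str


def _inside(inner: Shape, outer: Shape) -> bool:
    """Conservative containment test for the nesting patterns used here."""
    bi, bo = inner.bounds(), outer.bounds()
    tol = 1e-9
    for (li, hi_), (lo, ho) in zip(bi, bo):
        if li < lo - tol or hi_ > ho + tol:
            return False
    ci = tuple((b[0] + b[1]) / 2 for b in bi)
    return outer.contains(*ci)


def _disjoint(a: Shape, b: Shape) -> bool:
    ba, bb = a.bounds(), b.bounds()
    for (la, ha), (lb, hb) in zip(ba, bb):
        if ha <= lb + 1e-9 or la >= hb - 1e-9:
            return True
    return False


def _materially_overlap(a: Shape, b: Shape, rng, n: int = 400) -> bool:
    """Sampled test for genuine volume overlap within the AABB intersection."""
    ba, bb = a.bounds(), b.bounds()
    lo = [max(x[0], y[0]) for x, y in zip(ba, bb)]
    hi = [min(x[1], y[1]) for x, y in zip(ba, bb)]
    if any(h - l <= 1e-9 for l, h in zip(lo, hi)):
        return False
    pts = rng.uniform(lo, hi, size=(n, 3))
    for p in pts:
        if a.contains(*p) and b.contains(*p):
            return True
    return False


@dataclass
class GeometryModel:
    """Ordered component list + generation box + phantom placements.

    Phantom water cylinders are appended automatically as the innermost
    components (labels ``phantom_<i>``).
    """

    components: list[Component]
    box: Box
    phantoms: list[Phantom] = field(default_factory=list)
    name: str = "custom"
    allow_clipped: tuple[str, ...] = ()

    def __post_init__(self):
        for i, ph in enumerate(self.phantoms):
            shape = Cylinder(ph.center, ph.axis, ph.radius, ph.half_length)
            self.components.append(Component(shape, WATER, f"phantom_{i}"))
        self._phantom_start = len(self.components) - len(self.phantoms)
        self.validate()
        self._build_fast_path()

    def _build_fast_path(self):
        """Flat parameter arrays for the compiled coaxial tracer."""
        self._fast = False
        shells = []
        for comp in self.components:
            s = comp.shape
            if isinstance(s, CylinderShell) and s.axis == "z":
                shells.append(s)
            else:
                return
        if not shells:
            return
        self._cx = np.array([s.center[0] for s in shells])
        self._cy = np.array([s.center[1] for s in shells])
        self._cz = np.array([s.center[2] for s in shells])
        self._rin = np.array([s.r_in for s in shells])
        self._rout = np.array([s.r_out for s in shells])
        self._hl = np.array([s.half_length for s in shells])
        self._fast = True

    def validate(self):
        for comp in self.components:
            if comp.label in self.allow_clipped:
                continue
            bb, bx = comp.shape.bounds(), self.box.bounds()
            for (lo, hi), (blo, bhi) in zip(bb, bx):
                if lo < blo - 1e-9 or hi > bhi + 1e-9:
                    raise ValueError(
                        f"component {comp.label!r} extends outside the "
                        f"generation box")
        rng = np.random.default_rng(20160608)
        n = len(self.components)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = self.components[i], self.components[j]
                if _disjoint(a.shape, b.shape):
                    continue
                if _inside(b.shape, a.shape) or _inside(a.shape, b.shape):
                    continue
                if _materially_overlap(a.shape, b.shape, rng):
                    raise ValueError(
                        f"components {a.label!r} and {b.label!r} "
                        f"partially overlap")

    # -- queries -----------------------------------------------------------

    def material_at(self, x, y, z) -> tuple[MaterialSpec, int]:
        """(material, phantom index or -1) of the innermost component."""
        comps = self.components
        if self._fast:
            idx = _kernels.innermost_z(self._cx, self._cy, self._cz,
                                       self._rin, self._rout, self._hl,
                                       x, y, z)
            if idx < 0:
                return VACUUM, -1
            pid = idx - self._phantom_start
            return comps[idx].material, (pid if pid >= 0 else -1)
        for idx in range(len(comps) - 1, -1, -1):
            if comps[idx].shape.contains(x, y, z):
                pid = idx - self._phantom_start
                return comps[idx].material, (pid if pid >= 0 else -1)
        return VACUUM, -1

    def next_boundary(self, x, y, z, dx, dy, dz) -> float:
        """Distance to the nearest component surface or box exit."""
        t = self.box.exit_distance(x, y, z, dx, dy, dz)
        if self._fast:
            return _kernels.next_boundary_z(self._cx, self._cy, self._cz,
                                            self._rin, self._rout, self._hl,
                                            x, y, z, dx, dy, dz, t)
        for comp in self.components:
            for tc in comp.shape.crossings(x, y, z, dx, dy, dz):
                if tc < t:
                    t = tc
                break  # crossings are sorted; only the first matters
        return t

    def trace(self, point, direction):
        """(distance, label ahead, material ahead) along a unit-vector ray."""
        x, y, z = point
        dx, dy, dz = direction
        n = math.sqrt(dx * dx + dy * dy + dz * dz)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not self.box.contains(x, y, z):
            raise ValueError("point outside generation box: track terminated")
        t = self.next_boundary(x, y, z, dx, dy, dz)
        mx, my, mz = x + 0.5 * t * dx, y + 0.5 * t * dy, z + 0.5 * t * dz
        mat, pid = self.material_at(mx, my, mz)
        label = "vacuum"
        for idx in range(len(self.components) - 1, -1, -1):
            if self.components[idx].shape.contains(mx, my, mz):
                label = self.components[idx].label
                break
        return t, label, mat


@dataclass
class MassTable:
    table: pd.DataFrame  # columns: label, material, volume_m3, mass_t

    @property
    def total(self) -> float:
        return float(self.table["mass_t"].sum())

    def mass_of(self, label: str) -> float:
        sel = self.table[self.table["label"] == label]
        if sel.empty:
            raise KeyError(label)
        return float(sel["mass_t"].sum())

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def component_masses(geometry: GeometryModel,
                     include_gases: bool = False) -> MassTable:
    """Analytic volume x density per component, nested volumes subtracted.

    The volume of a component fully contained in another is subtracted from
    its immediate enclosure, so masses reflect the material actually
    occupying each region.  Air and vacuum are listed only on request.
    """
    comps = geometry.components
    vols = [c.shape.volume() for c in comps]
    net = list(vols)
    for j, cj in enumerate(comps):
        best, best_vol = None, math.inf
        for i, ci in enumerate(comps):
            if i == j:
                continue
            if vols[i] > vols[j] and _inside(cj.shape, ci.shape) \
                    and not _disjoint(cj.shape, ci.shape):
                if vols[i] < best_vol:
                    best, best_vol = i, vols[i]
        if best is not None:
            net[best] -= vols[j]
    rows = []
    for c, v in zip(comps, net):
        is_gas = c.material.is_vacuum or c.material.density < 0.01
        if is_gas and not include_gases:
            continue
        mass_t = v * c.material.density  # m^3 * g/cm^3 = t
        rows.append({"label": c.label, "material": c.material.name,
                     "volume_m3": v, "mass_t": mass_t})
    df = pd.DataFrame(rows, columns=["label", "material", "volume_m3", "mass_t"])
    return MassTable(df)
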