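"""Isotropic-flux surface source on the generation box.

Primaries are generated uniformly on the active faces of the generation
box with cosine-law directions about the inward normal.  This is the
unique surface sampling that reproduces an isotropic flux in the interior,
and it carries the acceptance A = pi * S (cm^2 sr) used to convert
recorded doses to absolute rates.  "Barrel" uses the four lateral (x, y)
faces, "endcaps" the two z faces, "full" all six.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Box
from .physics import ParticleState
from .spectrum import GCRSpectrum, MASS_NUMBERS

_SIDES = {
    "barrel": ("x-", "x+", "y-", "y+"),
    "endcaps": ("z-", "z+"),
    "full": ("x-", "x+", "y-", "y+", "z-", "z+"),
}


@dataclass(frozen=True)
class GenerationSurface:
    box: Box
    region: str = "full"

    def __post_init__(self):
        if self.region not in _SIDES:
            raise ValueError(f"region must be one of {sorted(_SIDES)}")

    @property
    def faces(self) -> tuple[str, ...]:
        return _SIDES[self.region]

    def face_area(self, face: str) -> float:
        hx, hy, hz = self.box.half
        axis = face[0]
        if axis == "x":
            return 4.0 * hy * hz
        if axis == "y":
            return 4.0 * hx * hz
        return 4.0 * hx * hy

    @property
    def active_area(self) -> float:
        """Total active area (m^2)."""
        return sum(self.face_area(f) for f in self.faces)


def acceptance(surface: GenerationSurface) -> float:
    """A = pi * active area, in cm^2 sr (cosine-law surface source)."""
    return math.pi * surface.active_area * 1e4


def sample_positions_directions(rng: np.random.Generator,
                                surface: GenerationSurface,
                                n: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of n surface points and inward cosine-law directions."""
    faces = surface.faces
    areas = np.array([surface.face_area(f) for f in faces])
    probs = areas / areas.sum()
    face_idx = rng.choice(len(faces), size=n, p=probs)
    hx, hy, hz = surface.box.half
    cx, cy, cz = surface.box.center
    pos = np.empty((n, 3))
    normal = np.empty((n, 3))
    u1 = rng.uniform(-1.0, 1.0, size=n)
    u2 = rng.uniform(-1.0, 1.0, size=n)
    for i, face in enumerate(faces):
        m = face_idx == i
        if not np.any(m):
            continue
        axis, sign = face[0], (1.0 if face[1] == "+" else -1.0)
        k = "xyz".index(axis)
        half = (hx, hy, hz)[k]
        others = [j for j in range(3) if j != k]
        pos[m, k] = (cx, cy, cz)[k] + sign * half
        for j, u in zip(others, (u1, u2)):
            h = (hx, hy, hz)[j]
            pos[m, j] = (cx, cy, cz)[j] + u[m] * h
        normal[m] = 0.0
        normal[m, k] = -sign  # inward
    # cosine-law about the inward normal
    mu = np.sqrt(rng.uniform(size=n))          # cos(theta) ~ 2 mu
    psi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    sin_t = np.sqrt(1.0 - mu * mu)
    # tangent frame per point
    t1 = np.zeros((n, 3))
    k_arr = np.argmax(np.abs(normal), axis=1)
    for k in range(3):
        m = k_arr == k
        j = (k + 1) % 3
        t1[m, j] = 1.0
    t2 = np.cross(normal, t1)
    t2 /= np.linalg.norm(t2, axis=1, keepdims=True)
    t1 = np.cross(t2, normal)
    dirs = (mu[:, None] * normal
            + (sin_t * np.cos(psi))[:, None] * t1
            + (sin_t * np.sin(psi))[:, None] * t2)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return pos, dirs


def sample_energies(rng: np.random.Generator, spectrum: GCRSpectrum,
                    Z: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw energies from f_z by inverse CDF over bins; returns (E, bin)."""
    weights = spectrum.bin_weights(Z)
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"zero integral flux for Z={Z}")
    probs = weights / total
    bins = rng.choice(len(probs), size=n, p=probs)
    e = spectrum.energy
    lo, hi = e[bins], e[bins + 1]
    # log-uniform within the bin (grid is logarithmic)
    u = rng.uniform(size=n)
    energies = lo * (hi / lo) ** u
    return energies, bins


@dataclass
class PrimarySample:
    state: ParticleState
    bin_index: int
    weight: float

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("statistical weight must be > 0")


def sample_primary(rng: np.random.Generator, surface: GenerationSurface,
                   spectrum: GCRSpectrum, Z: int,
                   scheme: str = "spectrum_sampled",
                   bin_index: int | None = None) -> PrimarySample:
    """Draw one primary.

    scheme="per_bin" generates at the center of ``bin_index`` with unit
    weight (the Eq.-6 aggregation divides by the per-bin count);
    scheme="spectrum_sampled" draws the energy from f_z by inverse CDF.
    """
    if Z not in spectrum.flux:
        raise ValueError(f"spectrum lacks Z={Z}")
    pos, dirs = sample_positions_directions(rng, surface, 1)
    if scheme == "per_bin":
        if bin_index is None:
            raise ValueError("per_bin scheme requires bin_index")
        centers, _ = spectrum.bin_centers_widths()
        E, j = float(centers[bin_index]), bin_index
    elif scheme == "spectrum_sampled":
        energies, bins = sample_energies(rng, spectrum, Z, 1)
        E, j = float(energies[0]), int(bins[0])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    state = ParticleState(Z=Z, A=MASS_NUMBERS[Z], E=E,
                          position=pos[0], direction=dirs[0])
    return PrimarySample(state=state, bin_index=j, weight=1.0)
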