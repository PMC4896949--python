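"""Closed-form single-particle physics.

Kinematics of fully ionized nuclei (Z = 1..28), mean ionization energy loss
(Bethe formula with density correction), unrestricted LET in water, the
piecewise quality factor Q(L), and the small-angle magnetic deflection
estimate theta ~ BL/R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import (
    ELECTRON_MASS,
    K_BETHE,
    SPEED_FACTOR,
    WATER_DENSITY,
    nucleon_rest_energy,
)
from .materials import WATER, MaterialSpec


@dataclass
class ParticleState:
    """A charged nucleus in flight.

    E is the kinetic energy *per nucleon* in MeV/n; direction is a unit
    3-vector; position is in meters.
    """

    Z: int
    A: int
    E: float
    position: np.ndarray
    direction: np.ndarray
    alive: bool = True

    def __post_init__(self):
        if not (1 <= self.Z <= 28):
            raise ValueError(f"Z={self.Z} outside 1..28")
        if self.A < self.Z and not (self.Z == 1 and self.A == 1):
            raise ValueError(f"A={self.A} < Z={self.Z}")
        if self.E < 0:
            raise ValueError("kinetic energy must be >= 0")
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        self.direction = self.direction / n

    @property
    def rest_energy_per_nucleon(self) -> float:
        return nucleon_rest_energy(self.Z, self.A)

    @property
    def gamma(self) -> float:
        return 1.0 + self.E / self.rest_energy_per_nucleon

    @property
    def beta(self) -> float:
        g = self.gamma
        return math.sqrt(1.0 - 1.0 / (g * g))

    @property
    def momentum(self) -> float:
        """Total momentum in MeV/c."""
        m = self.rest_energy_per_nucleon
        return self.A * math.sqrt(self.E * (self.E + 2.0 * m))

    def with_energy(self, E: float) -> "ParticleState":
        return replace(self, E=E)


def kinematics(E: float, Z: int, A: int) -> tuple[float, float]:
    """Return (beta, gamma) for kinetic energy E (MeV/n)."""
    m = nucleon_rest_energy(Z, A)
    gamma = 1.0 + E / m
    beta = math.sqrt(max(0.0, 1.0 - 1.0 / (gamma * gamma)))
    return beta, gamma


def rigidity(E: float, Z: int, A: int, rest_energy: float | None = None) -> float:
    """Magnetic rigidity R = p/(Z e) in GV for kinetic energy E (MeV/n).

    R = A * sqrt(E (E + 2 m_n)) / (1000 Z), with m_n the per-nucleon rest
    energy (938.272 MeV for protons, 931.494 MeV otherwise unless overridden).
    """
    if E < 0:
        raise ValueError("kinetic energy must be >= 0")
    m = rest_energy if rest_energy is not None else nucleon_rest_energy(Z, A)
    return A * math.sqrt(E * (E + 2.0 * m)) / (Z * 1000.0)


def dedx_ionization(Z: int, beta: float, material: MaterialSpec,
                    density_correction: bool = True) -> float:
    """Mean mass stopping power dE/dx (MeV cm^2/g) from the Bethe formula.

    Compounds enter through the mass-fraction-weighted Z/A and the
    logarithmic-average mean excitation energy (Bragg additivity); the
    density correction delta is evaluated per material unless disabled.
    """
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must be in (0, 1)")
    if material.is_vacuum:
        return 0.0
    gamma = 1.0 / math.sqrt(1.0 - beta * beta)
    bg = beta * gamma
    M = 931.494 * 1.0  # heavy projectile; m_e/M corrections negligible but kept
    ratio = ELECTRON_MASS / M
    tmax = (2.0 * ELECTRON_MASS * bg * bg
            / (1.0 + 2.0 * gamma * ratio + ratio * ratio))
    I_mev = material.mean_excitation_energy * 1e-6
    delta = material.density_correction(bg) if density_correction else 0.0
    bracket = (0.5 * math.log(2.0 * ELECTRON_MASS * bg * bg * tmax / (I_mev * I_mev))
               - beta * beta - 0.5 * delta)
    return K_BETHE * Z * Z * material.z_over_a / (beta * beta) * bracket


def let_water(Z: int, beta: float) -> float:
    """Unrestricted LET in water, L (keV/um).

    L = dE/dx(water) * rho_water * 0.1  (MeV/cm -> keV/um).
    """
    return dedx_ionization(Z, beta, WATER) * WATER_DENSITY * 0.1


def quality_factor(L: float, mode: str = "printed") -> float:
    """Quality factor Q(L), L in keV/um.

    mode="printed" (default): Q = 1 for L <= 10; 0.32 L - 3.2 for
    10 < L < 100; 300/L for L >= 100.
    mode="icrp60": Q = 1 for L < 10; 0.32 L - 2.2 for 10 <= L <= 100;
    300/sqrt(L) for L > 100.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    if mode == "printed":
        if L <= 10.0:
            return 1.0
        if L < 100.0:
            return 0.32 * L - 3.2
        return 300.0 / L
    if mode == "icrp60":
        if L < 10.0:
            return 1.0
        if L <= 100.0:
            return 0.32 * L - 2.2
        return 300.0 / math.sqrt(L)
    raise ValueError(f"unknown quality-factor mode {mode!r}")


def deflection_angle(BL: float, R: float) -> float:
    """Small-angle deflection estimate theta = 0.29979 * BL / R (rad).

    BL in T*m, rigidity R in GV.  Valid for theta << 1; documented as an
    estimate, the transport engine integrates the Lorentz force exactly.
    """
    if R <= 0:
        raise ValueError("rigidity must be > 0")
    return SPEED_FACTOR * BL / R


def gyroradius(p_gev_per_c: float, Z: int, B: float) -> float:
    """Gyroradius r = p / (0.29979 z B) in meters (p in GeV/c, B in T)."""
    if B <= 0 or Z <= 0:
        raise ValueError("Z and B must be > 0")
    return p_gev_per_c / (SPEED_FACTOR * Z * B)
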