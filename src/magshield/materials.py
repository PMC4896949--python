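"""Material specifications for stopping-power evaluation and mass accounting.

A material is a density plus a list of elemental constituents with mass
fractions.  Stopping power of compounds follows Bragg additivity: the
effective Z/A and mean excitation energy are mass-fraction weighted
(logarithmic average for I).  The density-effect correction uses tabulated
Sternheimer constants where available and an asymptotic plasma-energy form
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache


@dataclass(frozen=True)
class Element:
    Z: int
    A: float
    fraction: float       # mass fraction
    I: float              # mean excitation energy (eV)


@dataclass(frozen=True)
class SternheimerParams:
    """Piecewise density-effect parameterization delta(x), x = log10(beta*gamma)."""
    C: float
    x0: float
    x1: float
    a: float
    k: float
    delta0: float = 0.0

    def delta(self, x: float) -> float:
        if x < self.x0:
            return self.delta0 * 10.0 ** (2.0 * (x - self.x0))
        if x < self.x1:
            return 4.6052 * x + self.C + self.a * (self.x1 - x) ** self.k
        return 4.6052 * x + self.C


@dataclass(frozen=True)
class MaterialSpec:
    name: str
    density: float                       # g/cm^3
    elements: tuple[Element, ...]
    I_eff: float | None = None           # override effective I (eV)
    sternheimer: SternheimerParams | None = None

    def __post_init__(self):
        if self.name != "vacuum" and self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be > 0")
        if self.elements:
            total = sum(e.fraction for e in self.elements)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"material {self.name!r}: mass fractions sum to {total}, not 1"
                )

    @property
    def is_vacuum(self) -> bool:
        return not self.elements or self.density == 0.0

    @property
    def z_over_a(self) -> float:
        return _z_over_a(self)

    @property
    def mean_excitation_energy(self) -> float:
        """Effective I (eV); Bragg-rule logarithmic average unless overridden."""
        return _mean_excitation(self)

    @property
    def plasma_energy(self) -> float:
        """hbar*omega_p in eV for this material."""
        return 28.816 * math.sqrt(self.density * self.z_over_a)

    def density_correction(self, beta_gamma: float) -> float:
        """delta(beta*gamma): tabulated Sternheimer form if present, else the
        asymptotic conductor-free form clipped at zero."""
        x = math.log10(beta_gamma)
        if self.sternheimer is not None:
            return self.sternheimer.delta(x)
        # asymptotic form: delta -> 2 ln(h_omega_p/I) + 2 ln(beta*gamma) - 1
        asym = (2.0 * math.log(self.plasma_energy / self.mean_excitation_energy)
                + 2.0 * math.log(beta_gamma) - 1.0)
        return max(0.0, asym)


@lru_cache(maxsize=None)
def _z_over_a(material: "MaterialSpec") -> float:
    return sum(e.fraction * e.Z / e.A for e in material.elements)


@lru_cache(maxsize=None)
def _mean_excitation(material: "MaterialSpec") -> float:
    if material.I_eff is not None:
        return material.I_eff
    num = sum(e.fraction * (e.Z / e.A) * math.log(e.I)
              for e in material.elements)
    return math.exp(num / material.z_over_a)


def _el(Z, A, frac, I):
    return Element(Z=Z, A=A, fraction=frac, I=I)


VACUUM = MaterialSpec("vacuum", 0.0, ())

WATER = MaterialSpec(
    "water", 1.0,
    (_el(1, 1.008, 0.111894, 19.2), _el(8, 15.999, 0.888106, 95.0)),
    I_eff=75.0,
    sternheimer=SternheimerParams(C=-3.5017, x0=0.2400, x1=2.8004,
                                  a=0.09116, k=3.4773),
)

ALUMINUM = MaterialSpec(
    "aluminum", 2.699,
    (_el(13, 26.982, 1.0, 166.0),),
    sternheimer=SternheimerParams(C=-4.2395, x0=0.1708, x1=3.0127,
                                  a=0.08024, k=3.6345),
)

COPPER = MaterialSpec(
    "copper", 8.960,
    (_el(29, 63.546, 1.0, 322.0),),
    sternheimer=SternheimerParams(C=-4.4190, x0=-0.0254, x1=3.2792,
                                  a=0.14339, k=2.9044),
)

GRAPHITE = MaterialSpec(
    "graphite", 1.70,
    (_el(6, 12.011, 1.0, 78.0),),
    sternheimer=SternheimerParams(C=-3.1550, x0=0.0480, x1=2.5387,
                                  a=0.20762, k=2.9532),
)

TITANIUM = MaterialSpec(
    "titanium", 4.540,
    (_el(22, 47.867, 1.0, 233.0),),
    sternheimer=SternheimerParams(C=-4.4450, x0=0.0957, x1=3.0386,
                                  a=0.15675, k=3.0302),
)

AIR = MaterialSpec(
    "air", 1.205e-3,
    (_el(7, 14.007, 0.755, 82.0), _el(8, 15.999, 0.232, 95.0),
     _el(18, 39.948, 0.013, 188.0)),
    I_eff=85.7,
)

# Carbon-fiber support structure; treated as graphite-like carbon.
CARBON_FIBER = MaterialSpec("carbon_fiber", 1.70, (_el(6, 12.011, 1.0, 78.0),))

KEVLAR = MaterialSpec(
    "kevlar", 1.44,
    (_el(1, 1.008, 0.04, 19.2), _el(6, 12.011, 0.71, 78.0),
     _el(7, 14.007, 0.12, 82.0), _el(8, 15.999, 0.13, 95.0)),
)

MGB2 = MaterialSpec(
    "mgb2", 2.57,
    (_el(12, 24.305, 0.529, 156.0), _el(5, 10.811, 0.471, 76.0)),
)

# Smeared MgB2-cable core of the continuous-coil toroid:
# 57.4% Al, 8.6% MgB2, 23% Ti, 11% SiO2 by mass, density 3.0 g/cm^3.
CABLE_CORE = MaterialSpec(
    "cable_core", 3.0,
    (
        _el(13, 26.982, 0.574, 166.0),
        _el(12, 24.305, 0.086 * 0.529, 156.0),   # Mg of MgB2
        _el(5, 10.811, 0.086 * 0.471, 76.0),     # B of MgB2
        _el(22, 47.867, 0.230, 233.0),
        _el(14, 28.085, 0.110 * 0.467, 173.0),   # Si of SiO2
        _el(8, 15.999, 0.110 * 0.533, 95.0),     # O of SiO2
    ),
)

# Aluminum / boron-carbide metal-matrix composite (60% B4C by mass),
# density 2.6 g/cm^3.  B4C is 78.3% B / 21.7% C by mass.
AL_B4C = MaterialSpec(
    "al_b4c", 2.6,
    (
        _el(13, 26.982, 0.40, 166.0),
        _el(5, 10.811, 0.60 * 0.783, 76.0),
        _el(6, 12.011, 0.60 * 0.217, 78.0),
    ),
)

CATALOG: dict[str, MaterialSpec] = {
    m.name: m
    for m in (VACUUM, WATER, ALUMINUM, COPPER, GRAPHITE, TITANIUM, AIR,
              CARBON_FIBER, KEVLAR, MGB2, CABLE_CORE, AL_B4C)
}
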