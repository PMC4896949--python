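"""Synthetic galactic cosmic-ray spectra with force-field solar modulation.

The generator emulates CREME-2009-style per-charge (Z = 1..28) differential
fluxes in cm^-2 sr^-1 s^-1 (MeV/n)^-1 on a logarithmic energy grid spanning
1..1e5 MeV/n.  The local interstellar spectrum is a power law in total
energy per nucleon, f_LIS(E) = C_z (E + m_n)^-gamma, with relative
abundances from a built-in table; solar modulation follows the one-parameter
force-field transform with default potentials phi = 500 MV (solar minimum)
and 1100 MV (solar maximum), which suppresses the flux below ~1 GeV/n at
solar maximum.  Spectra are synthetic: shapes and ratios are realistic,
absolute dose magnitudes are approximate by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import AMU, PROTON_MASS

PHI_SOLAR_MIN = 500.0    # MV
PHI_SOLAR_MAX = 1100.0   # MV
SPECTRAL_INDEX = 2.7

# most-abundant isotope mass number per Z = 1..28
MASS_NUMBERS = {
    1: 1, 2: 4, 3: 7, 4: 9, 5: 11, 6: 12, 7: 14, 8: 16, 9: 19, 10: 20,
    11: 23, 12: 24, 13: 27, 14: 28, 15: 31, 16: 32, 17: 35, 18: 40,
    19: 39, 20: 40, 21: 45, 22: 48, 23: 51, 24: 52, 25: 55, 26: 56,
    27: 59, 28: 58,
}

# GCR relative abundances (number relative to hydrogen at equal energy per
# nucleon); representative of measured composition near 1 GeV/n.  Fluorine
# (Z=9) carries no anomalous-component enhancement, producing the local
# structure in the solar max/min ratio sequence.
ABUNDANCES = {
    1: 1.0, 2: 7.0e-2, 3: 1.6e-4, 4: 1.0e-4, 5: 3.0e-4, 6: 2.5e-3,
    7: 7.0e-4, 8: 2.4e-3, 9: 4.0e-5, 10: 3.7e-4, 11: 8.0e-5, 12: 5.0e-4,
    13: 8.5e-5, 14: 3.7e-4, 15: 2.5e-5, 16: 7.5e-5, 17: 1.5e-5,
    18: 3.5e-5, 19: 2.5e-5, 20: 6.0e-5, 21: 1.3e-5, 22: 4.5e-5,
    23: 2.2e-5, 24: 4.5e-5, 25: 2.7e-5, 26: 3.0e-4, 27: 1.7e-6,
    28: 1.5e-5,
}


def nucleon_mass(Z: int) -> float:
    return PROTON_MASS if Z == 1 else AMU


@dataclass
class GCRSpectrum:
    """Per-charge differential flux on a strictly increasing energy grid.

    ``energy`` holds the grid nodes (MeV/n); consecutive nodes bound the
    generation bins (geometric-mean centers).  ``flux[Z]`` gives the
    differential flux at the nodes in cm^-2 sr^-1 s^-1 (MeV/n)^-1.
    """

    energy: np.ndarray
    flux: dict[int, np.ndarray]
    epoch: str = "custom"
    phi: float | None = None

    def __post_init__(self):
        self.energy = np.asarray(self.energy, float)
        if self.energy.ndim != 1 or len(self.energy) < 2:
            raise ValueError("energy grid needs at least two nodes")
        if not np.all(np.diff(self.energy) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if not self.flux:
            raise ValueError("spectrum must cover at least one charge")
        for Z, f in self.flux.items():
            if not (1 <= Z <= 28):
                raise ValueError(f"Z={Z} outside 1..28")
            f = np.asarray(f, float)
            if f.shape != self.energy.shape:
                raise ValueError(f"flux for Z={Z} does not match the grid")
            if np.any(f < 0):
                raise ValueError(f"negative flux for Z={Z}")
            self.flux[Z] = f

    @property
    def charges(self) -> list[int]:
        return sorted(self.flux)

    @property
    def n_bins(self) -> int:
        return len(self.energy) - 1

    def bin_centers_widths(self) -> tuple[np.ndarray, np.ndarray]:
        e = self.energy
        centers = np.sqrt(e[:-1] * e[1:])
        widths = np.diff(e)
        return centers, widths

    def bin_weights(self, Z: int) -> np.ndarray:
        """f_z(E_j) * dE_j per bin (cm^-2 sr^-1 s^-1)."""
        centers, widths = self.bin_centers_widths()
        return np.interp(centers, self.energy, self.flux[Z]) * widths

    def integral_flux(self, Z: int) -> float:
        """Energy-integrated flux (cm^-2 sr^-1 s^-1)."""
        return float(np.sum(self.bin_weights(Z)))


def _lis(E: np.ndarray, Z: int, index: float, norm: float) -> np.ndarray:
    m = nucleon_mass(Z)
    return norm * ABUNDANCES[Z] * (E + m) ** (-index)


def _force_field(E: np.ndarray, Z: int, A: int, phi: float, index: float,
                 norm: float) -> np.ndarray:
    """Force-field transform: shift by Phi = (Z/A) phi, rescale by p^2 ratio."""
    m = nucleon_mass(Z)
    Phi = Z / A * phi
    Es = E + Phi
    jac = (E * (E + 2 * m)) / (Es * (Es + 2 * m))
    return _lis(Es, Z, index, norm) * jac


def _proton_norm(index: float) -> float:
    """Normalize so the solar-min proton flux at 1 GeV is 2e-4 /cm2/sr/s/MeV."""
    E = np.array([1000.0])
    raw = _force_field(E, 1, 1, PHI_SOLAR_MIN, index, 1.0)[0]
    return 2.0e-4 / raw


def synthetic_spectrum(epoch: str = "solar_min", phi: float | None = None,
                       z_list=None, n_bins: int = 48,
                       e_min: float = 1.0, e_max: float = 1e5,
                       index: float = SPECTRAL_INDEX) -> GCRSpectrum:
    """Generate a CREME-emulating spectrum for the requested solar epoch.

    phi overrides the epoch's default modulation potential (MV); phi = 0
    returns the unmodulated interstellar form.
    """
    if phi is None:
        if epoch == "solar_min":
            phi = PHI_SOLAR_MIN
        elif epoch == "solar_max":
            phi = PHI_SOLAR_MAX
        else:
            raise ValueError("custom epoch requires an explicit phi")
    if phi < 0:
        raise ValueError("modulation potential must be >= 0")
    if z_list is None:
        z_list = list(range(1, 29))
    z_list = list(z_list)
    if not z_list:
        raise ValueError("empty charge list")
    energy = np.geomspace(e_min, e_max, n_bins + 1)
    norm = _proton_norm(index)
    flux = {}
    for Z in z_list:
        A = MASS_NUMBERS[Z]
        if phi == 0.0:
            flux[Z] = _lis(energy, Z, index, norm)
        else:
            flux[Z] = _force_field(energy, Z, A, phi, index, norm)
    return GCRSpectrum(energy=energy, flux=flux, epoch=epoch, phi=phi)


FLUX_COLUMNS = ("Z", "E_MeV_per_n", "flux_per_cm2_sr_s_MeVn")


def write_flux_table(spectrum: GCRSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(FLUX_COLUMNS) + "\n")
        for Z in spectrum.charges:
            for e, f in zip(spectrum.energy, spectrum.flux[Z]):
                fh.write(f"{Z},{float(e)!r},{float(f)!r}\n")


def read_flux_table(path) -> GCRSpectrum:
    """Parse the CSV flux dialect; malformed rows raise with line numbers."""
    per_z: dict[int, list[tuple[float, float]]] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        for name in FLUX_COLUMNS:
            if name not in cols:
                raise ValueError(f"flux table missing column {name!r}")
        iz = cols.index(FLUX_COLUMNS[0])
        ie = cols.index(FLUX_COLUMNS[1])
        if_ = cols.index(FLUX_COLUMNS[2])
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                Z = int(parts[iz])
                e = float(parts[ie])
                f = float(parts[if_])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed flux row at line {lineno}: "
                                 f"{line!r}") from exc
            if f < 0:
                raise ValueError(f"negative flux at line {lineno}")
            per_z.setdefault(Z, []).append((e, f))
    if not per_z:
        raise ValueError("flux table contains no rows")
    grids = {}
    fluxes = {}
    for Z, rows in per_z.items():
        e = np.array([r[0] for r in rows])
        if not np.all(np.diff(e) > 0):
            raise ValueError(f"non-monotone energy grid for Z={Z}")
        grids[Z] = e
        fluxes[Z] = np.array([r[1] for r in rows])
    ref = grids[min(grids)]
    for Z, e in grids.items():
        if e.shape != ref.shape or not np.allclose(e, ref):
            raise ValueError("all charges must share one energy grid")
    return GCRSpectrum(energy=ref, flux=fluxes, epoch="custom")


def io_flux_table(path, mode: str, spectrum: GCRSpectrum | None = None):
    """Read or write the flux-table CSV dialect (lossless round-trip)."""
    if mode == "read":
        return read_flux_table(path)
    if mode == "write":
        if spectrum is None:
            raise ValueError("write mode needs a spectrum")
        write_flux_table(spectrum, path)
        return spectrum
    raise ValueError(f"mode must be 'read' or 'write', got {mode!r}")
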