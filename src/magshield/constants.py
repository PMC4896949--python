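"""Physical constants (MeV / cm / g units unless noted)."""

# Rest energies (MeV)
ELECTRON_MASS = 0.510998950
PROTON_MASS = 938.272089
AMU = 931.49410242          # per-nucleon rest energy used for A > 1 nuclei

# Bethe coefficient K = 4 pi N_A r_e^2 m_e c^2  (MeV cm^2 / mol)
K_BETHE = 0.307075

# Conversion factors
MEV_TO_JOULE = 1.602176634e-13
GV_PER_MV = 1e-3
SPEED_FACTOR = 0.299792458   # p[GeV/c] = 0.29979 * q[e] * B[T] * r[m]

SECONDS_PER_YEAR = 3.156e7   # 365.25 d

WATER_DENSITY = 1.0          # g/cm^3


def nucleon_rest_energy(Z: int, A: int) -> float:
    """Per-nucleon rest energy in MeV: protons exact, heavier nuclei A*amu/A."""
    if Z == 1 and A == 1:
        return PROTON_MASS
    return AMU
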