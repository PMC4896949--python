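"""Charged-particle transport through geometry and field.

Propagation alternates exact helical advancement in the regional magnetic
field (the direction vector is rotated about B, which preserves |v|, the
parallel velocity component and the particle energy) with continuous
slowing-down in matter (dE = dE/dx * rho * ds, deposited locally).  Step
length is limited by a maximum fractional energy loss, a maximum bend
angle, and the distance to the next geometry or field-region boundary.
Particles terminate at the generation-box boundary or below the stopping
cutoff, where the residual energy is deposited on the spot.

An optional toy nuclear model (Bradt-Peters geometric cross-sections,
velocity-conserving projectile fragment plus evaporation nucleons) exists
for qualitative secondary build-up studies only; it is off by default and
makes no claim of Geant-class hadronic fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import SPEED_FACTOR
from .fields import FieldMap
from .geometry import GeometryModel
from .materials import MaterialSpec
from .physics import ParticleState, dedx_ionization, kinematics, let_water
from .source import PrimarySample

_PUSH = 1e-9          # m, nudge across boundaries
_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class TransportSettings:
    max_frac_eloss: float = 0.02     # per step
    max_bend: float = 0.05           # rad per step
    cutoff: float = 1.0              # MeV/n stopping cutoff
    nuclear: bool = False            # toy nuclear model
    r0: float = 1.26e-13             # cm, Bradt-Peters radius parameter
    overlap_b: float = 1.0           # Bradt-Peters overlap parameter
    max_step: float = 10.0           # m, absolute cap
    q_mode: str = "printed"

    def __post_init__(self):
        if min(self.max_frac_eloss, self.max_bend, self.max_step) <= 0:
            raise ValueError("step limits must be positive")
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")


@dataclass
class DepositRecord:
    position: tuple[float, float, float]
    dE: float                     # MeV
    material: str
    phantom_id: int               # -1 outside phantoms
    regions: frozenset[str]
    lineage: str = "primary"

    def __post_init__(self):
        if self.dE <= 0:
            raise ValueError("dE must be > 0")


def deposits_to_csv(deposits: list["DepositRecord"], path) -> None:
    """Write a deposit stream (x,y,z,dE_MeV,material,phantom,regions,
    lineage) for re-scoring without re-transport."""
    with open(path, "w") as fh:
        fh.write("x,y,z,dE_MeV,material,phantom,regions,lineage\n")
        for d in deposits:
            regions = "|".join(sorted(d.regions))
            fh.write(f"{d.position[0]!r},{d.position[1]!r},"
                     f"{d.position[2]!r},{d.dE!r},{d.material},"
                     f"{d.phantom_id},{regions},{d.lineage}\n")


def _helix_advance(x, y, z, dx, dy, dz, bx, by, bz, omega_vec_scale, ds):
    """Advance a particle by path length ds in a locally uniform field.

    omega_vec_scale = 0.29979 * Z / p_GV (rad per m per tesla); the
    direction rotates about b_hat at rate omega = scale * |B| while the
    parallel component stays fixed (exact helix, energy conserving).
    """
    bmag = math.sqrt(bx * bx + by * by + bz * bz)
    if bmag < 1e-15:
        return x + ds * dx, y + ds * dy, z + ds * dz, dx, dy, dz
    ux, uy, uz = bx / bmag, by / bmag, bz / bmag
    dpar = dx * ux + dy * uy + dz * uz
    px, py, pz = dx - dpar * ux, dy - dpar * uy, dz - dpar * uz
    pmag2 = px * px + py * py + pz * pz
    if pmag2 < 1e-30:
        return x + ds * dx, y + ds * dy, z + ds * dz, dx, dy, dz
    omega = omega_vec_scale * bmag       # signed by charge via scale
    ang = omega * ds
    c, s = math.cos(ang), math.sin(ang)
    # q = d_perp x b_hat completes the rotation frame
    qx = py * uz - pz * uy
    qy = pz * ux - px * uz
    qz = px * uy - py * ux
    ndx = dpar * ux + c * px + s * qx
    ndy = dpar * uy + c * py + s * qy
    ndz = dpar * uz + c * pz + s * qz
    # exact position integral of the rotating direction
    if abs(ang) > 1e-8:
        sa, ca = s / omega, (1.0 - c) / omega
    else:
        sa, ca = ds * (1 - ang * ang / 6.0), 0.5 * ds * ang
    nx = x + dpar * ds * ux + sa * px + ca * qx
    ny = y + dpar * ds * uy + sa * py + ca * qy
    nz = z + dpar * ds * uz + sa * pz + ca * qz
    n = math.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
    return nx, ny, nz, ndx / n, ndy / n, ndz / n


def step_in_field(state: ParticleState, fmap: FieldMap, ds: float) -> ParticleState:
    """Advance a particle by path length ds through the field (no matter)."""
    if not state.alive:
        raise ValueError("particle is not alive")
    if ds <= 0:
        raise ValueError("ds must be > 0")
    x, y, z = state.position
    dx, dy, dz = state.direction
    bx, by, bz = fmap.field_at(x, y, z)
    p_gv = state.momentum / 1000.0
    scale = SPEED_FACTOR * state.Z / p_gv if p_gv > 0 else 0.0
    nx, ny, nz, ndx, ndy, ndz = _helix_advance(
        x, y, z, dx, dy, dz, bx, by, bz, scale, ds)
    return replace(state, position=np.array([nx, ny, nz]),
                   direction=np.array([ndx, ndy, ndz]))


def _field_boundary_distance(fmap: FieldMap, x, y, z, dx, dy, dz) -> float:
    t = math.inf
    for reg in fmap.regions:
        cr = reg.shape.crossings(x, y, z, dx, dy, dz)
        if cr and cr[0] < t:
            t = cr[0]
    return t


def bradt_peters_sigma(A_p: int, A_t: float, r0: float = 1.26e-13,
                       b: float = 1.0) -> float:
    """Geometric nucleus-nucleus inelastic cross-section (cm^2)."""
    reach = A_p ** (1.0 / 3.0) + A_t ** (1.0 / 3.0) - b
    if reach <= 0:
        return 0.0
    return math.pi * r0 * r0 * reach * reach


def interaction_length(A_p: int, material: MaterialSpec,
                       r0: float = 1.26e-13, b: float = 1.0) -> float:
    """Mean free path in meters for the toy nuclear model."""
    if material.is_vacuum:
        return math.inf
    inv = 0.0
    for el in material.elements:
        n_per_g = _AVOGADRO * el.fraction / el.A  # nuclei per gram
        inv += n_per_g * bradt_peters_sigma(A_p, el.A, r0, b)
    if inv <= 0:
        return math.inf
    lam_gcm2 = 1.0 / inv
    return lam_gcm2 / material.density / 100.0  # g/cm^2 -> m


def toy_nuclear_interaction(state: ParticleState, material: MaterialSpec,
                            rng: np.random.Generator,
                            settings: TransportSettings | None = None
                            ) -> list[ParticleState]:
    """Sample a toy inelastic interaction: fragment + evaporation nucleons.

    The projectile fragment keeps the projectile velocity exactly; knocked
    out nucleons are emitted isotropically with evaporation-like
    (exponential, 20 MeV mean) energies.  Returns an empty list when the
    model is disabled.
    """
    if settings is not None and not settings.nuclear:
        return []
    secondaries = []
    dZ = int(rng.integers(0, min(2, state.Z - 1) + 1))
    dA_extra = int(rng.integers(0, 3))
    dA = min(dZ + dA_extra, state.A - 1) if state.A > 1 else 0
    dZ = min(dZ, dA)
    if state.A - dA >= 1 and dA > 0:
        fz = max(1, state.Z - dZ)
        fa = max(fz, state.A - dA)
        secondaries.append(ParticleState(
            Z=fz, A=fa, E=state.E, position=state.position.copy(),
            direction=state.direction.copy()))
    n_nucleons = dA if dA > 0 else 1
    for _ in range(n_nucleons):
        e = float(rng.exponential(20.0))
        if e < 0.1:
            continue
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        # charged nucleon (proton); neutrons are handled separately as
        # non-depositing unless they recoil in hydrogenous material
        if rng.uniform() < 0.5:
            secondaries.append(ParticleState(
                Z=1, A=1, E=e, position=state.position.copy(), direction=u))
    return secondaries


def propagate(sample: PrimarySample, geometry: GeometryModel, fmap: FieldMap,
              settings: TransportSettings, rng: np.random.Generator,
              score=None, record_all: bool = False, lineage: str = "primary",
              _depth: int = 0) -> tuple[list[DepositRecord], ParticleState]:
    """Transport one particle; returns (deposit records, exit/final state).

    With ``score`` (a PhantomScore), phantom deposits are accumulated
    directly; deposit records are returned for phantom deposits always and
    for all materials when ``record_all``.
    """
    state = sample.state
    Z, A = state.Z, state.A
    x, y, z = map(float, state.position)
    dx, dy, dz = map(float, state.direction)
    E = state.E
    deposits: list[DepositRecord] = []
    box = geometry.box
    phantoms = geometry.phantoms
    zero_field = fmap.is_zero
    cutoff = settings.cutoff

    def record(dE, pos, mat_name, pid, beta, pstart=None, pend=None):
        if pid >= 0:
            ph = phantoms[pid]
            if pstart is not None:
                fractions = ph.segment_region_fractions(pstart, pend)
            else:
                fractions = {r: 1.0 for r in ph.region_of(pos)}
            if fractions:
                L = let_water(Z, beta) if beta > 0 else 1e4
                if score is not None:
                    for region, frac in fractions.items():
                        score.add_deposit(pid, (region,), Z,
                                          sample.bin_index, dE * frac, L,
                                          ph, settings.q_mode)
                deposits.append(DepositRecord(tuple(pos), dE, mat_name, pid,
                                              frozenset(fractions), lineage))
                return
        if record_all:
            deposits.append(DepositRecord(tuple(pos), dE, mat_name, pid,
                                          frozenset(), lineage))

    max_steps = 200000
    for _ in range(max_steps):
        if not box.contains(x, y, z):
            break
        if E <= cutoff:
            beta, _g = kinematics(max(E, 1e-6), Z, A)
            mat, pid = geometry.material_at(x, y, z)
            if E > 0:
                record(E * A, (x, y, z), mat.name, pid, beta)
            E = 0.0
            break
        mat, pid = geometry.material_at(x, y, z)
        beta, _gamma = kinematics(E, Z, A)
        p_gv = A * math.sqrt(E * (E + 2.0 * state.rest_energy_per_nucleon)) / 1000.0
        ds = geometry.next_boundary(x, y, z, dx, dy, dz) + _PUSH
        ds = min(ds, settings.max_step)
        if not zero_field:
            tf = _field_boundary_distance(fmap, x, y, z, dx, dy, dz)
            if tf + _PUSH < ds:
                ds = tf + _PUSH
            bx, by, bz = fmap.field_at(x, y, z)
            bmag = math.sqrt(bx * bx + by * by + bz * bz)
            if bmag > 0:
                ds_bend = settings.max_bend * p_gv / (SPEED_FACTOR * Z * bmag)
                if ds_bend < ds:
                    ds = ds_bend
        else:
            bx = by = bz = 0.0
        dedx = 0.0
        if not mat.is_vacuum:
            dedx = dedx_ionization(Z, beta, mat)  # MeV cm^2/g
            de_per_m = dedx * mat.density * 100.0  # MeV (total) per m
            if de_per_m > 0:
                ds_eloss = settings.max_frac_eloss * E * A / de_per_m
                if ds_eloss < ds:
                    ds = max(ds_eloss, 1e-6)
        if ds <= 0:
            ds = _PUSH
        # advance
        if zero_field or (bx == 0.0 and by == 0.0 and bz == 0.0):
            nx, ny, nz = x + ds * dx, y + ds * dy, z + ds * dz
            ndx, ndy, ndz = dx, dy, dz
        else:
            scale = SPEED_FACTOR * Z / p_gv
            nx, ny, nz, ndx, ndy, ndz = _helix_advance(
                x, y, z, dx, dy, dz, bx, by, bz, scale, ds)
        if not mat.is_vacuum:
            dE_total = dedx * mat.density * 100.0 * ds  # MeV
            dE_total = min(dE_total, E * A)
            mid = ((x + nx) / 2, (y + ny) / 2, (z + nz) / 2)
            if dE_total > 0:
                record(dE_total, mid, mat.name, pid, beta,
                       pstart=(x, y, z), pend=(nx, ny, nz))
            E -= dE_total / A
            if settings.nuclear and E > cutoff:
                lam = interaction_length(A, mat, settings.r0,
                                         settings.overlap_b)
                if lam < math.inf and rng.uniform() < 1.0 - math.exp(-ds / lam):
                    inter = ParticleState(Z=Z, A=A, E=E,
                                          position=np.array(mid),
                                          direction=np.array([dx, dy, dz]))
                    if _depth < 3:
                        for sec in toy_nuclear_interaction(inter, mat, rng):
                            sub = PrimarySample(state=sec,
                                                bin_index=sample.bin_index,
                                                weight=sample.weight)
                            d2, _ = propagate(sub, geometry, fmap, settings,
                                              rng, score=score,
                                              record_all=record_all,
                                              lineage="secondary",
                                              _depth=_depth + 1)
                            deposits.extend(d2)
                    E = 0.0
                    x, y, z = nx, ny, nz
                    break
        x, y, z, dx, dy, dz = nx, ny, nz, ndx, ndy, ndz
    final = ParticleState(Z=Z, A=A, E=max(E, 0.0),
                          position=np.array([x, y, z]),
                          direction=np.array([dx, dy, dz]),
                          alive=False)
    return deposits, final
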