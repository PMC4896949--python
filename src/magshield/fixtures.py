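"""Shield and habitat fixture catalog.

Each fixture materializes one evaluated configuration: nested material
shapes, phantom placements, the generation box and the region-wise field
map.  Conventions: habitat axis = z, origin at the habitat center (the ESA
spacecraft is shifted so the propulsion cylinder fits the generation box),
lengths in meters.

Fixture names: free_space, esa_habitat, esa_spacecraft, dh_solenoid_toroid,
racetrack_toroid, niac_61, sr2s_cct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

from . import materials as mat
from .dosimetry import Phantom
from .fields import FieldMap, FieldRegion
from .geometry import (
    AnnularDisk,
    Box,
    Component,
    Cylinder,
    CylinderShell,
    Disk,
    GeometryModel,
    component_masses,
)

FIXTURE_NAMES = ("free_space", "esa_habitat", "esa_spacecraft",
                 "dh_solenoid_toroid", "racetrack_toroid", "niac_61",
                 "sr2s_cct")


@dataclass
class Fixture:
    geometry: GeometryModel
    field: FieldMap
    name: str
    params: dict = dc_field(default_factory=dict)
    notes: tuple[str, ...] = ()


def standard_phantoms(inner_radius: float, length: float,
                      z0: float = 0.0) -> list[Phantom]:
    """Six-cylinder placement inside a habitat of given inner radius/length.

    Cylinders 1 and 6 on the axis at +-(L/2 - 1 m); 2-5 at 90 deg azimuth,
    outer phantom surface 10 cm from the inner wall, centered
    longitudinally.
    """
    z_ax = length / 2.0 - 1.0
    r_c = inner_radius - 0.10 - 0.12
    phantoms = [Phantom(center=(0.0, 0.0, z0 + z_ax)),
                Phantom(center=(0.0, 0.0, z0 - z_ax))]
    for k in range(4):
        phi = math.pi / 2.0 * k
        phantoms.append(Phantom(center=(r_c * math.cos(phi),
                                        r_c * math.sin(phi), z0)))
    return phantoms


def _habitat_components(inner_r: float, wall: float, half_len: float,
                        z0: float, endcap: float,
                        prefix: str = "habitat") -> list[Component]:
    c = (0.0, 0.0, z0)
    comps = [
        Component(CylinderShell(c, "z", inner_r, inner_r + wall, half_len),
                  mat.ALUMINUM, f"{prefix}_shell"),
        Component(Disk((0.0, 0.0, z0 + half_len + endcap / 2), "z",
                       inner_r + wall, endcap / 2),
                  mat.ALUMINUM, f"{prefix}_endcap_p"),
        Component(Disk((0.0, 0.0, z0 - half_len - endcap / 2), "z",
                       inner_r + wall, endcap / 2),
                  mat.ALUMINUM, f"{prefix}_endcap_m"),
        Component(Cylinder(c, "z", inner_r, half_len), mat.AIR,
                  f"{prefix}_air"),
    ]
    return comps


def _free_space(params):
    size = params.get("box_size", 3.0)
    box = Box((0.0, 0.0, 0.0), (size / 2,) * 3)
    geom = GeometryModel([], box, [Phantom(center=(0.0, 0.0, 0.0))],
                         name="free_space")
    return Fixture(geom, FieldMap([]), "free_space", dict(params))


def _esa_habitat(params):
    box = Box((0.0, 0.0, 0.0), (5.85, 5.85, 5.0))
    comps = _habitat_components(2.0, 0.018, 2.75, 0.0, 0.018)
    geom = GeometryModel(comps, box, standard_phantoms(2.0, 5.5),
                         name="esa_habitat")
    return Fixture(geom, FieldMap([]), "esa_habitat", dict(params))


_ESA_Z0 = 2.2  # habitat center offset so the propulsion cylinder fits


def _esa_spacecraft_components(params) -> tuple[list[Component], list[Phantom], Box, float]:
    box = Box((0.0, 0.0, 0.0), (5.85, 5.85, 5.0))
    z0 = _ESA_Z0
    comps = _habitat_components(2.0, 0.018, 2.75, z0, 0.018)
    # propulsion: 1.16-m-diameter, 6-m-long solid Al cylinder on -z; the part
    # outside the generation box is clipped (effective thickness is set by
    # the spacecraft position in the box)
    top = z0 - 2.75 - 0.018
    bottom = max(top - 6.0, -5.0)
    hl = (top - bottom) / 2.0
    comps.append(Component(
        Cylinder((0.0, 0.0, (top + bottom) / 2.0), "z", 0.58, hl),
        mat.ALUMINUM, "propulsion"))
    phantoms = standard_phantoms(2.0, 5.5, z0=z0)
    return comps, phantoms, box, z0


def _esa_spacecraft(params):
    comps, phantoms, box, _ = _esa_spacecraft_components(params)
    geom = GeometryModel(comps, box, phantoms, name="esa_spacecraft")
    return Fixture(geom, FieldMap([]), "esa_spacecraft", dict(params),
                   notes=("propulsion cylinder clipped at the -z box face",))


def _toroid_field(r_in, r_out, half_len, z0, BL, profile="uniform"):
    B0 = BL / (r_out - r_in)
    region = FieldRegion(CylinderShell((0.0, 0.0, z0), "z", r_in, r_out,
                                       half_len),
                         "toroidal", B0, profile=profile)
    return FieldMap([region], nominal_BL=BL)


def _dh_solenoid_toroid(params):
    BL = params.get("BL", 4.0)
    comps, phantoms, box, z0 = _esa_spacecraft_components(params)
    hl = 2.75
    c = (0.0, 0.0, z0)
    # double-helix coils as simulated: 8 x 90 um Cu + 2-mm carbon support,
    # smeared into inner/outer cylindrical shells bounding the field annulus
    cu = 8 * 90e-6
    layers = [
        (2.030, cu, mat.COPPER, "dh_coil_cu_inner"),
        (2.032, 0.002, mat.CARBON_FIBER, "dh_support_inner"),
        (4.000, cu, mat.COPPER, "dh_coil_cu_outer"),
        (4.002, 0.002, mat.CARBON_FIBER, "dh_support_outer"),
    ]
    for r0, t, m, label in layers:
        comps.append(Component(CylinderShell(c, "z", r0, r0 + t, hl), m, label))
    geom = GeometryModel(comps, box, phantoms, name="dh_solenoid_toroid")
    fmap = _toroid_field(2.04, 4.00, hl, z0, BL,
                         params.get("profile", "uniform"))
    return Fixture(geom, fmap, "dh_solenoid_toroid", {"BL": BL, **params})


def _racetrack_toroid(params):
    BL = params.get("BL", 4.9)
    comps, phantoms, box, z0 = _esa_spacecraft_components(params)
    hl = 2.75
    c = (0.0, 0.0, z0)
    # MgB2 racetrack coil stack: Cu 0.30, Al 1.65, Ti 1.50, MgB2 1.55 cm,
    # plus a 5-mm Al frame; inner and outer legs of the smeared toroid
    stack = [(0.0030, mat.COPPER, "cu"), (0.0165, mat.ALUMINUM, "al"),
             (0.0150, mat.TITANIUM, "ti"), (0.0155, mat.MGB2, "mgb2"),
             (0.0050, mat.ALUMINUM, "frame")]
    for side, r0 in (("inner", 2.030), ("outer", 4.000)):
        r = r0
        for t, m, tag in stack:
            comps.append(Component(CylinderShell(c, "z", r, r + t, hl), m,
                                   f"rt_{side}_{tag}"))
            r += t
    geom = GeometryModel(comps, box, phantoms, name="racetrack_toroid")
    fmap = _toroid_field(2.090, 3.995, hl, z0, BL,
                         params.get("profile", "uniform"))
    return Fixture(geom, fmap, "racetrack_toroid", {"BL": BL, **params})


def _niac_61(params):
    B = params.get("B", 1.0)
    B_cs = params.get("B_cs", 0.0)
    half = float(params.get("box_size", 30.0)) / 2.0
    box = Box((0.0, 0.0, 0.0), (half, half, half))
    # habitat: 6-m diameter, 10-m long, 1.8-cm Al, air filled
    comps = _habitat_components(3.0, 0.018, 5.0, 0.0, 0.018)
    # compensation solenoid: 6.4-m diameter, 20-m long, 111-um Cu + 2.4-mm
    # graphite support
    cu = 111e-6
    comps.append(Component(CylinderShell((0, 0, 0), "z", 3.2, 3.2 + cu, 10.0),
                           mat.COPPER, "comp_coil_cu"))
    comps.append(Component(CylinderShell((0, 0, 0), "z", 3.202, 3.2044, 10.0),
                           mat.GRAPHITE, "comp_coil_support"))
    ring_r = params.get("ring_radius", 8.0)  # tangent 8-m coils
    regions = []
    for i in range(6):
        phi = math.pi / 3.0 * i
        cx, cy = ring_r * math.cos(phi), ring_r * math.sin(phi)
        cc = (cx, cy, 0.0)
        comps.append(Component(CylinderShell(cc, "z", 4.0, 4.0 + cu, 10.0),
                               mat.COPPER, f"shield_coil_{i}_cu"))
        comps.append(Component(CylinderShell(cc, "z", 0.49, 0.50, 10.0),
                               mat.GRAPHITE, f"shield_coil_{i}_core"))
        for s in range(6):
            sphi = phi + math.pi / 3.0 * s + math.pi / 6.0
            sc = (cx + 2.25 * math.cos(sphi), cy + 2.25 * math.sin(sphi), 0.0)
            comps.append(Component(
                Box(sc, (1.75, 0.00125, 10.0), yaw=sphi),
                mat.GRAPHITE, f"shield_coil_{i}_spoke_{s}"))
        regions.append(FieldRegion(Cylinder(cc, "z", 4.0, 10.0),
                                   "uniform_axial", B))
    if B_cs:
        regions.append(FieldRegion(Cylinder((0, 0, 0), "z", 3.2, 10.0),
                                   "uniform_axial", B_cs))
    geom = GeometryModel(comps, box, standard_phantoms(3.0, 10.0),
                         name="niac_61")
    fmap = FieldMap(regions, nominal_BL=average_BL_niac(B))
    return Fixture(geom, fmap, "niac_61", {"B": B, "B_cs": B_cs, **params})


def average_BL_niac(B: float = 1.0) -> float:
    """Mean field integral of one 8-m shield solenoid over parallel chords."""
    return B * math.pi / 4.0 * 8.0


# SR2S continuous-coil toroid ------------------------------------------------

_SR2S_R_COIL_IN = 2.80    # inner conductor legs start here
_SR2S_R_COIL_OUT = 5.00   # outer conductor legs start here
_SR2S_HL_COIL = 4.3       # coils span the 8.6-m support-cylinder length
_SR2S_KEVLAR = 0.0006
_SR2S_AL = 0.012

# printed simulation masses (t) of the 120-coil toroid used to calibrate the
# smeared cable-core thickness (coil cross-sections are not dimensioned in
# the configuration description)
_SR2S_TOROID_MASS = {8.0: 79.0, 11.5: 120.1, 23.0: 120.1,
                     50.0: 120.1, 100.0: 120.1}


def _sr2s_toroid_components(t_core: float) -> list[Component]:
    c = (0.0, 0.0, 0.0)
    hl = _SR2S_HL_COIL
    comps = []
    # inner legs (outward): Kevlar sheath, Al shell, cable core
    r = _SR2S_R_COIL_IN
    for t, m, tag in ((_SR2S_KEVLAR, mat.KEVLAR, "kevlar_in"),
                      (_SR2S_AL, mat.ALUMINUM, "al_in"),
                      (t_core, mat.CABLE_CORE, "core_in")):
        comps.append(Component(CylinderShell(c, "z", r, r + t, hl), m,
                               f"toroid_{tag}"))
        r += t
    # outer legs (outward): cable core, Al shell, Kevlar sheath
    r = _SR2S_R_COIL_OUT
    for t, m, tag in ((t_core, mat.CABLE_CORE, "core_out"),
                      (_SR2S_AL, mat.ALUMINUM, "al_out"),
                      (_SR2S_KEVLAR, mat.KEVLAR, "kevlar_out")):
        comps.append(Component(CylinderShell(c, "z", r, r + t, hl), m,
                               f"toroid_{tag}"))
        r += t
    # end turns: annular disks closing the racetrack windings
    r_out_all = _SR2S_R_COIL_OUT + t_core + _SR2S_AL + _SR2S_KEVLAR
    for sign, tag in ((1.0, "p"), (-1.0, "m")):
        z = sign * (hl + t_core / 2.0)
        comps.append(Component(
            AnnularDisk((0, 0, z), "z", _SR2S_R_COIL_IN, r_out_all,
                        t_core / 2.0),
            mat.CABLE_CORE, f"toroid_end_core_{tag}"))
        z2 = sign * (hl + t_core + _SR2S_AL / 2.0)
        comps.append(Component(
            AnnularDisk((0, 0, z2), "z", _SR2S_R_COIL_IN, r_out_all,
                        _SR2S_AL / 2.0),
            mat.ALUMINUM, f"toroid_end_al_{tag}"))
    return comps


def _sr2s_toroid_mass(t_core: float) -> float:
    comps = _sr2s_toroid_components(t_core)
    return sum(c.shape.volume() * c.material.density for c in comps)


def sr2s_core_thickness(BL: float) -> float:
    """Cable-core thickness (m) calibrated to the printed toroid mass."""
    target = _SR2S_TOROID_MASS.get(BL, _SR2S_TOROID_MASS[8.0]
                                   if BL <= 8.0 else _SR2S_TOROID_MASS[23.0])
    lo, hi = 1e-4, 0.5
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _sr2s_toroid_mass(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sr2s_cct(params):
    BL = float(params.get("BL", 8.0))
    t_core = params.get("core_thickness", sr2s_core_thickness(BL))
    half = float(params.get("box_size", 30.0)) / 2.0
    box = Box((0.0, 0.0, 0.0), (half, half, half))
    # Columbus habitat: 4.5-m outer diameter, 6-m long, 1.5-cm Al shell and
    # two 3.0-cm Al endcaps, air filled
    comps = [
        Component(CylinderShell((0, 0, 0), "z", 2.235, 2.250, 3.0),
                  mat.ALUMINUM, "habitat_shell"),
        Component(Disk((0, 0, 3.015), "z", 2.25, 0.015), mat.ALUMINUM,
                  "habitat_endcap_p"),
        Component(Disk((0, 0, -3.015), "z", 2.25, 0.015), mat.ALUMINUM,
                  "habitat_endcap_m"),
        Component(Cylinder((0, 0, 0), "z", 2.235, 3.0), mat.AIR,
                  "habitat_air"),
        # Al-B4C support cylinder: 5.5-m outer diameter, 4.4 cm, 8.6 m
        Component(CylinderShell((0, 0, 0), "z", 2.706, 2.750, 4.3),
                  mat.AL_B4C, "support_cylinder"),
    ]
    comps += _sr2s_toroid_components(t_core)
    geom = GeometryModel(comps, box, standard_phantoms(2.235, 6.0),
                         name="sr2s_cct")
    r_field_in = _SR2S_R_COIL_IN + _SR2S_KEVLAR + _SR2S_AL + t_core
    fmap = _toroid_field(r_field_in, _SR2S_R_COIL_OUT, _SR2S_HL_COIL, 0.0, BL,
                         params.get("profile", "uniform"))
    return Fixture(geom, fmap, "sr2s_cct",
                   {"BL": BL, "core_thickness": t_core, **params})


_BUILDERS = {
    "free_space": _free_space,
    "esa_habitat": _esa_habitat,
    "esa_spacecraft": _esa_spacecraft,
    "dh_solenoid_toroid": _dh_solenoid_toroid,
    "racetrack_toroid": _racetrack_toroid,
    "niac_61": _niac_61,
    "sr2s_cct": _sr2s_cct,
}


def build_fixture(name: str, **params) -> Fixture:
    """Materialize a named shield/habitat configuration.

    params may override the field integral (``BL``), flux density (``B``),
    box size and similar knobs; unknown names raise.
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None
    return builder(params)


def fixture_masses(name: str, **params):
    """Mass table of a fixture (air/vacuum excluded)."""
    return component_masses(build_fixture(name, **params).geometry)
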