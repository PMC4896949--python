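"""Shield performance statistics and published reference comparisons.

The shield figures of merit are ratios of dose-table cells: the on/off
fraction (field on / field off), the percent contribution of the field to
the dose reduction, 100*(off-on)/off, and reference ratios of one
configuration's dose to another's.  Uncertainties propagate in quadrature.

`REFERENCE_CELLS` carries the published per-configuration dose cells used
as inputs for recomputing the derived statistics (fractions and percent
columns) that accompany them; `recompute_reference_statistics` rebuilds
every derived value from those cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


def _ratio_err(a, b, ea, eb):
    r = a / b
    return abs(r) * math.sqrt((ea / a) ** 2 + (eb / b) ** 2) if a else 0.0


def onoff_fraction(on: float, off: float, on_err: float = 0.0,
                   off_err: float = 0.0) -> tuple[float, float]:
    """Field on/off dose fraction with propagated uncertainty."""
    if off <= 0:
        raise ValueError("field-off dose must be > 0")
    if on == 0:
        return 0.0, 0.0
    return on / off, _ratio_err(on, off, on_err, off_err)


def field_contribution(off: float, on: float, off_err: float = 0.0,
                       on_err: float = 0.0) -> tuple[float, float]:
    """Percent of the dose removed by the field: 100 (off - on) / off."""
    if off <= 0:
        raise ValueError("field-off dose must be > 0")
    pct = 100.0 * (off - on) / off
    err = 100.0 * (on / off) * math.sqrt(
        (on_err / on) ** 2 + (off_err / off) ** 2) if on > 0 else 0.0
    return pct, err


def reference_ratio(config_dose: float, reference_dose: float,
                    config_err: float = 0.0,
                    reference_err: float = 0.0) -> tuple[float, float]:
    """Dose of a configuration relative to a reference configuration."""
    if reference_dose <= 0:
        raise ValueError("reference dose must be > 0")
    if config_dose == 0:
        return 0.0, 0.0
    return (config_dose / reference_dose,
            _ratio_err(config_dose, reference_dose, config_err,
                       reference_err))


def habitat_reduction(habitat: float, shield_on: float) -> float:
    """Percent reduction relative to the bare habitat:
    100 (habitat - shield_on) / habitat."""
    if habitat <= 0:
        raise ValueError("habitat dose must be > 0")
    return 100.0 * (habitat - shield_on) / habitat


@dataclass
class PerformanceRow:
    label: str
    BL: float
    mass_t: float
    dose_off: float
    dose_on: float
    off_err: float = 0.0
    on_err: float = 0.0
    habitat_dose: float | None = None

    @property
    def pct_field(self) -> float:
        return field_contribution(self.dose_off, self.dose_on,
                                  self.off_err, self.on_err)[0]

    @property
    def pct_habitat(self) -> float | None:
        if self.habitat_dose is None:
            return None
        return habitat_reduction(self.habitat_dose, self.dose_on)


PERFORMANCE_FORMULAS = (
    "% field = 100*(off - on)/off",
    "% habitat = 100*(habitat - shield_on)/habitat",
)


def performance_table(rows: list[PerformanceRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        recs.append({
            "shield": r.label, "BL_Tm": r.BL, "mass_t": r.mass_t,
            "dose_off": r.dose_off, "dose_on": r.dose_on,
            "pct_field": r.pct_field, "pct_habitat": r.pct_habitat,
        })
    return pd.DataFrame(recs)


# --------------------------------------------------------------------------
# Published annual dose-equivalent cells (cSv/y unless noted) used as inputs
# for recomputing the derived statistics printed alongside them.
# Keys: configuration -> region -> (value, error); error 0 where not quoted.

REFERENCE_CELLS = {
    # free space, solar minimum / maximum, per charge group + totals
    "free_space_min": {
        "groups": {"1": (10.8, 11.3, 11.1), "2": (5.3, 5.2, 5.1),
                   "3-10": (35.9, 22.2, 11.8), "11-20": (38.4, 16.6, 14.8),
                   "21-28": (27.3, 7.1, 8.7)},
        "total": (117.7, 62.4, 51.5),
    },
    "free_space_max": {
        "groups": {"1": (5.5, 5.6, 5.6), "2": (2.9, 2.8, 2.7),
                   "3-10": (22.1, 14.8, 6.8), "11-20": (23.1, 11.2, 9.2),
                   "21-28": (17.4, 5.1, 5.8)},
        "total": (71.0, 39.5, 30.1),
    },
    # passive/active decomposition totals (skin, BFO, body)
    "spacecraft": {"total": (74.2, 45.2, 36.8)},
    "dh_with_coils": {"total": (54.0, 35.2, 30.5)},
    "dh_without_coils": {"total": (65.2, 40.4, 33.7)},
    # extendable solenoid shield, barrel acceptance
    "shield_61": {"total": (45.5, 30.9, 23.2), "err": (1.4, 0.9, 0.6)},
    "shield_61_spacecraft": {"total": (48.3, 33.2, 25.6),
                             "err": (11.1, 6.8, 4.4)},
    # solenoid field on/off (first simulation program)
    "niac_g3_off": {"total": (37.5, 27.6, 22.0), "err": (1.7, 1.3, 0.7)},
    "niac_g3_on": {"total": (36.5, 26.1, 20.8), "err": (1.9, 1.0, 0.7)},
    # solenoid field on/off (second simulation program)
    "niac_g4_off": {"total": (36.4, 25.6, 28.8), "err": (1.5, 1.3, 0.7)},
    "niac_g4_on": {"total": (33.2, 23.6, 26.2), "err": (1.7, 1.4, 0.8)},
    # continuous-coil toroid on/off, 8 Tm
    "cct_off": {"total": (23.8, 21.9, 22.1), "err": (0.5, 1.0, 0.4)},
    "cct_on": {"total": (18.7, 16.7, 17.4), "err": (1.0, 0.5, 0.3)},
    # proton+He body dose across the BL scan (field off, field on)
    "cct_scan": {"8": ((19.0, 1.0), (14.4, 0.6)),
                 "11.5": ((20.3, 2.1), (12.8, 1.8)),
                 "23": ((20.3, 2.1), (10.5, 1.2))},
}

# published derived values the cells above must reproduce
REFERENCE_DERIVED = {
    "fraction_spacecraft_dh_coils": (0.73, 0.78, 0.83),
    "fraction_spacecraft_dh_nocoils": (0.88, 0.89, 0.92),
    "fraction_61_shield_spacecraft": (1.06, 1.07, 1.10),
    "onoff_niac_g3": (0.97, 0.95, 0.95),
    "onoff_cct": (0.79, 0.76, 0.79),
    "pct_field_niac_es": 7.8,
    "pct_field_cct8": 23.7,
    "pct_field_cct_scan": {"8": 24.0, "11.5": 37.0, "23": 48.0},
}

_REGIONS = ("skin", "bfo", "body")


def recompute_reference_statistics() -> pd.DataFrame:
    """Recompute every derived statistic from the published dose cells.

    Returns a frame with columns quantity, region, computed, published.
    """
    C = REFERENCE_CELLS
    rows = []

    def add(quantity, region, computed, published):
        rows.append({"quantity": quantity, "region": region,
                     "computed": computed, "published": published})

    # free-space totals are the sums of the charge-group rows
    for epoch in ("free_space_min", "free_space_max"):
        sums = [sum(v[i] for v in C[epoch]["groups"].values())
                for i in range(3)]
        for i, r in enumerate(_REGIONS):
            add(f"{epoch}_total", r, round(sums[i], 1), C[epoch]["total"][i])
    # solar-maximum body-dose reduction (the ~40% statement)
    drop = 100.0 * (1.0 - C["free_space_max"]["total"][2]
                    / C["free_space_min"]["total"][2])
    add("free_space_solar_max_body_drop_pct", "body", round(drop, 1), 41.6)

    for i, r in enumerate(_REGIONS):
        add("fraction_spacecraft_dh_coils", r,
            round(C["dh_with_coils"]["total"][i] / C["spacecraft"]["total"][i], 2),
            REFERENCE_DERIVED["fraction_spacecraft_dh_coils"][i])
        add("fraction_spacecraft_dh_nocoils", r,
            round(C["dh_without_coils"]["total"][i]
                  / C["spacecraft"]["total"][i], 2),
            REFERENCE_DERIVED["fraction_spacecraft_dh_nocoils"][i])
        add("fraction_61_shield_spacecraft", r,
            round(C["shield_61_spacecraft"]["total"][i]
                  / C["shield_61"]["total"][i], 2),
            REFERENCE_DERIVED["fraction_61_shield_spacecraft"][i])
        add("onoff_niac_g3", r,
            round(onoff_fraction(C["niac_g3_on"]["total"][i],
                                 C["niac_g3_off"]["total"][i])[0], 2),
            REFERENCE_DERIVED["onoff_niac_g3"][i])
        add("onoff_cct", r,
            round(onoff_fraction(C["cct_on"]["total"][i],
                                 C["cct_off"]["total"][i])[0], 2),
            REFERENCE_DERIVED["onoff_cct"][i])

    add("pct_field_niac_es", "bfo",
        round(field_contribution(C["niac_g4_off"]["total"][1],
                                 C["niac_g4_on"]["total"][1])[0], 1),
        REFERENCE_DERIVED["pct_field_niac_es"])
    add("pct_field_cct8", "bfo",
        round(field_contribution(C["cct_off"]["total"][1],
                                 C["cct_on"]["total"][1])[0], 1),
        REFERENCE_DERIVED["pct_field_cct8"])
    for bl, ((off, _eo), (on, _en)) in C["cct_scan"].items():
        add("pct_field_cct_scan", bl,
            round(field_contribution(off, on)[0]),
            REFERENCE_DERIVED["pct_field_cct_scan"][bl])
    return pd.DataFrame(rows)
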