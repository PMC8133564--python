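"""The standardized per-plant trait battery: 35 uptake parameters + 15 plant traits.

Each phenotyped plant yields 50 traits. The uptake block (35 columns) holds,
for each of the five focal ions, the net uptake rate, the two specific
uptake rates (per root length and per root mass) and the fractional
depletion over the selected interval (4 × 5 = 20), the uptake-rate ratio for
each of the 10 unordered ion pairs, and each ion's molar fraction of total
focal uptake (5). The plant block (15 columns) holds the root class lengths
and total length, five dry weights, specific root length, total and specific
root respiration, leaf area, leaf length and the root:shoot dry-weight
ratio.

The enumeration is a pinned reconstruction that reproduces both published
trait counts; it is versioned (``SCHEMA_VERSION``) so a revised list can
replace it without touching downstream code.

Ratio ordering is alphabetical by ion identifier (``ratio_a_b`` = rate_a /
rate_b); figure-parity orderings are available as named aliases. Net efflux
(negative rates) propagates through rate and ratio traits with a QC flag
but contributes zero to the stoichiometric fractions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .solution_chemistry import FOCAL_IONS
from .uptake_core import (
    PlantRecord,
    UptakeRecord,
    specific_respiration,
    specific_root_length,
)

SCHEMA_VERSION = "1.0"

#: QC flag vocabulary for trait computation
FLAG_ZERO_DENOMINATOR = "zero_denominator_ratio"
FLAG_NEGATIVE_RATE = "negative_rate"
FLAG_NO_POSITIVE_UPTAKE = "no_positive_uptake"

_PER_ION_QUANTITIES = (
    "net_uptake_umol_h",
    "sur_length_umol_cm_h",
    "sur_mass_umol_g_h",
    "fractional_depletion",
)

ION_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(sorted(FOCAL_IONS), 2)
)

#: figure-parity aliases: alias name -> (numerator, denominator)
RATIO_ALIASES: dict[str, tuple[str, str]] = {
    "ammonium_to_nitrate": ("ammonium", "nitrate"),
    "potassium_to_phosphate": ("potassium", "phosphate"),
}

UPTAKE_TRAIT_COLUMNS: tuple[str, ...] = (
    tuple(
        f"{ion}_{q}" for ion in sorted(FOCAL_IONS) for q in _PER_ION_QUANTITIES
    )
    + tuple(f"ratio_{a}_{b}" for a, b in ION_PAIRS)
    + tuple(f"fraction_{ion}" for ion in sorted(FOCAL_IONS))
)

PLANT_TRAIT_COLUMNS: tuple[str, ...] = (
    "root_length_seminal_cm",
    "root_length_lateral_cm",
    "root_length_secondary_lateral_cm",
    "root_length_total_cm",
    "dw_root_g",
    "dw_leaf_g",
    "dw_stem_g",
    "dw_shoot_g",
    "dw_total_g",
    "specific_root_length_cm_g",
    "root_respiration_nmol_s",
    "specific_root_respiration_nmol_m_s",
    "leaf_area_cm2",
    "leaf_length_cm",
    "root_shoot_dw_ratio",
)

TRAIT_COLUMNS: tuple[str, ...] = UPTAKE_TRAIT_COLUMNS + PLANT_TRAIT_COLUMNS
METADATA_COLUMNS: tuple[str, ...] = ("plant", "genotype", "treatment", "run", "block")

assert len(UPTAKE_TRAIT_COLUMNS) == 35
assert len(TRAIT_COLUMNS) == 50

#: units per trait column, written to the trait-table schema sidecar
TRAIT_UNITS: dict[str, str] = {}
for _ion in sorted(FOCAL_IONS):
    TRAIT_UNITS[f"{_ion}_net_uptake_umol_h"] = "umol/h"
    TRAIT_UNITS[f"{_ion}_sur_length_umol_cm_h"] = "umol/cm/h"
    TRAIT_UNITS[f"{_ion}_sur_mass_umol_g_h"] = "umol/g/h"
    TRAIT_UNITS[f"{_ion}_fractional_depletion"] = "unitless"
    TRAIT_UNITS[f"fraction_{_ion}"] = "unitless"
for _a, _b in ION_PAIRS:
    TRAIT_UNITS[f"ratio_{_a}_{_b}"] = "unitless"
TRAIT_UNITS.update(
    {
        "root_length_seminal_cm": "cm",
        "root_length_lateral_cm": "cm",
        "root_length_secondary_lateral_cm": "cm",
        "root_length_total_cm": "cm",
        "dw_root_g": "g",
        "dw_leaf_g": "g",
        "dw_stem_g": "g",
        "dw_shoot_g": "g",
        "dw_total_g": "g",
        "specific_root_length_cm_g": "cm/g",
        "root_respiration_nmol_s": "nmol CO2/s",
        "specific_root_respiration_nmol_m_s": "nmol CO2/m/s",
        "leaf_area_cm2": "cm^2",
        "leaf_length_cm": "cm",
        "root_shoot_dw_ratio": "unitless",
    }
)


@dataclass
class TraitRow:
    """One plant's metadata, 50 trait values and QC flags."""

    metadata: dict[str, str]
    traits: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        data = {**self.metadata}
        data.update({c: self.traits.get(c, math.nan) for c in TRAIT_COLUMNS})
        data["qc_flags"] = ";".join(self.flags)
        return pd.Series(data)


def uptake_ratio(rate_a: float, rate_b: float) -> tuple[float, list[str]]:
    """rate_a / rate_b with QC flags; zero denominator yields a missing value."""
    flags: list[str] = []
    if rate_b == 0 or rate_b is None or math.isnan(rate_b):
        return math.nan, [FLAG_ZERO_DENOMINATOR]
    if rate_a < 0 or rate_b < 0:
        flags.append(FLAG_NEGATIVE_RATE)
    return rate_a / rate_b, flags


def stoichiometric_fractions(
    rates: dict[str, float]
) -> tuple[dict[str, float], list[str]]:
    """Each ion's share of total positive focal uptake.

    Negative (efflux) rates contribute 0 to the total and receive fraction 0,
    flagged; if no rate is positive all fractions are missing.
    """
    flags: list[str] = []
    positive = {ion: r for ion, r in rates.items() if r is not None and r > 0}
    if any(r is not None and r < 0 for r in rates.values()):
        flags.append(FLAG_NEGATIVE_RATE)
    if not positive:
        flags.append(FLAG_NO_POSITIVE_UPTAKE)
        return {ion: math.nan for ion in rates}, flags
    total = sum(positive.values())
    return (
        {ion: (positive.get(ion, 0.0) / total) for ion in rates},
        flags,
    )


def compute_traits(
    plant: PlantRecord, uptake: list[UptakeRecord]
) -> TraitRow:
    """Assemble one plant's 50-trait row from its measurements and uptake records.

    Missing measurements leave the corresponding traits missing; the row is
    retained. Duplicate ion records are an error.
    """
    ions_seen = [u.ion for u in uptake]
    if len(ions_seen) != len(set(ions_seen)):
        dupes = sorted({i for i in ions_seen if ions_seen.count(i) > 1})
        raise ValidationError(f"duplicate uptake records for ion(s) {dupes}")
    by_ion = {u.ion: u for u in uptake}

    traits: dict[str, float] = {}
    flags: list[str] = []

    net_rates: dict[str, float] = {}
    for ion in sorted(FOCAL_IONS):
        u = by_ion.get(ion)
        if u is None:
            for q in _PER_ION_QUANTITIES:
                traits[f"{ion}_{q}"] = math.nan
            net_rates[ion] = math.nan
            continue
        traits[f"{ion}_net_uptake_umol_h"] = u.net_influx
        traits[f"{ion}_sur_length_umol_cm_h"] = (
            u.sur_length if u.sur_length is not None else math.nan
        )
        traits[f"{ion}_sur_mass_umol_g_h"] = (
            u.sur_mass if u.sur_mass is not None else math.nan
        )
        traits[f"{ion}_fractional_depletion"] = u.fractional_depletion
        net_rates[ion] = u.net_influx
        flags.extend(f"{ion}:{f}" for f in u.flags)

    for a, b in ION_PAIRS:
        ra, rb = net_rates.get(a, math.nan), net_rates.get(b, math.nan)
        if math.isnan(ra) or math.isnan(rb):
            traits[f"ratio_{a}_{b}"] = math.nan
            continue
        val, rflags = uptake_ratio(ra, rb)
        traits[f"ratio_{a}_{b}"] = val
        flags.extend(f"ratio_{a}_{b}:{f}" for f in rflags)

    valid_rates = {i: r for i, r in net_rates.items() if not math.isnan(r)}
    if len(valid_rates) == len(FOCAL_IONS):
        fracs, fflags = stoichiometric_fractions(valid_rates)
        flags.extend(fflags)
    else:
        fracs = {ion: math.nan for ion in FOCAL_IONS}
    for ion in sorted(FOCAL_IONS):
        traits[f"fraction_{ion}"] = fracs.get(ion, math.nan)

    # plant block
    traits["root_length_seminal_cm"] = plant.seminal_length
    traits["root_length_lateral_cm"] = plant.lateral_length
    traits["root_length_secondary_lateral_cm"] = plant.secondary_lateral_length
    traits["root_length_total_cm"] = (
        plant.total_root_length if plant.total_root_length is not None else math.nan
    )
    traits["dw_root_g"] = plant.root_dw if plant.root_dw is not None else math.nan
    traits["dw_leaf_g"] = plant.leaf_dw if plant.leaf_dw is not None else math.nan
    traits["dw_stem_g"] = plant.stem_dw if plant.stem_dw is not None else math.nan
    shoot = (
        plant.leaf_dw + plant.stem_dw
        if plant.leaf_dw is not None and plant.stem_dw is not None
        else math.nan
    )
    traits["dw_shoot_g"] = shoot
    traits["dw_total_g"] = (
        shoot + plant.root_dw
        if not math.isnan(shoot) and plant.root_dw is not None
        else math.nan
    )
    traits["specific_root_length_cm_g"] = (
        specific_root_length(plant.total_root_length, plant.root_dw)
        if plant.root_dw and plant.root_dw > 0 and plant.total_root_length is not None
        else math.nan
    )
    traits["root_respiration_nmol_s"] = (
        plant.total_respiration if plant.total_respiration is not None else math.nan
    )
    traits["specific_root_respiration_nmol_m_s"] = (
        specific_respiration(plant.total_respiration, plant.total_root_length)
        if plant.total_respiration is not None
        and plant.total_root_length
        and plant.total_root_length > 0
        else math.nan
    )
    traits["leaf_area_cm2"] = (
        plant.leaf_area if plant.leaf_area is not None else math.nan
    )
    traits["leaf_length_cm"] = (
        plant.leaf_length if plant.leaf_length is not None else math.nan
    )
    traits["root_shoot_dw_ratio"] = (
        plant.root_dw / shoot
        if plant.root_dw is not None and not math.isnan(shoot) and shoot > 0
        else math.nan
    )

    metadata = {
        "plant": plant.plant,
        "genotype": plant.genotype,
        "treatment": plant.treatment,
        "run": plant.run,
        "block": plant.block,
    }
    return TraitRow(metadata=metadata, traits=traits, flags=flags)


def build_trait_table(rows: list[TraitRow]) -> pd.DataFrame:
    """Stack trait rows into a DataFrame with the stable canonical column order."""
    if not rows:
        return pd.DataFrame(
            columns=list(METADATA_COLUMNS) + list(TRAIT_COLUMNS) + ["qc_flags"]
        )
    df = pd.DataFrame([r.as_series() for r in rows])
    return df[list(METADATA_COLUMNS) + list(TRAIT_COLUMNS) + ["qc_flags"]]
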