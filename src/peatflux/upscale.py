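"""Upscale daily emission factors to seasonal and annual national budgets.

Daily ecozone x class emission factors are converted to seasonal totals with
the ecozone's growing-season length (reversing the daily harmonization),
multiplied by mapped areas to give megatonnes per season, and summed. SEs
propagate linearly by default — combined SEs are sums of component SEs —
with quadrature offered as an option. Winter constants annualize seasonal
budgets and a growing-season-length scenario rescales them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .constants import Constants, GRAMS_PER_MEGATONNE, M2_PER_KM2

__all__ = [
    "seasonal_emission_factor", "scale_to_area", "combine_emissions",
    "to_co2e", "net_emission", "annualize_total", "gs_scenario",
    "national_budget",
]

ValueSE = Tuple[float, float]


def seasonal_emission_factor(
    mean: float, se: float, gs_days: float, gas: str, k: float = 5.0
) -> ValueSE:
    """Daily EF (g CO2 or mg CH4 m-2 day-1) -> seasonal total (g m-2 season-1).

    The transformation is linear, so the SE scales by the same factor.
    """
    if gs_days <= 0:
        raise ValueError("gs_days must be positive")
    if gas == "NEE":
        f = gs_days / k
    elif gas == "CH4":
        f = gs_days / 1000.0  # mg -> g
    else:
        raise ValueError(f"unknown gas {gas!r}")
    return mean * f, se * f


def scale_to_area(ef: float, se: float, area_km2: float) -> ValueSE:
    """Seasonal EF (g m-2) x area (km2) -> Mt, SE scaled identically."""
    if area_km2 < 0:
        raise ValueError("area must be non-negative")
    f = area_km2 * M2_PER_KM2 / GRAMS_PER_MEGATONNE
    return ef * f, se * f


def combine_emissions(components: Iterable[ValueSE], rule: str = "linear") -> ValueSE:
    """Sum component (mass, se) pairs; SE combined linearly or in quadrature."""
    comps = list(components)
    if not comps:
        raise ValueError("no components to combine")
    mass = float(sum(c[0] for c in comps))
    ses = np.array([c[1] for c in comps], dtype=float)
    if rule == "linear":
        se = float(ses.sum())
    elif rule == "quadrature":
        se = float(np.sqrt((ses**2).sum()))
    else:
        raise ValueError(f"unknown SE rule {rule!r}")
    return mass, se


def to_co2e(ch4_mass: float, ch4_se: float = 0.0, gwp: float = 25.0) -> ValueSE:
    """CH4 mass (Mt) -> CO2-equivalent mass via the global warming potential."""
    if gwp <= 0:
        raise ValueError("gwp must be positive")
    return ch4_mass * gwp, ch4_se * gwp


def net_emission(nee: ValueSE, ch4_co2e: ValueSE, rule: str = "linear") -> ValueSE:
    """Net CO2e budget: NEE plus CH4-as-CO2e, SEs combined by ``rule``."""
    return combine_emissions([nee, ch4_co2e], rule=rule)


def annualize_total(
    seasonal_mass: float,
    winter_rate: float,
    gas: str,
    areas_km2: Mapping[str, float],
    gs_by_ecozone: Mapping[str, float],
) -> float:
    """Add constant winter emissions over each ecozone's non-growing season.

    ``winter_rate`` is g CO2 m-2 day-1 (NEE) or mg CH4 m-2 day-1 (CH4) and is
    treated as exact, so the SE of the seasonal budget carries over unchanged.
    """
    if winter_rate < 0:
        raise ValueError("winter rate must be non-negative")
    rate_g = winter_rate if gas == "NEE" else winter_rate / 1000.0
    extra = 0.0
    for zone, area in areas_km2.items():
        if zone not in gs_by_ecozone:
            raise ValueError(f"no growing-season length for ecozone {zone!r}")
        days = 365.0 - gs_by_ecozone[zone]
        extra += rate_g * days * area * M2_PER_KM2 / GRAMS_PER_MEGATONNE
    return seasonal_mass + extra


def gs_scenario(mass: float, se: float, gs_scale: float) -> ValueSE:
    """Rescale a seasonal budget for a changed growing-season length.

    Seasonal totals are linear in GS under the harmonization, so a fractional
    GS change multiplies mass and SE alike.
    """
    if gs_scale <= 0:
        raise ValueError("gs_scale must be positive")
    return mass * gs_scale, se * gs_scale


def national_budget(
    ef_table: pd.DataFrame,
    area_table: pd.DataFrame,
    gs_by_ecozone: Mapping[str, float],
    constants: Optional[Constants] = None,
    se_rule: str = "linear",
) -> pd.DataFrame:
    """Full seasonal budget: EF x GS x area per (ecozone, class, gas), then sums.

    ``ef_table`` is a gap-filled emission-factor table (columns ecozone,
    peatland_class, gas, mean, se on the daily basis); ``area_table`` has
    columns ecozone, class, area_km2. Returns per-cell rows plus ``class``
    aggregates and a ``combined`` national row per gas (Mt season-1).
    """
    constants = constants or Constants()
    merged = ef_table.merge(
        area_table.rename(columns={"class": "peatland_class"}),
        on=["ecozone", "peatland_class"],
        how="inner",
    )
    rows = []
    for _, r in merged.iterrows():
        gs = gs_by_ecozone.get(r["ecozone"], constants.default_gs_days)
        ef, se = seasonal_emission_factor(
            r["mean"], r["se"], gs, r["gas"], k=constants.scaling_factor
        )
        mass, mse = scale_to_area(ef, se, r["area_km2"])
        rows.append((r["ecozone"], r["peatland_class"], r["gas"], mass, mse, "cell"))
    cells = pd.DataFrame(
        rows, columns=["ecozone", "peatland_class", "gas", "mass_mt", "se_mt", "level"]
    )

    out = [cells]
    for (gas, cls), grp in cells.groupby(["gas", "peatland_class"]):
        mass, se = combine_emissions(zip(grp["mass_mt"], grp["se_mt"]), rule=se_rule)
        out.append(pd.DataFrame(
            [("all", cls, gas, mass, se, "class")], columns=cells.columns
        ))
    class_rows = pd.concat(out[1:], ignore_index=True) if len(out) > 1 else cells.iloc[0:0]
    for gas, grp in class_rows.groupby("gas"):
        mass, se = combine_emissions(zip(grp["mass_mt"], grp["se_mt"]), rule=se_rule)
        out.append(pd.DataFrame(
            [("all", "combined", gas, mass, se, "combined")], columns=cells.columns
        ))
    return pd.concat(out, ignore_index=True)
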