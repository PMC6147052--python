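"""Physical constants and conversion parameters for the flux pipeline.

All values are configurable; the defaults reproduce the published national
synthesis: a shoulder-season scaling factor of 5 for NEE, winter (non-growing
season) emission rates of 0.9 g CO2 m-2 day-1 and 7 mg CH4 m-2 day-1, and a
100-year global warming potential of 25 for CH4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canadian ecozones holding the bulk of national peatland area.
PRIMARY_ECOZONES = (
    "Atlantic Maritime",
    "Mixedwood Plains",
    "Boreal Shield",
    "Boreal Plains",
    "Hudson Plains",
    "Taiga Shield",
    "Taiga Plains",
)

PEATLAND_CLASSES = ("bog", "poor_fen", "rich_fen")

#: Broad climatic region membership of the primary ecozones.
DEFAULT_REGION_MAP = {
    "Atlantic Maritime": "temperate",
    "Mixedwood Plains": "temperate",
    "Boreal Shield": "boreal",
    "Boreal Plains": "boreal",
    "Hudson Plains": "subarctic",
    "Taiga Shield": "subarctic",
    "Taiga Plains": "subarctic",
}

GRAMS_PER_MEGATONNE = 1e12
M2_PER_KM2 = 1e6


@dataclass
class Constants:
    """Tunable constants of the harmonization and upscaling procedure.

    Attributes
    ----------
    scaling_factor:
        Unitless multiplier applied when converting seasonal NEE to a daily
        rate; corrects for shoulder-season exchange outside the growing
        season proper.
    winter_co2:
        Non-growing-season CO2 emission rate, g CO2 m-2 day-1.
    winter_ch4:
        Non-growing-season CH4 emission rate, mg CH4 m-2 day-1.
    gwp_ch4:
        100-year global warming potential of CH4 (mass basis).
    default_gs_days:
        Growing-season length (days) used where no ecozone-specific value
        is available.
    """

    scaling_factor: float = 5.0
    winter_co2: float = 0.9
    winter_ch4: float = 7.0
    gwp_ch4: float = 25.0
    default_gs_days: int = 165

    def __post_init__(self) -> None:
        for name in ("scaling_factor", "winter_co2", "winter_ch4", "gwp_ch4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.default_gs_days < 365:
            raise ValueError("default_gs_days must lie in (0, 365)")


@dataclass
class MapRules:
    """Thresholds of the rule-based peatland classification.

    The probability threshold selects treed/forested peatland pixels from the
    boosted-regression-tree probability surface; tamarack biomass fraction
    separates bog, poor fen and rich fen along the nutrient gradient; canopy
    closure separates open, treed and forested cover.
    """

    prob_threshold: float = 0.5
    # tamarack fraction bins: bog [0, .10), poor fen [.10, .25], rich fen (.25, 1]
    tamarack_poor_min: float = 0.10
    tamarack_rich_min: float = 0.25
    # canopy-closure (%) bins: open < 10, treed 10-50, forested >= 50
    canopy_treed_min: float = 10.0
    canopy_forested_min: float = 50.0
    wetland_codes: tuple = (80, 81, 82, 83)
    cell_area_km2: float = 0.0625  # 250 m cells, equal-area projection

    def __post_init__(self) -> None:
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if not 0 <= self.tamarack_poor_min < self.tamarack_rich_min <= 1:
            raise ValueError("tamarack bins must be ordered within [0, 1]")
        if self.cell_area_km2 <= 0:
            raise ValueError("cell_area_km2 must be positive")
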