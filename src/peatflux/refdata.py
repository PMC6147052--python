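"""Published reference tables from the national Canadian peatland synthesis.

These are printed inputs, not computed outputs: literature winter emission
rates, ecozone x peatland-class emission factors, mapped peatland areas, the
ground-validation confusion counts and the scaled national budgets. They feed
the synthetic-data defaults, the worked examples in the test suite and the
reproduction script.

Units: NEE in g CO2 m-2 day-1 (negative = uptake), CH4 in mg CH4 m-2 day-1,
areas in 10^3 km2, scaled budgets in Mt season-1.
"""

from __future__ import annotations

import pandas as pd

# --- Literature non-growing-season emission rates -------------------------

#: (study, value) pairs; g CO2 m-2 day-1.
WINTER_CO2_STUDIES = [
    ("Roehm & Roulet", 1.0),
    ("Lafleur et al.", 1.0),
    ("Strack et al. (hummock)", 0.4),
    ("Strack et al. (lawn)", 0.3),
    ("Strack et al. (hollow)", 0.7),
    ("Strack & Zuback", 0.9),
    ("Trudeau et al. (hollow)", 0.2),
    ("Trudeau et al. (hummock)", 2.7),
    ("Trudeau et al. (lawn)", 0.7),
    ("Wang et al.", 1.5),
]

#: (study, value) pairs; mg CH4 m-2 day-1.
WINTER_CH4_STUDIES = [
    ("Strack et al. (hummock)", 19.4),
    ("Strack et al. (lawn)", 17.0),
    ("Strack et al. (hollow)", 0.6),
    ("Pelletier et al. (hummock)", 2.5),
    ("Pelletier et al. (hummock with shrubs)", 1.9),
    ("Pelletier et al. (hollow)", 4.7),
    ("Pelletier et al. (sedges and vascular)", 4.6),
    ("Trudeau et al.", 2.7),
    ("Strack & Zuback", 8.1),
]


def _ef_frame(rows):
    return pd.DataFrame(
        rows, columns=["ecozone", "peatland_class", "gas", "n", "mean", "se", "borrowed"]
    )


# --- Emission factors, fens combined (polygon-map accounting) --------------
# borrowed=True marks cells printed in italics (value taken from a similar
# ecozone, or SE borrowed where n = 1).

EMISSION_FACTORS_COMBINED = _ef_frame([
    ("Atlantic Maritime", "bog", "NEE", 5, -0.7, 5.2, False),
    ("Atlantic Maritime", "fen", "NEE", 0, -1.3, 2.8, True),
    ("Atlantic Maritime", "bog", "CH4", 7, 40.8, 7.0, False),
    ("Atlantic Maritime", "fen", "CH4", 0, 65.8, 8.4, True),
    ("Boreal Plains", "bog", "NEE", 11, -8.6, 2.7, False),
    ("Boreal Plains", "fen", "NEE", 6, -11.2, 1.2, False),
    ("Boreal Plains", "bog", "CH4", 3, 2.2, 2.1, False),
    ("Boreal Plains", "fen", "CH4", 12, 78.8, 23.6, False),
    ("Boreal Shield", "bog", "NEE", 13, -4.4, 2.0, False),
    ("Boreal Shield", "fen", "NEE", 5, -0.2, 1.4, False),
    ("Boreal Shield", "bog", "CH4", 28, 33.0, 8.4, False),
    ("Boreal Shield", "fen", "CH4", 31, 39.6, 7.8, False),
    ("Hudson Plains", "bog", "NEE", 5, -3.8, 1.4, False),
    ("Hudson Plains", "fen", "NEE", 7, -0.9, 2.2, False),
    ("Hudson Plains", "bog", "CH4", 15, 28.8, 7.8, False),
    ("Hudson Plains", "fen", "CH4", 17, 17.1, 6.0, False),
    ("Mixedwood Plains", "bog", "NEE", 2, -3.1, 0.1, False),
    ("Mixedwood Plains", "fen", "NEE", 4, -1.3, 2.8, False),
    ("Mixedwood Plains", "bog", "CH4", 3, 7.0, 6.5, False),
    ("Mixedwood Plains", "fen", "CH4", 3, 65.8, 8.4, False),
    ("Taiga Plains", "bog", "NEE", 1, -1.3, 2.7, True),   # SE borrowed
    ("Taiga Plains", "fen", "NEE", 4, -5.8, 3.2, False),
    ("Taiga Plains", "bog", "CH4", 4, 124.2, 54.9, False),
    ("Taiga Plains", "fen", "CH4", 4, 63.8, 36.5, False),
    ("Taiga Shield", "bog", "NEE", 0, -1.3, 2.7, True),
    ("Taiga Shield", "fen", "NEE", 3, 0.3, 0.5, False),
    ("Taiga Shield", "bog", "CH4", 2, 27.0, 21.0, False),
    ("Taiga Shield", "fen", "CH4", 28, 34.3, 7.4, False),
])

# --- Emission factors, fens separated (raster-map accounting) ---------------
# Mixedwood Plains bog CH4 SE is illegible in the source table; 6.5 is the
# combined-panel bog CH4 SE for the same ecozone (reconstructed value).

EMISSION_FACTORS_SEPARATED = _ef_frame([
    ("Atlantic Maritime", "bog", "NEE", 5, -0.7, 5.2, False),
    ("Atlantic Maritime", "poor_fen", "NEE", 0, -1.3, 2.8, True),
    ("Atlantic Maritime", "rich_fen", "NEE", 0, -0.9, 2.2, True),
    ("Atlantic Maritime", "bog", "CH4", 7, 40.8, 7.0, False),
    ("Atlantic Maritime", "poor_fen", "CH4", 0, 65.8, 8.4, True),
    ("Atlantic Maritime", "rich_fen", "CH4", 0, 17.1, 6.0, True),
    ("Boreal Plains", "bog", "NEE", 11, -8.6, 2.7, False),
    ("Boreal Plains", "poor_fen", "NEE", 1, -12.5, 0.5, True),  # SE borrowed
    ("Boreal Plains", "rich_fen", "NEE", 5, -10.2, 1.1, False),
    ("Boreal Plains", "bog", "CH4", 3, 2.2, 2.1, False),
    ("Boreal Plains", "poor_fen", "CH4", 1, 0.9, 9.4, True),    # SE borrowed
    ("Boreal Plains", "rich_fen", "CH4", 11, 85.8, 24.7, False),
    ("Boreal Shield", "bog", "NEE", 13, -5.5, 2.1, False),
    ("Boreal Shield", "poor_fen", "NEE", 1, 0.4, 0.5, True),    # SE borrowed
    ("Boreal Shield", "rich_fen", "NEE", 4, -0.3, 1.8, False),
    ("Boreal Shield", "bog", "CH4", 28, 33.0, 8.4, False),
    ("Boreal Shield", "poor_fen", "CH4", 12, 34.2, 9.4, False),
    ("Boreal Shield", "rich_fen", "CH4", 19, 43.0, 11.4, False),
    ("Hudson Plains", "bog", "NEE", 5, -5.4, 1.7, False),
    ("Hudson Plains", "poor_fen", "NEE", 0, -1.3, 2.8, True),
    ("Hudson Plains", "rich_fen", "NEE", 7, -0.9, 2.2, False),
    ("Hudson Plains", "bog", "CH4", 15, 28.8, 7.8, False),
    ("Hudson Plains", "poor_fen", "CH4", 0, 34.2, 9.4, True),
    ("Hudson Plains", "rich_fen", "CH4", 17, 17.1, 6.0, False),
    ("Mixedwood Plains", "bog", "NEE", 2, -7.6, 2.1, False),
    ("Mixedwood Plains", "poor_fen", "NEE", 4, -1.3, 2.8, False),
    ("Mixedwood Plains", "bog", "CH4", 3, 37.0, 6.5, False),
    ("Mixedwood Plains", "poor_fen", "CH4", 3, 65.8, 8.4, False),
    ("Taiga Plains", "bog", "NEE", 1, -1.3, 2.7, True),         # SE borrowed
    ("Taiga Plains", "poor_fen", "NEE", 0, 0.3, 0.5, True),
    ("Taiga Plains", "rich_fen", "NEE", 4, -5.8, 3.2, False),
    ("Taiga Plains", "bog", "CH4", 4, 124.2, 54.9, False),
    ("Taiga Plains", "poor_fen", "CH4", 1, 165.3, 11.6, True),  # SE borrowed
    ("Taiga Plains", "rich_fen", "CH4", 3, 30.0, 19.4, False),
    ("Taiga Shield", "bog", "NEE", 0, -1.3, 2.7, True),
    ("Taiga Shield", "poor_fen", "NEE", 3, 0.3, 0.5, False),
    ("Taiga Shield", "rich_fen", "NEE", 0, -5.8, 3.2, True),
    ("Taiga Shield", "bog", "CH4", 2, 27.0, 21.0, False),
    ("Taiga Shield", "poor_fen", "CH4", 7, 39.5, 11.6, False),
    ("Taiga Shield", "rich_fen", "CH4", 21, 32.5, 9.2, False),
])

#: Rich fen is not mapped in the Mixedwood Plains; cells absent above.

# --- Mapped peatland areas by ecozone (10^3 km2) ----------------------------
# pcm_* columns: polygon (soil-survey) map; new_* columns: 250 m raster map.

AREAS_BY_ECOZONE = pd.DataFrame(
    [
        ("Arctic Cordillera", 0.1, 0.0, 0.0, 0.0, 0.0),
        ("Northern Arctic", 2.0, 2.5, 0.0, 0.0, 0.0),
        ("Southern Arctic", 13.3, 3.1, 0.0, 0.0, 0.0),
        ("Taiga Plains", 131.1, 44.6, 71.6, 4.9, 0.2),
        ("Taiga Shield", 81.6, 55.9, 33.4, 0.3, 0.012),
        ("Boreal Shield", 259.8, 58.8, 218.7, 48.8, 8.1),
        ("Atlantic Maritime", 8.0, 2.1, 5.5, 0.4, 0.001),
        ("Mixedwood Plains", 1.7, 1.1, 1.4, 0.005, 0.0),
        ("Boreal Plains", 83.1, 64.2, 106.4, 57.0, 26.7),
        ("Prairie", 0.2, 0.4, 2.4, 0.4, 0.1),
        ("Taiga Cordillera", 4.1, 0.0, 1.8, 0.0, 0.0),
        ("Boreal Cordillera", 5.7, 1.4, 5.6, 0.0, 0.0),
        ("Pacific Maritime", 3.4, 0.3, 0.1, 0.0, 0.0),
        ("Montane Cordillera", 3.2, 9.3, 0.7, 0.0, 0.0),
        ("Hudson Plains", 127.7, 130.4, 85.5, 34.9, 13.7),
    ],
    columns=["ecozone", "pcm_bog", "pcm_fen", "new_bog", "new_poor_fen", "new_rich_fen"],
)

#: New-map areas by the nine expanded cover x nutrient categories (10^3 km2),
#: primary ecozones only.
AREAS_EXPANDED = pd.DataFrame(
    [
        ("Taiga Plains", 43.4, 17.0, 11.1, 3.5, 1.4, 0.1, 0.1, 0.1, 0.003),
        ("Taiga Shield", 4.0, 7.8, 21.6, 0.1, 0.1, 0.1, 0.003, 0.003, 0.006),
        ("Boreal Shield", 187.0, 25.0, 6.8, 41.0, 5.9, 1.8, 5.1, 2.1, 0.9),
        ("Atlantic Maritime", 5.1, 0.3, 0.1, 0.3, 0.03, 0.001, 0.001, 0.001, 0.0),
        ("Mixedwood Plains", 1.2, 0.2, 0.011, 0.004, 0.001, 0.0, 0.0, 0.0, 0.0),
        ("Boreal Plains", 88.2, 12.4, 5.8, 48.6, 7.0, 1.4, 21.4, 5.1, 0.3),
        ("Hudson Plains", 33.5, 19.2, 32.8, 17.4, 13.0, 4.5, 3.2, 8.4, 2.1),
        ("Prairie", 1.1, 1.3, 0.1, 0.3, 0.1, 0.0, 0.1, 0.0, 0.0),
        ("Taiga Cordillera", 0.1, 0.7, 1.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("Boreal Cordillera", 1.5, 2.8, 1.3, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("Pacific Maritime", 0.0, 0.0, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("Montane Cordillera", 0.2, 0.1, 0.4, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    ],
    columns=[
        "ecozone",
        "forested_bog", "treed_bog", "open_bog",
        "forested_poor_fen", "treed_poor_fen", "open_poor_fen",
        "forested_rich_fen", "treed_rich_fen", "open_rich_fen",
    ],
)

# --- Ground-validation confusion counts (northern Alberta case study) -------
# rows = ground truth, columns = raster-map prediction.

VALIDATION_CLASSES = ["bog", "poor_fen", "rich_fen", "upland"]
VALIDATION_CONFUSION = pd.DataFrame(
    [
        [64, 4, 21, 0],
        [34, 3, 29, 0],
        [12, 0, 41, 0],
        [58, 3, 19, 0],
    ],
    index=VALIDATION_CLASSES,
    columns=VALIDATION_CLASSES,
)

# --- Scaled national seasonal budgets (Mt season-1) -------------------------
# Printed (mean, se) components per peatland class; combined columns in the
# source equal the linear sums of these components.

BUDGET_PCM = {
    "NEE": {"bog": (-84.2, 47.4), "fen": (-34.7, 18.9)},
    "CH4": {"bog": (4.6, 1.8), "fen": (2.3, 2.3)},
    "CH4_CO2e": {"bog": (116.0, 44.8), "fen": (56.6, 56.6)},
    "net": {"bog": (31.8, 92.2), "fen": (21.9, 75.5)},
}

BUDGET_NEWMAP = {
    "NEE": {"bog": (-76.0, 36.4), "poor_fen": (-22.6, 2.2), "rich_fen": (-10.2, 2.7)},
    "CH4": {"bog": (3.0, 1.1), "poor_fen": (0.6, 0.2), "rich_fen": (0.5, 0.1)},
    "CH4_CO2e": {"bog": (75.3, 27.4), "poor_fen": (14.6, 5.6), "rich_fen": (11.9, 3.4)},
    "net": {"bog": (-0.8, 63.8), "poor_fen": (-7.9, 7.7), "rich_fen": (1.7, 6.1)},
}

#: Printed combined national figures (mean, se), Mt season-1.
BUDGET_COMBINED = {
    "pcm": {"NEE": (-118.9, 66.4), "CH4": (6.9, 4.1),
            "CH4_CO2e": (172.6, 101.4), "net": (53.7, 167.7)},
    "newmap": {"NEE": (-108.8, 41.3), "CH4": (4.1, 1.5),
               "CH4_CO2e": (101.8, 36.4), "net": (-7.0, 77.6)},
}

#: Seasonal CH4 budget for the Hudson Plains ecozone alone, Mt season-1.
HUDSON_PLAINS_CH4_SEASONAL = 0.6
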