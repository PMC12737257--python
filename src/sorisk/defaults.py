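"""Shipped reference data for the drawdown-zone heavy-metal risk pipeline.

Everything here is configuration-level data, not logic: background values,
toxicity coefficients, grade schemes, reference doses, slope factors and
exposure-parameter catalogues are all user-overridable through the YAML
config surface (:mod:`sorisk.data`, :mod:`sorisk.health`).

Provenance
----------
* ``HENAN_BACKGROUND`` — background values for surface soils of Henan
  Province (mg/kg; Fe converted from g/kg).
* ``HAKANSON_TOXICITY`` — the Hakanson toxicity coefficient set extended
  with Mn = 1; Fe carries no coefficient and is excluded from ecological
  risk by default.
* ``RFD`` / ``SLOPE_FACTOR`` — USEPA RSL/IRIS-style oral, dermal and
  inhalation reference doses (mg/kg/day) and carcinogenic slope factors
  ((mg/kg/day)^-1) as commonly used in soil heavy-metal risk studies.
* ``DRAWDOWN_ZONE_STATS`` — summary statistics of a 24-sample survey of
  reservoir drawdown-zone soils in Henan, China (mean/max/min/SD/CV per
  element, mg/kg), used to calibrate the synthetic generator and as the
  reference mean-concentration vector for desk-scale index checks.
"""

from __future__ import annotations

ELEMENTS = ["Pb", "Cu", "Mn", "Ni", "Zn", "Cd", "Cr", "Hg", "As", "Fe"]

LAND_USES = ("farmland", "forest", "grassland", "flooded")

PATHWAYS = ("ingestion", "dermal", "inhalation")

# mg/kg; Fe stored in mg/kg (19.9 g/kg * 1000)
HENAN_BACKGROUND = {
    "Pb": 22.3, "Cu": 20.0, "Mn": 567.0, "Ni": 27.4, "Zn": 62.5,
    "Cd": 0.065, "Cr": 63.2, "Hg": 0.025, "As": 9.8, "Fe": 19900.0,
}

# Hakanson toxicity coefficients, Mn added at 1; Fe intentionally absent.
HAKANSON_TOXICITY = {
    "Hg": 40.0, "Cd": 30.0, "As": 10.0, "Pb": 5.0, "Cu": 5.0,
    "Ni": 5.0, "Cr": 2.0, "Zn": 1.0, "Mn": 1.0,
}

# 24-sample drawdown-zone survey summary (mg/kg). Fe rows converted from g/kg.
DRAWDOWN_ZONE_STATS = {
    "mean": {"Pb": 28.26, "Cu": 34.55, "Mn": 860.94, "Ni": 38.02, "Zn": 78.42,
             "Cd": 0.11, "Cr": 98.27, "Hg": 0.05, "As": 12.01, "Fe": 34300.0},
    "max": {"Pb": 47.97, "Cu": 63.43, "Mn": 1832.11, "Ni": 62.25, "Zn": 197.57,
            "Cd": 0.20, "Cr": 156.37, "Hg": 0.15, "As": 16.59, "Fe": 48240.0},
    "min": {"Pb": 16.44, "Cu": 16.44, "Mn": 471.38, "Ni": 16.44, "Zn": 33.06,
            "Cd": 0.03, "Cr": 54.85, "Hg": 0.004, "As": 3.35, "Fe": 19170.0},
    "sd": {"Pb": 9.29, "Cu": 12.32, "Mn": 360.16, "Ni": 9.21, "Zn": 34.34,
           "Cd": 0.04, "Cr": 29.74, "Hg": 0.03, "As": 3.52, "Fe": 7190.0},
    "cv": {"Pb": 0.33, "Cu": 0.36, "Mn": 0.42, "Ni": 0.24, "Zn": 0.44,
           "Cd": 0.40, "Cr": 0.30, "Hg": 0.62, "As": 0.29, "Fe": 0.21},
}

# PMF uncertainty inputs for synthetic fixtures: MDL = 5% of background,
# analytical error fraction 10%. Real surveys must supply their own.
DEFAULT_MDL = {el: 0.05 * bv for el, bv in HENAN_BACKGROUND.items()}
DEFAULT_ERROR_FRACTION = {el: 0.10 for el in ELEMENTS}

# Reference doses, mg/kg/day, per pathway.
RFD = {
    "ingestion": {"Pb": 3.5e-3, "Cu": 4.0e-2, "Mn": 4.6e-2, "Ni": 2.0e-2,
                  "Zn": 3.0e-1, "Cd": 1.0e-3, "Cr": 3.0e-3, "Hg": 3.0e-4,
                  "As": 3.0e-4, "Fe": 7.0e-1},
    "dermal": {"Pb": 5.25e-4, "Cu": 1.2e-2, "Mn": 1.84e-3, "Ni": 5.4e-3,
               "Zn": 6.0e-2, "Cd": 1.0e-5, "Cr": 6.0e-5, "Hg": 2.1e-5,
               "As": 1.23e-4, "Fe": 7.0e-1},
    "inhalation": {"Pb": 3.52e-3, "Cu": 4.02e-2, "Mn": 1.43e-5, "Ni": 2.06e-2,
                   "Zn": 3.0e-1, "Cd": 1.0e-3, "Cr": 2.86e-5, "Hg": 8.57e-5,
                   "As": 3.01e-4, "Fe": 7.0e-1},
}

# Carcinogenic slope factors, (mg/kg/day)^-1; elements absent are treated
# as non-carcinogens for that pathway.
SLOPE_FACTOR = {
    "ingestion": {"As": 1.5, "Cd": 6.1, "Cr": 0.5, "Ni": 0.84, "Pb": 8.5e-3},
    "dermal": {"As": 3.66, "Cd": 6.1, "Cr": 20.0, "Ni": 0.84, "Pb": 8.5e-3},
    "inhalation": {"As": 15.1, "Cd": 6.3, "Cr": 42.0, "Ni": 0.84, "Pb": 4.2e-2},
}

# Grade schemes: ordered (label, lower bound) pairs; half-open intervals
# [lower, next lower). A value sitting on a break belongs to the higher grade.
GRADE_SCHEMES = {
    "PI": [("clean", 0.0), ("slight", 1.0), ("moderate", 2.0), ("strong", 3.0)],
    "NIPI": [("clean", 0.0), ("warning", 0.7), ("slight", 1.0),
             ("moderate", 2.0), ("strong", 3.0)],
    "Er": [("low", 0.0), ("moderate", 40.0), ("considerable", 80.0),
           ("high", 160.0), ("very high", 320.0)],
    "RI": [("low", 0.0), ("moderate", 150.0), ("considerable", 300.0),
           ("very high", 600.0)],
    # NIRI scheme mirrors the single-element Er breaks.
    "NIRI": [("low", 0.0), ("moderate", 40.0), ("considerable", 80.0),
             ("high", 160.0), ("very high", 320.0)],
}

# Exposure-parameter catalogue per receptor. Units: IR_ing mg/day,
# IR_inh m3/day, EF day/yr, ED yr, BW kg, SA cm2, AF mg/cm2/day,
# ABS -, PEF m3/kg, CF kg/mg.
EXPOSURE_CATALOGUE = {
    "child": {
        "IR_ing": {"dist": "lognormal", "mean": 200.0, "sd": 100.0},
        "IR_inh": {"dist": "point", "value": 7.5},
        "EF": {"dist": "triangular", "left": 180.0, "mode": 350.0, "right": 365.0},
        "ED": {"dist": "point", "value": 6.0},
        "BW": {"dist": "normal", "mean": 15.0, "sd": 2.0},
        "SA": {"dist": "point", "value": 2800.0},
        "AF": {"dist": "point", "value": 0.2},
        "ABS": {"dist": "point", "value": 0.001},
        "PEF": {"dist": "point", "value": 1.36e9},
        "CF": {"dist": "point", "value": 1e-6},
    },
    "adult": {
        "IR_ing": {"dist": "lognormal", "mean": 100.0, "sd": 50.0},
        "IR_inh": {"dist": "point", "value": 14.5},
        "EF": {"dist": "triangular", "left": 180.0, "mode": 350.0, "right": 365.0},
        "ED": {"dist": "point", "value": 24.0},
        "BW": {"dist": "normal", "mean": 60.0, "sd": 8.0},
        "SA": {"dist": "point", "value": 5700.0},
        "AF": {"dist": "point", "value": 0.07},
        "ABS": {"dist": "point", "value": 0.001},
        "PEF": {"dist": "point", "value": 1.36e9},
        "CF": {"dist": "point", "value": 1e-6},
    },
}

# Averaging-time convention: AT_nc = ED*365 days; AT_ca = 70 yr * 365 days.
AT_CARCINOGENIC_YEARS = 70.0

HI_THRESHOLD = 1.0
TCR_THRESHOLD = 1e-4
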