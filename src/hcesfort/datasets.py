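"""Packaged parameter tables and the default synthetic food system.

Two kinds of data live here.  Parameter tables that the study itself
prints (the three fortification scenarios) are shipped verbatim as CSV.
Tables that in a real application come from national sources — the food
composition table, unit-conversion factors, energy requirements, H-AR /
H-UL thresholds, recipe flour fractions — are shipped as *synthetic*,
documented placeholders (files suffixed ``_synthetic``) or generated
deterministically in code, and are fully overridable by user files with
the same schemas.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .nutrients import ENERGY, NUTRIENTS

_COMP_COLS = [ENERGY] + NUTRIENTS


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("hcesfort.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_scenario_table() -> pd.DataFrame:
    """Long-format fortification scenario parameters (content per 100 g).

    Columns: scenario, vehicle_item, nutrient, content_per_100g.  Vehicles
    absent for a nutrient (oil and sugar carry only vitamin A) simply have
    no row.
    """
    df = _read_packaged("fortification_scenarios.csv")
    df["content_per_100g"] = df["content_per_100g"].astype(float)
    return df


def load_requirement_table() -> pd.DataFrame:
    """H-AR / H-UL placeholder thresholds for the adult female."""
    return _read_packaged("requirements_nutrients_synthetic.csv")


def load_energy_requirement_table() -> pd.DataFrame:
    """Age/sex-band energy requirements with the reference row flagged."""
    return _read_packaged("requirements_energy_synthetic.csv")


def load_energy_increments() -> pd.DataFrame:
    """Pregnancy / lactation energy increments (kcal/day)."""
    return _read_packaged("energy_increments_synthetic.csv")


def load_recipe_table() -> pd.DataFrame:
    """Fortifiable wheat-flour fraction of flour-containing products."""
    return _read_packaged("recipes_synthetic.csv")


# ---------------------------------------------------------------------------
# Default synthetic food system
# ---------------------------------------------------------------------------

# Named staple/vegetable/fruit/animal-source items with hand-set per-100-g
# compositions broadly typical of an eastern-African food composition table.
# Fields: energy, vitA, thiamine, riboflavin, niacin, B6, folate, B12, iron,
# zinc, edible fraction, base coverage (probability of any consumption in a
# 7-day recall), median consumed quantity among consumers (g/day per AFE),
# SEP slope on coverage (log-odds per unit expenditure percentile), seasonal
# amplitude and peak study-day (None = aseasonal).
_NAMED_ITEMS = [
    # code,           kcal,  vA, thi,  rib,  nia,  b6,  fol,  b12, fe,  zn,  ed,  cov, med, slope, amp, peak
    ("maize_flour",    362,   0, 0.25, 0.08, 1.8, 0.30,  25, 0.0, 2.4, 1.2, 1.00, 0.95, 330, -0.3, 0.0, None),
    ("rice",           360,   0, 0.07, 0.05, 1.6, 0.16,   8, 0.0, 0.8, 1.1, 1.00, 0.30,  60,  0.8, 0.0, None),
    ("cassava",        160,   1, 0.09, 0.05, 0.9, 0.09,  27, 0.0, 0.3, 0.3, 0.80, 0.35,  80, -0.5, 0.0, None),
    ("sweet_potato",    86,   5, 0.08, 0.06, 0.6, 0.21,  11, 0.0, 0.6, 0.3, 0.86, 0.30,  70, -0.4, 0.3, 170),
    ("potato",          77,   0, 0.08, 0.03, 1.0, 0.30,  16, 0.0, 0.8, 0.3, 0.85, 0.25,  60,  0.4, 0.0, None),
    ("beans",          337,   0, 0.60, 0.20, 2.0, 0.40, 394, 0.0, 5.1, 2.8, 1.00, 0.50,  40,  0.2, 0.0, None),
    ("groundnut",      567,   0, 0.64, 0.14,12.0, 0.35, 240, 0.0, 4.6, 3.3, 0.70, 0.40,  30,  0.2, 0.0, None),
    ("leafy_greens",    36, 280, 0.07, 0.19, 0.7, 0.17, 120, 0.0, 2.7, 0.4, 0.90, 0.80,  80,  0.1, 0.5, 275),
    ("tomato",          18,  42, 0.04, 0.02, 0.6, 0.08,  15, 0.0, 0.3, 0.2, 0.95, 0.70,  40,  0.4, 0.2, 240),
    ("onion",           40,   0, 0.05, 0.03, 0.1, 0.12,  19, 0.0, 0.2, 0.2, 0.90, 0.60,  15,  0.5, 0.0, None),
    ("pumpkin",         26, 250, 0.05, 0.11, 0.6, 0.06,  16, 0.0, 0.8, 0.3, 0.75, 0.30,  60, -0.1, 0.5, 300),
    ("mango",           60,  54, 0.03, 0.04, 0.7, 0.12,  43, 0.0, 0.2, 0.1, 0.69, 0.35, 100,  0.1, 0.9, 240),
    ("papaya",          43,  47, 0.02, 0.03, 0.4, 0.04,  37, 0.0, 0.3, 0.1, 0.62, 0.15,  80,  0.2, 0.6, 220),
    ("banana",          89,   3, 0.03, 0.07, 0.7, 0.37,  20, 0.0, 0.3, 0.2, 0.64, 0.40,  60,  0.4, 0.0, None),
    ("eggs",           143, 140, 0.04, 0.46, 0.1, 0.17,  47, 1.1, 1.8, 1.3, 0.88, 0.30,  25,  1.0, 0.0, None),
    ("dried_fish",     309,  40, 0.10, 0.30, 6.0, 0.40,  30, 6.0, 4.5, 2.5, 0.85, 0.55,  20,  0.3, 0.0, None),
    ("fresh_fish",     100,  15, 0.06, 0.10, 2.5, 0.30,  15, 2.0, 1.0, 0.8, 0.70, 0.25,  40,  0.5, 0.0, None),
    ("goat_meat",      143,   0, 0.11, 0.25, 4.0, 0.30,   5, 2.2, 3.7, 4.0, 0.85, 0.20,  30,  0.9, 0.0, None),
    ("chicken",        215,  16, 0.07, 0.13, 6.0, 0.35,   6, 0.3, 1.3, 1.3, 0.70, 0.20,  35,  0.8, 0.0, None),
    ("milk",            61,  46, 0.04, 0.18, 0.1, 0.04,   5, 0.45,0.0, 0.4, 1.00, 0.15,  50,  1.2, 0.0, None),
]

# Fortification vehicles and wheat products.  The wheat-flour base row
# equals the no-fortification scenario vector by construction; product base
# rows carry the flour share of those intrinsic values.
_VEHICLE_ITEMS = [
    ("oil",         884, [0, 0.0, 0.0, 0.0, 0.0, 0, 0.0, 0.0, 0.0]),
    ("sugar",       400, [0, 0.0, 0.0, 0.0, 0.0, 0, 0.0, 0.0, 0.0]),
    ("wheat_flour", 364, [0, 0.2, 0.1, 2.4, 0.5, 240, 0.0, 2.0, 0.5]),
    ("bread",       266, [0, 0.14, 0.07, 1.68, 0.35, 168, 0.0, 1.40, 0.35]),
    ("buns_scones", 300, [0, 0.13, 0.065, 1.56, 0.325, 156, 0.0, 1.30, 0.325]),
    ("mandasi",     400, [0, 0.10, 0.05, 1.20, 0.25, 120, 0.0, 1.00, 0.25]),
]

#: Items counted together as the "wheat flour and products" vehicle group.
WHEAT_GROUP = ["wheat_flour", "bread", "buns_scones", "mandasi"]

N_FOOD_ITEMS = 136
_FOOD_SYSTEM_SEED = 20160401  # fixed: the food list is part of the package


def default_food_list() -> pd.DataFrame:
    """Build the 136-item synthetic food list with consumption parameters.

    Columns: item_code, energy and nutrient per-100-g values, edible
    fraction, base 7-day coverage probability, median quantity among
    consumers (g/day per AFE), SEP coverage slope, seasonal amplitude and
    peak study-day (NaN for aseasonal items).
    """
    rows = []
    for (code, kcal, va, thi, rib, nia, b6, fol, b12, fe, zn,
         ed, cov, med, slope, amp, peak) in _NAMED_ITEMS:
        rows.append(dict(
            item_code=code, energy_kcal=kcal, vita_rae_ug=va, thiamine_mg=thi,
            riboflavin_mg=rib, niacin_mg=nia, vitb6_mg=b6, folate_ug=fol,
            vitb12_ug=b12, iron_mg=fe, zinc_mg=zn, edible_fraction=ed,
            coverage=cov, median_g_day_afe=med, sep_slope=slope,
            seasonal_amplitude=amp,
            seasonal_peak_day=np.nan if peak is None else float(peak),
        ))
    for code, kcal, nutr in _VEHICLE_ITEMS:
        rows.append(dict(
            item_code=code, energy_kcal=kcal,
            **dict(zip(NUTRIENTS, (float(v) for v in nutr))),
            edible_fraction=1.0, coverage=np.nan, median_g_day_afe=np.nan,
            sep_slope=np.nan, seasonal_amplitude=0.0, seasonal_peak_day=np.nan,
        ))
    # Pad with low-coverage miscellaneous items up to the 136-item list.
    rng = np.random.default_rng(_FOOD_SYSTEM_SEED)
    n_misc = N_FOOD_ITEMS - len(rows)
    for i in range(n_misc):
        kcal = float(rng.uniform(30, 420))
        nutr = {
            "vita_rae_ug": float(rng.exponential(6.0)),
            "thiamine_mg": float(rng.uniform(0, 0.15)),
            "riboflavin_mg": float(rng.uniform(0, 0.12)),
            "niacin_mg": float(rng.uniform(0, 2.0)),
            "vitb6_mg": float(rng.uniform(0, 0.25)),
            "folate_ug": float(rng.uniform(0, 60)),
            "vitb12_ug": float(rng.exponential(0.05)),
            "iron_mg": float(rng.uniform(0, 2.0)),
            "zinc_mg": float(rng.uniform(0, 1.0)),
        }
        rows.append(dict(
            item_code=f"misc_{i + 1:03d}", energy_kcal=kcal, **nutr,
            edible_fraction=float(rng.uniform(0.75, 1.0)),
            coverage=float(rng.uniform(0.02, 0.20)),
            median_g_day_afe=float(rng.uniform(5, 50)),
            sep_slope=float(rng.normal(0.2, 0.3)),
            seasonal_amplitude=0.0, seasonal_peak_day=np.nan,
        ))
    df = pd.DataFrame(rows)
    assert len(df) == N_FOOD_ITEMS
    return df


def default_fct(food_list: pd.DataFrame | None = None) -> pd.DataFrame:
    """Food composition table (per 100 g edible) for the synthetic food list."""
    fl = default_food_list() if food_list is None else food_list
    return fl[["item_code"] + _COMP_COLS].copy()


def default_units(food_list: pd.DataFrame | None = None) -> pd.DataFrame:
    """Unit-conversion table for the synthetic food system.

    Every item can be reported in kilograms; a deterministic subset also
    has a nonstandard unit (piece/pail/sachet/cup) with an item-specific
    kilogram factor, exercising the conversion path.
    """
    fl = default_food_list() if food_list is None else food_list
    rng = np.random.default_rng(_FOOD_SYSTEM_SEED + 1)
    rows = []
    for _, r in fl.iterrows():
        rows.append(dict(item_code=r.item_code, unit_code="kilogram",
                         kg_per_unit=1.0, edible_fraction=r.edible_fraction))
        if rng.random() < 0.5:
            unit = rng.choice(["piece", "pail", "sachet", "cup"])
            factor = {"piece": rng.uniform(0.05, 0.4),
                      "pail": rng.uniform(1.0, 5.0),
                      "sachet": rng.uniform(0.01, 0.1),
                      "cup": rng.uniform(0.1, 0.35)}[unit]
            rows.append(dict(item_code=r.item_code, unit_code=str(unit),
                             kg_per_unit=round(float(factor), 4),
                             edible_fraction=r.edible_fraction))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Default per-stratum vehicle coverage and consumption (study conditions)
# ---------------------------------------------------------------------------

#: Probability of any 7-day consumption of each vehicle group by residence
#: and within-residence expenditure quintile (index 0 = lowest SEP).
DEFAULT_VEHICLE_COVERAGE = {
    "oil": {"rural": [0.44, 0.66, 0.75, 0.83, 0.91],
            "urban": [0.87, 0.97, 0.98, 0.98, 0.99]},
    "sugar": {"rural": [0.17, 0.34, 0.47, 0.62, 0.80],
              "urban": [0.76, 0.92, 0.97, 0.98, 0.97]},
    "wheat_flour": {"rural": [0.20, 0.33, 0.42, 0.53, 0.73],
                    "urban": [0.64, 0.84, 0.92, 0.95, 0.94]},
}

#: Median consumed quantity among consumers, g/day per AFE, same layout.
DEFAULT_VEHICLE_MEDIAN = {
    "oil": {"rural": [3, 6, 9, 11, 19], "urban": [9, 15, 22, 26, 39]},
    "sugar": {"rural": [11, 18, 21, 26, 36], "urban": [23, 28, 36, 40, 45]},
    "wheat_flour": {"rural": [2, 3, 4, 6, 16], "urban": [7, 19, 29, 40, 58]},
}

#: Conditional probability that a wheat-consuming household reports each
#: wheat item (at least one is forced).
WHEAT_ITEM_SHARES = {"mandasi": 0.67, "bread": 0.42,
                     "buns_scones": 0.27, "wheat_flour": 0.15}
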