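"""Food composition and fortification-scenario arithmetic.

Scenario parameters give the *total* per-100-g content of each fortified
vehicle for every covered nutrient (the no-fortification row is the
vehicle's intrinsic composition), so applying a scenario to a vehicle
replaces the base value.  Flour-containing products are adjusted in
proportion to their fortifiable-flour mass fraction::

    product = base + flour_fraction * (flour[scenario] - flour[no_fortification])

Energy is never altered by a scenario: fortification adds micronutrients,
not calories.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .nutrients import ENERGY, NUTRIENTS, ConfigurationError

logger = logging.getLogger(__name__)

NO_FORTIFICATION = "no_fortification"
_COMP_COLS = [ENERGY] + NUTRIENTS


def validate_fct(fct: pd.DataFrame, consumed_items=None) -> pd.DataFrame:
    """Check composition-table completeness and nonnegativity.

    If ``consumed_items`` is given, every consumed item code must have a
    composition row; missing codes are reported together in the error.
    """
    missing_cols = [c for c in ["item_code"] + _COMP_COLS if c not in fct.columns]
    if missing_cols:
        raise ConfigurationError(f"composition table lacks columns: {missing_cols}")
    if fct["item_code"].duplicated().any():
        dup = fct.loc[fct["item_code"].duplicated(), "item_code"].tolist()
        raise ConfigurationError(f"duplicate composition rows: {dup}")
    if (fct[_COMP_COLS] < 0).any().any():
        raise ConfigurationError("composition values must be nonnegative")
    if consumed_items is not None:
        gaps = sorted(set(consumed_items) - set(fct["item_code"]))
        if gaps:
            raise ConfigurationError(f"consumed items missing from composition table: {gaps}")
    return fct


def scenario_vectors(scenario_table: pd.DataFrame) -> dict[str, dict[str, dict[str, float]]]:
    """Pivot the long scenario table into scenario -> vehicle -> nutrient -> value."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for (scen, veh), grp in scenario_table.groupby(["scenario", "vehicle_item"]):
        out.setdefault(scen, {})[veh] = dict(
            zip(grp["nutrient"], grp["content_per_100g"].astype(float))
        )
    return out


def scenario_composition(
    fct: pd.DataFrame,
    scenario_table: pd.DataFrame,
    recipes: pd.DataFrame,
    scenario: str,
    flour_item: str = "wheat_flour",
) -> pd.DataFrame:
    """Per-100-g composition of every item under a fortification scenario.

    Vehicles listed in the scenario table have their covered nutrients
    replaced; items with a recipe entry receive the flour-fraction-scaled
    fortificant increment; everything else (and energy throughout) is
    returned unchanged.
    """
    vectors = scenario_vectors(scenario_table)
    if scenario not in vectors:
        known = sorted(vectors)
        raise ConfigurationError(f"unknown scenario {scenario!r}; known: {known}")
    if NO_FORTIFICATION not in vectors:
        raise ConfigurationError(f"scenario table lacks the {NO_FORTIFICATION!r} baseline")

    comp = validate_fct(fct).set_index("item_code")[_COMP_COLS].astype(float).copy()

    # Vehicles: replace covered nutrients with the scenario's total content.
    for vehicle, contents in vectors[scenario].items():
        if vehicle not in comp.index:
            logger.warning("scenario vehicle %r not in composition table; skipped", vehicle)
            continue
        for nutrient, value in contents.items():
            comp.loc[vehicle, nutrient] = value

    # Flour products: add the recipe-proportional fortificant increment.
    if len(recipes):
        ff = recipes["flour_fraction"].astype(float)
        if ((ff < 0) | (ff > 1)).any():
            raise ConfigurationError("flour_fraction must lie in [0, 1]")
        scen_flour = vectors[scenario].get(flour_item)
        base_flour = vectors[NO_FORTIFICATION].get(flour_item)
        if scen_flour is None or base_flour is None:
            raise ConfigurationError(
                f"recipes provided but {flour_item!r} has no scenario composition"
            )
        for item, frac in zip(recipes["item_code"], ff):
            if item not in comp.index:
                logger.warning("recipe item %r not in composition table; skipped", item)
                continue
            for nutrient, value in scen_flour.items():
                delta = value - base_flour.get(nutrient, 0.0)
                comp.loc[item, nutrient] += frac * delta

    comp[ENERGY] = fct.set_index("item_code")[ENERGY].astype(float)  # never altered
    return comp.reset_index()


def household_supply(
    daily_kg: pd.DataFrame, composition: pd.DataFrame
) -> pd.DataFrame:
    """Daily household energy and nutrient supply from cleaned consumption.

    ``daily_kg`` has one row per (household, item) with ``daily_edible_kg``;
    supply of nutrient *n* is ``sum_items kg * 10 * content_per_100g`` (a
    kilogram is ten 100-g units).  Returns one row per household with
    energy and nutrient columns.
    """
    validate_fct(composition, consumed_items=daily_kg["item_code"].unique())
    comp = composition.set_index("item_code")[_COMP_COLS]
    per_record = comp.reindex(daily_kg["item_code"]).to_numpy() * (
        10.0 * daily_kg["daily_edible_kg"].to_numpy()[:, None]
    )
    wide = pd.DataFrame(per_record, columns=_COMP_COLS)
    wide["household_id"] = daily_kg["household_id"].to_numpy()
    return wide.groupby("household_id", as_index=False, sort=True)[_COMP_COLS].sum()
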