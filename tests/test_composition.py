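"""Fortification-scenario composition arithmetic and household supplies."""

import numpy as np
import pandas as pd
import pytest

from hcesfort import datasets
from hcesfort.composition import (
    household_supply,
    scenario_composition,
    scenario_vectors,
)
from hcesfort.nutrients import ENERGY, NUTRIENTS, SCENARIOS, ConfigurationError


def _toy_fct():
    rows = []
    for code, kcal in [("oil", 884), ("sugar", 400), ("wheat_flour", 364),
                       ("bread", 266), ("maize", 362)]:
        row = {"item_code": code, ENERGY: float(kcal)}
        row.update({n: 0.0 for n in NUTRIENTS})
        rows.append(row)
    fct = pd.DataFrame(rows)
    fct.loc[fct.item_code == "wheat_flour", "thiamine_mg"] = 0.2
    fct.loc[fct.item_code == "maize", "zinc_mg"] = 1.1
    return fct


def test_oil_status_quo_vitamin_a_is_1000():
    comp = scenario_composition(
        _toy_fct(), datasets.load_scenario_table(), datasets.load_recipe_table(),
        "status_quo",
    ).set_index("item_code")
    assert comp.loc["oil", "vita_rae_ug"] == 1000.0


def test_no_fortification_leaves_base_and_zero_vehicle_vitamin_a():
    fct = _toy_fct()
    comp = scenario_composition(
        fct, datasets.load_scenario_table(), datasets.load_recipe_table(),
        "no_fortification",
    ).set_index("item_code")
    for v in ["oil", "sugar", "wheat_flour"]:
        assert comp.loc[v, "vita_rae_ug"] == 0.0
    assert comp.loc["maize", "zinc_mg"] == 1.1  # non-vehicle untouched


def test_flour_product_recipe_rule_hand_arithmetic():
    # flour_fraction 0.6, flour vitamin A rising 0 -> 80: product gains 48.
    fct = _toy_fct()
    recipes = pd.DataFrame({"item_code": ["bread"], "flour_fraction": [0.6]})
    comp = scenario_composition(
        fct, datasets.load_scenario_table(), recipes, "status_quo"
    ).set_index("item_code")
    assert comp.loc["bread", "vita_rae_ug"] == pytest.approx(0.0 + 0.6 * 80.0)
    # thiamine rises by 0.6 * (0.5 - 0.2)
    assert comp.loc["bread", "thiamine_mg"] == pytest.approx(0.6 * 0.3)


def test_energy_never_altered_by_scenario():
    fct = _toy_fct()
    for scen in SCENARIOS:
        comp = scenario_composition(
            fct, datasets.load_scenario_table(), datasets.load_recipe_table(), scen
        ).set_index("item_code")
        for code in fct["item_code"]:
            assert comp.loc[code, ENERGY] == fct.set_index("item_code").loc[code, ENERGY]


def test_recipe_without_flour_composition_errors():
    table = datasets.load_scenario_table()
    table = table[table["vehicle_item"] != "wheat_flour"]
    recipes = pd.DataFrame({"item_code": ["bread"], "flour_fraction": [0.6]})
    with pytest.raises(ConfigurationError):
        scenario_composition(_toy_fct(), table, recipes, "status_quo")


def test_unknown_scenario_errors():
    with pytest.raises(ConfigurationError, match="unknown scenario"):
        scenario_composition(_toy_fct(), datasets.load_scenario_table(),
                             datasets.load_recipe_table(), "double_fortified")


def test_household_supply_arithmetic_and_additivity():
    fct = _toy_fct()
    comp = scenario_composition(fct, datasets.load_scenario_table(),
                                datasets.load_recipe_table(), "status_quo")
    one = pd.DataFrame({"household_id": ["h1"], "item_code": ["oil"],
                        "daily_edible_kg": [0.2]})
    s = household_supply(one, comp)
    # 0.2 kg/day at 1000 ug/100 g -> 2000 ug/day; at 884 kcal/100 g -> 1768 kcal
    assert s["vita_rae_ug"].iloc[0] == pytest.approx(0.2 * 10 * 1000)
    assert s[ENERGY].iloc[0] == pytest.approx(0.2 * 10 * 884)

    split = pd.DataFrame({"household_id": ["h1", "h1"], "item_code": ["oil", "oil"],
                          "daily_edible_kg": [0.1, 0.1]})
    s2 = household_supply(split, comp)
    pd.testing.assert_frame_equal(s, s2)


def test_supply_monotone_across_scenarios_random_tables():
    """Scenario upgrades can only add nutrients, for any consumption table."""
    rng = np.random.default_rng(42)
    fct = _toy_fct()
    scen_table = datasets.load_scenario_table()
    recipes = datasets.load_recipe_table()
    comps = {s: scenario_composition(fct, scen_table, recipes, s) for s in SCENARIOS}
    for _ in range(20):
        n = rng.integers(1, 8)
        daily = pd.DataFrame({
            "household_id": rng.choice(["a", "b", "c"], size=n),
            "item_code": rng.choice(fct["item_code"], size=n),
            "daily_edible_kg": rng.exponential(0.1, size=n),
        })
        supplies = [household_supply(daily, comps[s]).set_index("household_id")
                    for s in SCENARIOS]
        for lo, hi in zip(supplies, supplies[1:]):
            assert (hi[NUTRIENTS] - lo[NUTRIENTS] >= -1e-12).all().all()
            pd.testing.assert_series_equal(lo[ENERGY], hi[ENERGY])


def test_missing_composition_row_is_load_time_error():
    fct = _toy_fct()
    daily = pd.DataFrame({"household_id": ["h1"], "item_code": ["ugali"],
                          "daily_edible_kg": [0.1]})
    with pytest.raises(ConfigurationError, match="ugali"):
        household_supply(daily, fct)


def test_packaged_table_is_scenario_monotone_nutrient_wise():
    vec = scenario_vectors(datasets.load_scenario_table())
    for lo, hi in zip(SCENARIOS, SCENARIOS[1:]):
        for vehicle, contents in vec[lo].items():
            for nutrient, value in contents.items():
                assert vec[hi][vehicle][nutrient] >= value
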