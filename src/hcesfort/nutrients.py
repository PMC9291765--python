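"""Canonical nutrient and vehicle identifiers used across the package.

Column names encode the unit so that tables are self-describing:
``vita_rae_ug`` is micrograms of retinol activity equivalents per 100 g
(composition) or per day (supply), and so on.
"""

ENERGY = "energy_kcal"

#: The nine micronutrients covered by the fortification standard, in the
#: conventional reporting order.
NUTRIENTS = [
    "vita_rae_ug",
    "thiamine_mg",
    "riboflavin_mg",
    "niacin_mg",
    "vitb6_mg",
    "folate_ug",
    "vitb12_ug",
    "iron_mg",
    "zinc_mg",
]

NUTRIENT_LABELS = {
    "vita_rae_ug": "Vitamin A (ug RAE)",
    "thiamine_mg": "Thiamine (mg)",
    "riboflavin_mg": "Riboflavin (mg)",
    "niacin_mg": "Niacin (mg)",
    "vitb6_mg": "Vitamin B6 (mg)",
    "folate_ug": "Folate (ug)",
    "vitb12_ug": "Vitamin B12 (ug)",
    "iron_mg": "Iron (mg)",
    "zinc_mg": "Zinc (mg)",
}

#: Fortification vehicle item codes.  ``wheat_flour`` also fortifies
#: flour-containing products through the recipe table.
VEHICLES = ["oil", "sugar", "wheat_flour"]

#: Scenario names in increasing order of fortificant content.
SCENARIOS = ["no_fortification", "status_quo", "improved_compliance"]


class ConfigurationError(ValueError):
    """Raised when an input table or parameter set is internally invalid."""


class DataError(ValueError):
    """Raised when survey data violate a structural precondition."""
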