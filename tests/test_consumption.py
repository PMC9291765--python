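"""Unit-conversion, outlier replacement, and daily-scaling behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcesfort.consumption import (
    REJECT_MISSING_CONVERSION,
    clean_consumption,
    daily_apparent_consumption,
    replace_outliers,
    standardize_quantities,
)


def _units(rows):
    return pd.DataFrame(rows, columns=["item_code", "unit_code", "kg_per_unit", "edible_fraction"])


def _records(rows):
    return pd.DataFrame(rows, columns=["household_id", "item_code", "quantity", "unit_code"])


@pytest.mark.parametrize(
    "qty, kg_per_unit, edible, expected",
    [
        (2.0, 1.5, 1.0, 3.0),      # plain multiplication
        (0.5, 1.0, 1.0, 0.5),      # kilogram is the identity unit
        (1.0, 1.0, 0.64, 0.64),    # edible-portion scaling (e.g. banana skins)
    ],
)
def test_standardize_quantity(qty, kg_per_unit, edible, expected):
    rec = _records([("h1", "it", qty, "u")])
    units = _units([("it", "u", kg_per_unit, edible)])
    std, rejects = standardize_quantities(rec, units)
    assert rejects.empty
    assert std["weekly_edible_kg"].iloc[0] == pytest.approx(expected)


def test_missing_conversion_goes_to_rejects_not_crash():
    rec = _records([("h1", "it", 1.0, "pail"), ("h1", "it", 2.0, "kg")])
    units = _units([("it", "kg", 1.0, 1.0)])
    std, rejects = standardize_quantities(rec, units)
    assert len(std) == 1 and len(rejects) == 1
    assert rejects["reject_reason"].iloc[0] == REJECT_MISSING_CONVERSION


def test_outlier_replacement_hand_computed():
    # quantities {1, 2, 2, 3, 500}: on the log scale the robust z of 500
    # is (log500 - log2) / (1.4826 * MAD) ~ 9.2 > 3, everything else < 3;
    # the flagged record takes the item median, 2.
    weekly = pd.DataFrame({
        "household_id": list("abcde"),
        "item_code": ["x"] * 5,
        "weekly_edible_kg": [1.0, 2.0, 2.0, 3.0, 500.0],
    })
    out = replace_outliers(weekly)
    assert out["weekly_edible_kg"].tolist() == [1.0, 2.0, 2.0, 3.0, 2.0]
    assert out["outlier_replaced"].tolist() == [False, False, False, False, True]


def test_outlier_zero_dispersion_guard():
    weekly = pd.DataFrame({
        "household_id": list("abcd"),
        "item_code": ["x"] * 4,
        "weekly_edible_kg": [2.0, 2.0, 2.0, 2.0],
    })
    out = replace_outliers(weekly)
    assert not out["outlier_replaced"].any()
    assert out["weekly_edible_kg"].tolist() == [2.0] * 4


def test_outlier_replacement_idempotent():
    rng = np.random.default_rng(3)
    weekly = pd.DataFrame({
        "household_id": [f"h{i}" for i in range(200)],
        "item_code": rng.choice(["a", "b", "c"], size=200),
        "weekly_edible_kg": rng.lognormal(0, 0.6, size=200),
    })
    weekly.loc[:4, "weekly_edible_kg"] *= 300
    once = replace_outliers(weekly)
    twice = replace_outliers(once.drop(columns="outlier_replaced"))
    pd.testing.assert_series_equal(
        once["weekly_edible_kg"], twice["weekly_edible_kg"]
    )
    assert not twice["outlier_replaced"].any()


@given(
    st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=40)
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_replacement_never_increases_item_max(values):
    weekly = pd.DataFrame({
        "household_id": [f"h{i}" for i in range(len(values))],
        "item_code": ["x"] * len(values),
        "weekly_edible_kg": values,
    })
    out = replace_outliers(weekly)
    assert out["weekly_edible_kg"].max() <= max(values) + 1e-12
    assert len(out) == len(values)  # record conservation


@pytest.mark.parametrize("weekly, daily", [(14.0, 2.0), (0.0, 0.0)])
def test_daily_scaling(weekly, daily):
    df = pd.DataFrame({"household_id": ["h"], "item_code": ["x"],
                       "weekly_edible_kg": [weekly]})
    out = daily_apparent_consumption(df)
    assert out["daily_edible_kg"].iloc[0] == pytest.approx(daily)


def test_weekly_mass_conserved_through_daily_scaling(small_dataset):
    households, roster, consumption, _ = small_dataset
    from hcesfort.datasets import default_units

    std, _ = standardize_quantities(consumption, default_units())
    from hcesfort.consumption import aggregate_household_item

    agg = aggregate_household_item(std)
    daily = daily_apparent_consumption(agg)
    assert daily["daily_edible_kg"].sum() * 7 == pytest.approx(
        agg["weekly_edible_kg"].sum()
    )


def test_injected_outliers_flagged():
    """At multiplier 100 the detector catches at least 90% of injected
    records while the false-flag rate among untouched records stays below
    1%.  The catch rate is bounded away from 100% by design: quantities
    pool across households of very different size and wealth, so a
    multiplied record starting in the low tail of an item's pooled
    distribution can land inside the robust threshold."""
    from hcesfort.datasets import default_units
    from hcesfort.synthetic import SyntheticConfig, generate_dataset, inject_outliers

    _, _, consumption, _ = generate_dataset(SyntheticConfig(n_households=1000, seed=11))
    contaminated, idx = inject_outliers(consumption, rate=0.01, multiplier=100.0, seed=5)
    cleaned, rejects = clean_consumption(contaminated, default_units())
    assert rejects.empty
    flagged = cleaned.set_index(["household_id", "item_code"])["outlier_replaced"]
    hit_pairs = set(map(tuple, contaminated.iloc[idx][["household_id", "item_code"]].to_numpy()))
    all_pairs = set(map(tuple, contaminated[["household_id", "item_code"]].to_numpy()))
    caught = np.mean([flagged.loc[p] for p in hit_pairs])
    false = np.mean([flagged.loc[p] for p in all_pairs - hit_pairs])
    assert caught >= 0.90
    assert false <= 0.01
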