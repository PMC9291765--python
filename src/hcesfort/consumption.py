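"""Cleaning of 7-day household food-recall records.

Raw records arrive as (household, item, quantity, unit) in whatever units
the survey used.  The pipeline is:

1. convert each record to kilograms of edible food per week using an
   (item, unit) conversion table;
2. aggregate to one row per household-item;
3. flag outlying weekly quantities per item with a robust z-score on the
   log scale and replace them with the item's population median;
4. divide by seven to obtain daily apparent consumption.

Records whose (item, unit) pair has no conversion entry are not fatal:
they are collected into a rejects table with a reason code and excluded,
so a handful of bad codes never aborts a national survey run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REJECT_MISSING_CONVERSION = "missing_conversion"
REJECT_NEGATIVE_QUANTITY = "negative_quantity"

DAYS_PER_WEEK = 7.0


def standardize_quantities(
    consumption: pd.DataFrame, units: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert raw records to kilograms of edible food per week.

    Parameters
    ----------
    consumption
        Columns ``household_id, item_code, quantity, unit_code``.
    units
        Columns ``item_code, unit_code, kg_per_unit, edible_fraction``.

    Returns
    -------
    (standardized, rejects)
        ``standardized`` has one row per input record with a
        ``weekly_edible_kg`` column; ``rejects`` collects unconvertible
        records with a ``reject_reason`` column.
    """
    if (units["kg_per_unit"] <= 0).any():
        raise ValueError("kg_per_unit must be positive")
    ef = units["edible_fraction"]
    if ((ef <= 0) | (ef > 1)).any():
        raise ValueError("edible_fraction must lie in (0, 1]")

    merged = consumption.merge(
        units, on=["item_code", "unit_code"], how="left", validate="m:1"
    )
    bad_qty = merged["quantity"] < 0
    missing = merged["kg_per_unit"].isna() & ~bad_qty
    ok = ~(bad_qty | missing)

    rejects = merged.loc[~ok, ["household_id", "item_code", "quantity", "unit_code"]].copy()
    rejects["reject_reason"] = np.where(
        bad_qty[~ok], REJECT_NEGATIVE_QUANTITY, REJECT_MISSING_CONVERSION
    )

    out = merged.loc[ok].copy()
    out["weekly_edible_kg"] = (
        out["quantity"] * out["kg_per_unit"] * out["edible_fraction"]
    )
    return (
        out[["household_id", "item_code", "weekly_edible_kg"]],
        rejects.reset_index(drop=True),
    )


def aggregate_household_item(standardized: pd.DataFrame) -> pd.DataFrame:
    """Sum weekly edible kilograms to one row per (household, item)."""
    return (
        standardized.groupby(["household_id", "item_code"], as_index=False, sort=True)
        ["weekly_edible_kg"].sum()
    )


def replace_outliers(
    weekly: pd.DataFrame,
    z_threshold: float = 3.0,
    value_col: str = "weekly_edible_kg",
    max_iter: int = 10,
) -> pd.DataFrame:
    """Flag and median-replace outlying quantities per food item.

    For each item, a robust z-score is computed over the *nonzero*
    quantities on the log scale::

        z = (log q - median(log q)) / (1.4826 * MAD(log q))

    Records with ``|z| > z_threshold`` are replaced by the item's median
    reported quantity.  Flagging is iterated to a fixed point: gross
    outliers inflate the MAD and can mask one another, so after
    replacement the robust statistics are recomputed and flagging is
    repeated until the flag set stabilizes (typically one extra round).
    The fixed point makes the operation idempotent — every surviving
    record is within the threshold of the *cleaned* statistics, and
    replaced records sit at the median, whose z-score is zero.

    Items whose MAD is zero have no dispersion to judge against and are
    left alone; zero-quantity records are never flagged.
    """
    out = weekly.copy()
    q0 = out[value_col].to_numpy(dtype=float)
    flag = np.zeros(len(out), dtype=bool)
    repl = q0.copy()

    for _, idx in out.groupby("item_code").indices.items():
        nz = q0[idx] > 0
        if nz.sum() < 2:
            continue
        logq0 = np.log(q0[idx[nz]])
        hit = np.zeros(nz.sum(), dtype=bool)
        for _ in range(max_iter):
            current = np.where(hit, np.nan, logq0)
            med = np.nanmedian(current)
            cleaned = np.where(hit, med, logq0)
            mad = np.median(np.abs(cleaned - med))
            scale = 1.4826 * mad
            if scale == 0:
                break
            new_hit = np.abs((logq0 - med) / scale) > z_threshold
            if (new_hit == hit).all():
                break
            hit = new_hit
        if not hit.any():
            continue
        item_median = np.exp(np.nanmedian(np.where(hit, np.nan, logq0))) \
            if not hit.all() else np.median(np.exp(logq0))
        sub = idx[nz][hit]
        flag[sub] = True
        repl[sub] = item_median

    out[value_col] = repl
    out["outlier_replaced"] = flag
    return out


def daily_apparent_consumption(
    weekly: pd.DataFrame, value_col: str = "weekly_edible_kg"
) -> pd.DataFrame:
    """Scale cleaned weekly quantities to kg/day (7-day recall)."""
    out = weekly.copy()
    out["daily_edible_kg"] = out[value_col] / DAYS_PER_WEEK
    return out.drop(columns=[value_col])


def clean_consumption(
    consumption: pd.DataFrame,
    units: pd.DataFrame,
    z_threshold: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cleaning pipeline: raw records -> daily apparent consumption.

    Returns ``(cleaned, rejects)`` where ``cleaned`` has one row per
    (household, item) with columns ``daily_edible_kg`` and
    ``outlier_replaced``.
    """
    std, rejects = standardize_quantities(consumption, units)
    agg = aggregate_household_item(std)
    cleaned = replace_outliers(agg, z_threshold=z_threshold)
    return daily_apparent_consumption(cleaned), rejects
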