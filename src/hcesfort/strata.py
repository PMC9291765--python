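"""Socioeconomic stratification and vehicle coverage tables.

Households are stratified by urban/rural residence and, within each
residence, into five quintiles of inflation-adjusted per-capita
expenditure (SEP).  Quintiles are computed separately for urban and
rural pools, so the same expenditure can land in different quintiles in
the two pools.  Ties are ranked with average ranks and cut at rank
fifths, so all households sharing an expenditure value share a quintile;
quintile sizes then differ by at most the tie-block size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nutrients import DataError


def sep_quintiles(households: pd.DataFrame) -> pd.DataFrame:
    """Assign within-residence expenditure quintiles (1 = lowest).

    ``households`` needs columns ``household_id, residence,
    expenditure_pc`` and optionally ``deflator`` (expenditure is divided
    by it when present).  Returns household_id, residence, sep_quintile.
    Quintile assignment is invariant to row order and to positive
    rescaling of all expenditures.
    """
    hh = households.copy()
    if (hh["expenditure_pc"] < 0).any():
        raise DataError("expenditures must be nonnegative")
    exp = hh["expenditure_pc"].astype(float)
    if "deflator" in hh.columns:
        exp = exp / hh["deflator"].astype(float)
    hh["_exp"] = exp

    quint = np.zeros(len(hh), dtype=np.int64)
    pos = pd.Series(np.arange(len(hh)), index=hh.index)
    for residence, grp in hh.groupby("residence"):
        n = len(grp)
        if n < 5:
            raise DataError(
                f"residence {residence!r} has {n} households; quintiles undefined"
            )
        ranks = grp["_exp"].rank(method="average")
        q = np.ceil(ranks * 5.0 / n).astype(np.int64).clip(1, 5)
        quint[pos.loc[grp.index].to_numpy()] = q
    out = hh[["household_id", "residence"]].copy()
    out["sep_quintile"] = quint
    return out


def consumer_per_afe(
    daily_kg: pd.DataFrame,
    household_afe: pd.Series,
    items: list[str],
) -> pd.Series:
    """g/day per AFE of an item group, per household (0 where none consumed)."""
    sub = daily_kg[daily_kg["item_code"].isin(items)]
    total = sub.groupby("household_id")["daily_edible_kg"].sum() * 1000.0
    total = total.reindex(household_afe.index, fill_value=0.0)
    return (total / household_afe).rename("g_day_afe")


def coverage_table(
    daily_kg: pd.DataFrame,
    household_afe: pd.Series,
    households: pd.DataFrame,
    vehicle_groups: dict[str, list[str]],
    strata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vehicle coverage and consumption summary by population stratum.

    For each stratum (national, by residence, and residence x SEP when
    ``strata`` is given) and each vehicle group: percentage of households
    consuming any quantity, and the median (IQR) of g/day per AFE among
    consumers; plus the share of households consuming none of the
    vehicles.  Scenario-invariant by construction — fortification touches
    composition only.
    """
    hh = households[["household_id", "residence"]].copy()
    if strata is not None:
        hh = hh.merge(strata[["household_id", "sep_quintile"]], on="household_id")

    per_afe = {
        v: consumer_per_afe(daily_kg, household_afe, items).reindex(hh["household_id"]).to_numpy()
        for v, items in vehicle_groups.items()
    }
    any_vehicle = np.zeros(len(hh), dtype=bool)
    for v in per_afe:
        any_vehicle |= per_afe[v] > 0

    def pools():
        yield "national", "", np.ones(len(hh), dtype=bool)
        for res, grp in hh.groupby("residence"):
            yield "residence", str(res), hh["residence"].to_numpy() == res
        if strata is not None:
            for (res, q), grp in hh.groupby(["residence", "sep_quintile"]):
                m = (hh["residence"].to_numpy() == res) & (hh["sep_quintile"].to_numpy() == q)
                yield "residence_sep", f"{res}_q{q}", m

    rows = []
    for level, stratum, m in pools():
        n = int(m.sum())
        for v, x in per_afe.items():
            consumers = x[m][x[m] > 0]
            rows.append(dict(
                level=level, stratum=stratum, vehicle=v, n_households=n,
                coverage_pct=100.0 * np.mean(x[m] > 0),
                median_g_day_afe=float(np.median(consumers)) if consumers.size else np.nan,
                iqr_low=float(np.percentile(consumers, 25)) if consumers.size else np.nan,
                iqr_high=float(np.percentile(consumers, 75)) if consumers.size else np.nan,
            ))
        rows.append(dict(
            level=level, stratum=stratum, vehicle="none_consumed", n_households=n,
            coverage_pct=100.0 * np.mean(~any_vehicle[m]),
            median_g_day_afe=np.nan, iqr_low=np.nan, iqr_high=np.nan,
        ))
    return pd.DataFrame(rows)
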