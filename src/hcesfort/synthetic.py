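"""Synthetic HCES-like data with known ground truth.

The generator emulates the *structure* of a national household
consumption and expenditure survey — a ~136-item food list recalled over
7 days, zero-inflated right-skewed quantities, urban/rural strata with
within-residence expenditure quintiles, socioeconomic gradients in
fortification-vehicle consumption, seasonal fluctuation of vitamin
A-rich produce, survey weights, and a 12-month field window — without
replicating any real survey's sampling frame.

Consumption follows a Bernoulli gate (coverage) with conditionally
log-normal quantities, which matches the median/IQR structure of
household food-acquisition data.  The default per-stratum vehicle
coverage and median-quantity matrices are the published national
gradients for oil, sugar, and wheat flour, so the default configuration
*is* the study condition, with every stratum-level value recorded as
ground truth for parameter-recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .afe import EnergyRequirementTable, household_afe
from .nutrients import ConfigurationError

RESIDENCES = ["rural", "urban"]
_PERIOD = 365.0


def _check_prop(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic survey population.

    The vehicle coverage/median matrices are proportions and g/day per
    AFE by residence and within-residence SEP quintile (index 0 =
    lowest).  ``seasonal_amplitude_scale`` multiplies every item's
    seasonal amplitude (0 switches seasonality off).  Survey weights are
    arbitrary positive numbers drawn around 1 with the configured
    dispersion; no sampling-frame calibration is implied.
    """

    n_households: int = 2000
    urban_fraction: float = 0.18
    seed: int = 0
    vehicle_coverage: dict = field(
        default_factory=lambda: {v: {r: list(q) for r, q in d.items()}
                                 for v, d in datasets.DEFAULT_VEHICLE_COVERAGE.items()})
    vehicle_median: dict = field(
        default_factory=lambda: {v: {r: list(q) for r, q in d.items()}
                                 for v, d in datasets.DEFAULT_VEHICLE_MEDIAN.items()})
    vehicle_log_sd: float = 0.45
    item_log_sd: float = 0.55
    seasonal_amplitude_scale: float = 1.0
    quantity_sep_gamma: float = 0.45
    nonstandard_unit_fraction: float = 0.30
    weight_dispersion: float = 0.30
    expenditure_log_mean: dict = field(
        default_factory=lambda: {"rural": 11.0, "urban": 12.0})
    expenditure_log_sd: dict = field(
        default_factory=lambda: {"rural": 0.7, "urban": 0.8})
    pregnancy_rate: float = 0.05
    lactation_rate: float = 0.10
    start_date: str = "2016-04-01"
    n_days: int = 365
    wheat_item_shares: dict = field(
        default_factory=lambda: dict(datasets.WHEAT_ITEM_SHARES))

    def validate(self) -> None:
        if self.n_households < 1:
            raise ConfigurationError("n_households must be >= 1")
        _check_prop("urban_fraction", self.urban_fraction)
        _check_prop("nonstandard_unit_fraction", self.nonstandard_unit_fraction)
        _check_prop("pregnancy_rate", self.pregnancy_rate)
        _check_prop("lactation_rate", self.lactation_rate)
        if self.vehicle_log_sd < 0 or self.item_log_sd < 0:
            raise ConfigurationError("log-sd parameters must be nonnegative")
        for v, byres in self.vehicle_coverage.items():
            for r, quintiles in byres.items():
                for p in quintiles:
                    _check_prop(f"coverage[{v}][{r}]", p)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters, derivable deterministically from config.

    ``coverage`` / ``median_g_day_afe``: vehicle -> residence -> list of 5
    per-quintile values; ``national_coverage``: expectation under the
    configured urban fraction; ``seasonal``: item -> (amplitude,
    peak_day).
    """

    coverage: dict
    median_g_day_afe: dict
    national_coverage: dict
    seasonal: dict
    urban_fraction: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def ground_truth_from_config(
    config: SyntheticConfig, food_list: pd.DataFrame
) -> GroundTruth:
    national = {}
    for v, byres in config.vehicle_coverage.items():
        national[v] = (
            (1 - config.urban_fraction) * float(np.mean(byres["rural"]))
            + config.urban_fraction * float(np.mean(byres["urban"]))
        )
    seasonal = {
        r.item_code: {
            "amplitude": float(r.seasonal_amplitude) * config.seasonal_amplitude_scale,
            "peak_day": None if np.isnan(r.seasonal_peak_day) else float(r.seasonal_peak_day),
        }
        for r in food_list.itertuples()
        if r.seasonal_amplitude * config.seasonal_amplitude_scale > 0
        and not np.isnan(r.seasonal_peak_day)
    }
    return GroundTruth(
        coverage={v: {r: list(map(float, q)) for r, q in d.items()}
                  for v, d in config.vehicle_coverage.items()},
        median_g_day_afe={v: {r: list(map(float, q)) for r, q in d.items()}
                          for v, d in config.vehicle_median.items()},
        national_coverage=national,
        seasonal=seasonal,
        urban_fraction=config.urban_fraction,
    )


def _season_factor(amp: float, peak_day: float, day: np.ndarray) -> np.ndarray:
    """Multiplicative annual cycle 1 + A sin(...), peaking at peak_day."""
    if amp == 0 or np.isnan(peak_day):
        return np.ones_like(day, dtype=float)
    phase = peak_day - _PERIOD / 4.0
    return 1.0 + amp * np.sin(2.0 * np.pi * (day - phase) / _PERIOD)


def generate_dataset(
    config: SyntheticConfig,
    food_list: pd.DataFrame | None = None,
    energy_table: EnergyRequirementTable | None = None,
):
    """Generate (households, roster, consumption, ground_truth).

    households: household_id, residence, region, sep_quintile,
    expenditure_pc, weight, survey_date, survey_day.
    roster: household_id, member_id, age, sex, physiological_status.
    consumption: household_id, item_code, quantity, unit_code (7-day
    recall, only consumed items listed, quantities in reported units).
    """
    config.validate()
    fl = datasets.default_food_list() if food_list is None else food_list
    etab = EnergyRequirementTable.default() if energy_table is None else energy_table
    units = datasets.default_units(fl)
    rng = np.random.default_rng(config.seed)
    n = config.n_households

    # --- households ---------------------------------------------------
    n_urban = int(round(n * config.urban_fraction))
    residence = np.array(["urban"] * n_urban + ["rural"] * (n - n_urban))
    hh_id = np.array([f"hh{i + 1:06d}" for i in range(n)])
    expenditure = np.empty(n)
    sepq = np.empty(n, dtype=int)
    pct = np.empty(n)  # within-residence expenditure percentile in [0,1)
    for res in RESIDENCES:
        m = residence == res
        k = int(m.sum())
        if k == 0:
            continue
        e = rng.lognormal(config.expenditure_log_mean[res],
                          config.expenditure_log_sd[res], size=k)
        expenditure[m] = e
        ranks = pd.Series(e).rank(method="average").to_numpy()
        pct[m] = (ranks - 0.5) / k
        sepq[m] = np.ceil(ranks * 5.0 / k).astype(int).clip(1, 5)
    wd = config.weight_dispersion
    if wd > 0:
        weight = rng.gamma(shape=1.0 / wd**2, scale=wd**2, size=n)
    else:
        weight = np.ones(n)
    survey_day = rng.integers(0, config.n_days, size=n)
    start = pd.Timestamp(config.start_date)
    households = pd.DataFrame({
        "household_id": hh_id,
        "residence": residence,
        "region": rng.choice(["north", "center", "south"], size=n, p=[0.2, 0.34, 0.46]),
        "sep_quintile": sepq,
        "expenditure_pc": expenditure,
        "weight": weight,
        "survey_day": survey_day,
        "survey_date": [(start + pd.Timedelta(days=int(d))).date().isoformat()
                        for d in survey_day],
    })

    # --- roster -------------------------------------------------------
    size = rng.integers(1, 9, size=n)
    rows_hh = np.repeat(np.arange(n), size)
    total = rows_hh.size
    first = np.zeros(total, dtype=bool)
    first[np.cumsum(size) - size] = True
    age = rng.integers(0, 81, size=total)
    age[first] = rng.integers(18, 60, size=int(first.sum()))
    sex = np.where(rng.random(total) < 0.5, "f", "m")
    sex[first] = "f"  # ensure an adult woman heads each household
    status = np.full(total, "none", dtype=object)
    wra = (sex == "f") & (age >= 18) & (age <= 49)
    u = rng.random(total)
    status[wra & (u < config.pregnancy_rate)] = "pregnant"
    status[wra & (u >= config.pregnancy_rate)
           & (u < config.pregnancy_rate + config.lactation_rate)] = "lactating"
    roster = pd.DataFrame({
        "household_id": hh_id[rows_hh],
        "member_id": np.concatenate([np.arange(1, s + 1) for s in size]),
        "age": age,
        "sex": sex,
        "physiological_status": status,
    })
    afe = household_afe(roster, etab).reindex(hh_id).to_numpy()

    # --- consumption --------------------------------------------------
    day = survey_day.astype(float)
    qty_scale = np.exp(config.quantity_sep_gamma * (pct - 0.5))
    rec_hh, rec_item, rec_weekly_kg = [], [], []

    def add_records(hmask: np.ndarray, item: str, g_day_afe: np.ndarray) -> None:
        idx = np.flatnonzero(hmask)
        rec_hh.append(idx)
        rec_item.append(np.full(idx.size, item, dtype=object))
        rec_weekly_kg.append(g_day_afe[idx] * afe[idx] * 7.0 / 1000.0)

    # Fortification vehicles: per-stratum Bernoulli coverage and
    # log-normal quantities around the stratum median.
    quintile_idx = sepq - 1
    for vehicle in ["oil", "sugar", "wheat_flour"]:
        cov = np.empty(n)
        med = np.empty(n)
        for res in RESIDENCES:
            m = residence == res
            cov[m] = np.asarray(config.vehicle_coverage[vehicle][res], dtype=float)[quintile_idx[m]]
            med[m] = np.asarray(config.vehicle_median[vehicle][res], dtype=float)[quintile_idx[m]]
        consumes = rng.random(n) < cov
        qty = med * np.exp(config.vehicle_log_sd * rng.standard_normal(n))
        if vehicle != "wheat_flour":
            add_records(consumes, vehicle, qty)
            continue
        # split the wheat group total across flour items
        shares = config.wheat_item_shares
        items = list(shares)
        pick = rng.random((n, len(items))) < np.array([shares[i] for i in items])
        none = ~pick.any(axis=1)
        pick[none, 0] = True  # force at least one item for gated households
        alloc = rng.random((n, len(items))) * pick
        alloc /= alloc.sum(axis=1, keepdims=True)
        for j, item in enumerate(items):
            add_records(consumes & pick[:, j], item, qty * alloc[:, j])

    # Ordinary food items: coverage with an SEP log-odds slope, optional
    # seasonality on both the gate and the quantity.
    wheat_set = set(datasets.WHEAT_GROUP) | {"oil", "sugar"}
    for r in fl.itertuples():
        if r.item_code in wheat_set or np.isnan(r.coverage):
            continue
        amp = float(r.seasonal_amplitude) * config.seasonal_amplitude_scale
        season = _season_factor(amp, float(r.seasonal_peak_day), day)
        logit = np.log(r.coverage / (1 - r.coverage)) if r.coverage < 1 else 20.0
        p = 1.0 / (1.0 + np.exp(-(logit + r.sep_slope * (pct - 0.5) * 2.0)))
        p = np.clip(p * season, 0.0, 1.0)
        consumes = rng.random(n) < p
        qty = (r.median_g_day_afe * qty_scale * season
               * np.exp(config.item_log_sd * rng.standard_normal(n)))
        add_records(consumes, r.item_code, qty)

    hh_idx = np.concatenate(rec_hh)
    consumption = pd.DataFrame({
        "household_id": hh_id[hh_idx],
        "item_code": np.concatenate(rec_item),
        "quantity": np.concatenate(rec_weekly_kg),
        "unit_code": "kilogram",
    })

    # Report a share of records in the item's nonstandard unit; reported
    # quantity is the as-purchased amount, so divide by kg-per-unit and
    # edible fraction (cleaning recovers the edible kilograms exactly).
    umap = units.set_index(["item_code", "unit_code"])
    edible_kg_per_kgunit = units[units["unit_code"] == "kilogram"].set_index("item_code")
    consumption["quantity"] = consumption["quantity"] / (
        edible_kg_per_kgunit.loc[consumption["item_code"], "edible_fraction"].to_numpy()
    )
    nonstd = units[units["unit_code"] != "kilogram"].set_index("item_code")
    has_alt = consumption["item_code"].isin(nonstd.index).to_numpy()
    use_alt = has_alt & (rng.random(len(consumption)) < config.nonstandard_unit_fraction)
    if use_alt.any():
        alt_items = consumption.loc[use_alt, "item_code"]
        alt_units = nonstd.loc[alt_items, "unit_code"].to_numpy()
        factors = nonstd.loc[alt_items, "kg_per_unit"].to_numpy()
        consumption.loc[use_alt, "quantity"] = (
            consumption.loc[use_alt, "quantity"].to_numpy() / factors
        )
        consumption.loc[use_alt, "unit_code"] = alt_units

    consumption = consumption.sort_values(
        ["household_id", "item_code", "unit_code"], kind="stable"
    ).reset_index(drop=True)

    truth = ground_truth_from_config(config, fl)
    return households, roster, consumption, truth


def inject_outliers(
    consumption: pd.DataFrame, rate: float, multiplier: float, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Multiply a random ``round(rate * n)`` of records by ``multiplier``.

    Returns the modified table and the integer index of modified rows,
    for testing outlier detection against known contamination.
    """
    _check_prop("rate", rate)
    if multiplier <= 1:
        raise ConfigurationError("multiplier must exceed 1")
    out = consumption.copy()
    n_mod = int(round(rate * len(out)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(out), size=n_mod, replace=False) if n_mod else np.array([], dtype=int)
    out.iloc[idx, out.columns.get_loc("quantity")] *= multiplier
    return out, np.sort(idx)


def write_fixture(
    outdir,
    config: SyntheticConfig,
    food_list: pd.DataFrame | None = None,
) -> dict:
    """Generate a dataset and write the full fixture directory.

    Writes households.csv, roster.csv, consumption.csv,
    ground_truth.json, config.json plus the food-system tables the
    pipeline needs (fct.csv, units.csv, recipes.csv, scenarios.csv,
    requirements CSVs).  Returns a manifest of row counts.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fl = datasets.default_food_list() if food_list is None else food_list
    households, roster, consumption, truth = generate_dataset(config, fl)
    households.to_csv(outdir / "households.csv", index=False)
    roster.to_csv(outdir / "roster.csv", index=False)
    consumption.to_csv(outdir / "consumption.csv", index=False)
    truth.to_json(outdir / "ground_truth.json")
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    datasets.default_fct(fl).to_csv(outdir / "fct.csv", index=False)
    datasets.default_units(fl).to_csv(outdir / "units.csv", index=False)
    datasets.load_recipe_table().to_csv(outdir / "recipes.csv", index=False)
    datasets.load_scenario_table().to_csv(outdir / "scenarios.csv", index=False)
    datasets.load_requirement_table().to_csv(outdir / "requirements_nutrients.csv", index=False)
    datasets.load_energy_requirement_table().to_csv(outdir / "requirements_energy.csv", index=False)
    datasets.load_energy_increments().to_csv(outdir / "energy_increments.csv", index=False)
    return {
        "n_households": len(households),
        "n_members": len(roster),
        "n_consumption_records": len(consumption),
    }
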