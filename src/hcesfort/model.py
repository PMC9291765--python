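"""Model/Results interface to the fortification adequacy pipeline.

:class:`FortificationAdequacyModel` bundles the survey tables and
parameter files; :meth:`~FortificationAdequacyModel.fit` runs the full
pipeline — unit standardization, outlier cleaning, AFE computation,
scenario composition, household supplies, adequacy classification, and
stratification — and returns a :class:`FortificationAdequacyResults`
carrying the estimates with ``summary()``, prevalence and percentile
accessors, seasonality curves, and a ``save()`` that writes the output
bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import adequacy as adequacy_mod
from . import composition as composition_mod
from . import consumption as consumption_mod
from . import datasets, strata
from .adequacy import RequirementSet, critical_nutrient_density
from .afe import EnergyRequirementTable, household_afe
from .nutrients import ENERGY, NUTRIENTS, SCENARIOS, ConfigurationError, DataError
from .seasonality import seasonality_report

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A configuration or data failure attributed to a named stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (ConfigurationError, DataError, FileNotFoundError, KeyError) as exc:
        raise PipelineError(name, str(exc)) from exc


class FortificationAdequacyModel:
    """Fortification-scenario adequacy model for one HCES-style survey.

    Parameters
    ----------
    households
        household_id, residence, expenditure_pc, weight, survey_date
        (ISO) or survey_day, optionally region and deflator.
    roster
        household_id, member_id, age, sex, physiological_status.
    consumption
        7-day recall records: household_id, item_code, quantity, unit_code.
    fct, units, scenario_table, recipes, requirement_table, energy_table
        Parameter tables; packaged defaults are used where omitted.
    scenarios
        Scenario names to evaluate (default: the packaged three).
    z_threshold
        Robust-z cutoff for consumption outlier replacement.
    zinc_tier
        Zinc bioavailability tier for the H-AR ('low' for diets high in
        unrefined grains).
    """

    def __init__(
        self,
        households: pd.DataFrame,
        roster: pd.DataFrame,
        consumption: pd.DataFrame,
        *,
        fct: pd.DataFrame | None = None,
        units: pd.DataFrame | None = None,
        scenario_table: pd.DataFrame | None = None,
        recipes: pd.DataFrame | None = None,
        requirement_table: pd.DataFrame | None = None,
        energy_table: EnergyRequirementTable | None = None,
        scenarios: list[str] | None = None,
        z_threshold: float = 3.0,
        zinc_tier: str = "low",
        loess_span: float = 0.75,
        loess_degree: int = 2,
    ):
        self.households = households.copy()
        self.roster = roster
        self.consumption = consumption
        self.fct = datasets.default_fct() if fct is None else fct
        self.units = datasets.default_units() if units is None else units
        self.scenario_table = (
            datasets.load_scenario_table() if scenario_table is None else scenario_table
        )
        self.recipes = datasets.load_recipe_table() if recipes is None else recipes
        self.requirement_table = (
            datasets.load_requirement_table() if requirement_table is None else requirement_table
        )
        self.energy_table = (
            EnergyRequirementTable.default() if energy_table is None else energy_table
        )
        self.scenarios = list(SCENARIOS) if scenarios is None else list(scenarios)
        self.z_threshold = z_threshold
        self.zinc_tier = zinc_tier
        self.loess_span = loess_span
        self.loess_degree = loess_degree

        if "survey_day" not in self.households.columns:
            if "survey_date" in self.households.columns:
                dates = pd.to_datetime(self.households["survey_date"])
                self.households["survey_day"] = (dates - dates.min()).dt.days
            else:
                self.households["survey_day"] = np.nan

    @classmethod
    def from_fixture_dir(cls, path, **kwargs) -> "FortificationAdequacyModel":
        """Build the model from a directory of CSV tables (synth output)."""
        path = Path(path)

        def read(name, stage):
            f = path / name
            if not f.exists():
                raise PipelineError(stage, f"required input file missing: {f}")
            return pd.read_csv(f)

        energy = _stage(
            "afe_model",
            lambda: EnergyRequirementTable(
                bands=read("requirements_energy.csv", "afe_model"),
                increments=dict(zip(*(lambda d: (d["status"], d["kcal_increment"]))(
                    read("energy_increments.csv", "afe_model")))),
            ),
        )
        return cls(
            households=read("households.csv", "input"),
            roster=read("roster.csv", "input"),
            consumption=read("consumption.csv", "input"),
            fct=read("fct.csv", "fortification_composition"),
            units=read("units.csv", "consumption_processing"),
            scenario_table=read("scenarios.csv", "fortification_composition"),
            recipes=read("recipes.csv", "fortification_composition"),
            requirement_table=read("requirements_nutrients.csv", "adequacy"),
            energy_table=energy,
            **kwargs,
        )

    @classmethod
    def from_synthetic(cls, config=None, **kwargs) -> "FortificationAdequacyModel":
        """Generate a synthetic survey and build the model on it."""
        from .synthetic import SyntheticConfig, generate_dataset

        config = SyntheticConfig() if config is None else config
        households, roster, consumption, truth = generate_dataset(config)
        model = cls(households, roster, consumption, **kwargs)
        model.ground_truth = truth
        return model

    # ------------------------------------------------------------------
    def fit(self) -> "FortificationAdequacyResults":
        """Run the pipeline for every scenario and return results."""
        cleaned, rejects = _stage(
            "consumption_processing",
            consumption_mod.clean_consumption,
            self.consumption, self.units, self.z_threshold,
        )
        afe = _stage("afe_model", household_afe, self.roster, self.energy_table)
        missing_afe = set(cleaned["household_id"]) - set(afe.index)
        if missing_afe:
            raise PipelineError(
                "afe_model", f"households with consumption but no roster: {sorted(missing_afe)[:5]}"
            )
        req = _stage(
            "adequacy",
            RequirementSet.from_table,
            self.requirement_table, self.energy_table.reference_energy, self.zinc_tier,
        )
        strata_df = _stage("strata_seasonality", strata.sep_quintiles, self.households)

        supplies = {}
        adequacy_frames = []
        for scenario in self.scenarios:
            comp = _stage(
                "fortification_composition",
                composition_mod.scenario_composition,
                self.fct, self.scenario_table, self.recipes, scenario,
            )
            supply = _stage(
                "fortification_composition",
                composition_mod.household_supply, cleaned, comp,
            )
            supplies[scenario] = supply
            adequacy_frames.append(
                _stage("adequacy", adequacy_mod.compute_adequacy,
                       supply, afe, req, scenario)
            )

        vehicle_groups = {
            "oil": ["oil"], "sugar": ["sugar"], "wheat_flour": list(datasets.WHEAT_GROUP),
        }
        coverage = _stage(
            "strata_seasonality",
            strata.coverage_table,
            cleaned, afe, self.households, vehicle_groups, strata_df,
        )

        return FortificationAdequacyResults(
            model=self,
            cleaned=cleaned,
            rejects=rejects,
            afe=afe,
            requirements=req,
            strata=strata_df,
            supplies=supplies,
            adequacy=pd.concat(adequacy_frames, ignore_index=True),
            coverage=coverage,
        )


class FortificationAdequacyResults:
    """Fitted pipeline outputs with survey-weighted accessors."""

    def __init__(self, model, cleaned, rejects, afe, requirements, strata,
                 supplies, adequacy, coverage):
        self.model = model
        self.cleaned = cleaned
        self.rejects = rejects
        self.afe = afe
        self.requirements = requirements
        self.strata = strata
        self.supplies = supplies
        self.adequacy = adequacy
        self.coverage = coverage

    # ------------------------------------------------------------------
    def _household_meta(self) -> pd.DataFrame:
        hh = self.model.households[
            ["household_id", "residence", "weight", "survey_day"]
        ].merge(self.strata[["household_id", "sep_quintile"]], on="household_id")
        return hh.merge(self.afe.rename("afe"), left_on="household_id", right_index=True)

    def prevalence(
        self,
        metric: str = "density",
        by: str = "national",
        denominator: str = "households",
    ) -> pd.DataFrame:
        """Weighted prevalence of inadequacy (or UL exceedance).

        metric: 'density', 'intake', or 'ul'; by: 'national', 'residence',
        or 'residence_sep'; denominator: 'households' (survey weights) or
        'afe' (weights times household AFE, person-denominated).
        """
        flag_col = {"density": "density_inadequate",
                    "intake": "intake_inadequate",
                    "ul": "ul_exceeded"}[metric]
        df = self.adequacy.merge(self._household_meta(), on="household_id")
        w = df["weight"].to_numpy(dtype=float)
        if denominator == "afe":
            w = w * df["afe"].to_numpy(dtype=float)
        elif denominator != "households":
            raise ValueError("denominator must be 'households' or 'afe'")

        group_cols = {"national": [], "residence": ["residence"],
                      "residence_sep": ["residence", "sep_quintile"]}[by]
        rows = []
        for keys, grp in df.groupby(["scenario", "nutrient"] + group_cols, sort=False):
            keys = keys if isinstance(keys, tuple) else (keys,)
            prev, n = adequacy_mod.weighted_prevalence(
                grp[flag_col], w[grp.index.to_numpy()]
            )
            row = dict(zip(["scenario", "nutrient"] + group_cols, keys))
            row["prevalence_pct"] = 100.0 * prev
            row["n"] = n
            rows.append(row)
        return pd.DataFrame(rows)

    def percentile_curve(
        self, nutrient: str, metric: str = "density_per_1000kcal",
        scenario: str | None = None, weighted: bool = True,
    ) -> pd.DataFrame:
        """Population percentile curve(s) of density or apparent intake."""
        df = self.adequacy[self.adequacy["nutrient"] == nutrient]
        if scenario is not None:
            df = df[df["scenario"] == scenario]
        meta = self._household_meta().set_index("household_id")
        out = []
        for scen, grp in df.groupby("scenario", sort=False):
            w = meta.loc[grp["household_id"], "weight"].to_numpy() if weighted else None
            curve = adequacy_mod.percentile_curve(grp[metric], weights=w)
            curve.insert(0, "scenario", scen)
            out.append(curve)
        return pd.concat(out, ignore_index=True)

    def thresholds(self) -> dict[str, dict[str, float]]:
        """Reference lines: CND per 1000 kcal (density) and H-AR (intake)."""
        req = self.requirements
        dens = {}
        for n in NUTRIENTS:
            if req.classifiable(n) and n in req.har:
                dens[n] = critical_nutrient_density(req, n)
        return {"density_per_1000kcal": dens, "intake_per_afe": dict(req.har)}

    def seasonality(self, nutrients=None, **kwargs) -> pd.DataFrame:
        """Loess seasonality curves with CND/H-AR reference lines."""
        return seasonality_report(
            self.adequacy, self.model.households, self.strata,
            thresholds=self.thresholds(), nutrients=nutrients,
            span=self.model.loess_span, degree=self.model.loess_degree, **kwargs,
        )

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary of coverage and inadequacy by scenario."""
        lines = ["Fortification adequacy model results",
                 "=" * 52,
                 f"households: {self.model.households.shape[0]:>7}"
                 f"   consumption records: {len(self.model.consumption)}",
                 f"rejected records: {len(self.rejects)}"
                 f"   outliers replaced: {int(self.cleaned['outlier_replaced'].sum())}",
                 "",
                 "Vehicle coverage (national):"]
        nat = self.coverage[self.coverage["level"] == "national"]
        for _, r in nat.iterrows():
            med = ("" if np.isnan(r.median_g_day_afe)
                   else f"  median {r.median_g_day_afe:5.1f} g/day/AFE"
                        f" (IQR {r.iqr_low:.1f}, {r.iqr_high:.1f})")
            lines.append(f"  {r.vehicle:<14} {r.coverage_pct:5.1f}%{med}")
        lines += ["", "Inadequacy prevalence, % of households"
                      " (density | apparent intake):"]
        dens = self.prevalence("density").pivot(index="nutrient", columns="scenario",
                                                values="prevalence_pct")
        intk = self.prevalence("intake").pivot(index="nutrient", columns="scenario",
                                               values="prevalence_pct")
        scen = [s for s in self.model.scenarios]
        lines.append(f"  {'nutrient':<14}" + "".join(f"{s:>22}" for s in scen))
        for n in NUTRIENTS:
            if n not in intk.index:
                continue
            cells = []
            for s in scen:
                d = dens.loc[n, s] if n in dens.index and pd.notna(dens.loc[n, s]) else np.nan
                i = intk.loc[n, s]
                dtxt = " n/a" if np.isnan(d) else f"{d:4.1f}"
                cells.append(f"{dtxt:>10} |{i:5.1f}    ")
            lines.append(f"  {n:<14}" + "".join(cells))
        return "\n".join(lines)

    def save(self, outdir, seed: int | None = None) -> dict:
        """Write the output bundle and manifest; returns the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.adequacy.to_csv(outdir / "adequacy.csv", index=False)
        self.coverage.to_csv(outdir / "coverage_table.csv", index=False)
        prev = pd.concat(
            [self.prevalence("density", by="residence_sep"),
             self.prevalence("intake", by="residence_sep")],
            keys=["density", "intake"], names=["metric", None],
        ).reset_index(level=0)
        prev.to_csv(outdir / "prevalence_table.csv", index=False)
        curves = self.seasonality()
        curves.to_csv(outdir / "curves.csv", index=False)
        self.rejects.to_csv(outdir / "rejects.csv", index=False)

        config_repr = json.dumps({
            "scenarios": self.model.scenarios,
            "z_threshold": self.model.z_threshold,
            "zinc_tier": self.model.zinc_tier,
            "loess_span": self.model.loess_span,
            "loess_degree": self.model.loess_degree,
        }, sort_keys=True)
        manifest = {
            "config_hash": hashlib.sha256(config_repr.encode()).hexdigest(),
            "seed": seed,
            "n_households": int(self.model.households.shape[0]),
            "n_consumption_records": int(len(self.model.consumption)),
            "n_rejects": int(len(self.rejects)),
            "n_outliers_replaced": int(self.cleaned["outlier_replaced"].sum()),
            "n_adequacy_rows": int(len(self.adequacy)),
            "scenarios": self.model.scenarios,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
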