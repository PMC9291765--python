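"""Dietary adequacy metrics.

Two cut-point metrics are computed per household, nutrient, and scenario:

* **density**: nutrient supply per 1000 kcal of the household diet,
  compared against the critical nutrient density (CND), the adult
  female's harmonized average requirement (H-AR) divided by her energy
  requirement and expressed per 1000 kcal;
* **apparent intake**: nutrient supply divided by household AFE, compared
  against the H-AR directly.

A household strictly below a threshold is classified inadequate; a value
exactly at the threshold is adequate.  Iron is exempt from both cut-point
classifications because its requirement distribution is strongly skewed,
so the half-of-the-population logic behind the cut-point does not hold;
iron densities and intakes are still reported.  Vitamin A additionally
gets an upper-limit (H-UL) exceedance flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .nutrients import ENERGY, NUTRIENTS, ConfigurationError


class NotClassifiable(Exception):
    """Signals a nutrient whose density cut-point is undefined (iron)."""


@dataclass(frozen=True)
class RequirementSet:
    """H-AR / H-UL thresholds for the reference adult female.

    ``har`` and ``hul`` are nutrient -> units/day; ``density_classifiable``
    marks nutrients for which the CND cut-point is defined;
    ``reference_energy`` is the reference woman's kcal/day.
    """

    har: dict[str, float]
    reference_energy: float
    hul: dict[str, float] = field(default_factory=dict)
    density_classifiable: dict[str, bool] = field(default_factory=dict)
    zinc_tier: str = "low"

    def __post_init__(self) -> None:
        if self.reference_energy <= 0:
            raise ConfigurationError("reference energy must be positive")
        bad = [n for n, v in self.har.items() if v <= 0]
        if bad:
            raise ConfigurationError(f"nonpositive H-AR for: {bad}")

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, reference_energy: float, zinc_tier: str = "low"
    ) -> "RequirementSet":
        t = table.copy()
        tier = t["bioavailability_tier"].fillna("")
        t = t[(tier == "") | (tier == zinc_tier)]
        if t["nutrient"].duplicated().any():
            raise ConfigurationError("duplicate nutrient rows after tier selection")
        har = dict(zip(t["nutrient"], t["har_units_per_day"].astype(float)))
        hul = {
            n: float(v)
            for n, v in zip(t["nutrient"], t["hul_units_per_day"])
            if pd.notna(v)
        }
        dc = dict(zip(t["nutrient"], t["density_classifiable"].astype(bool)))
        return cls(har=har, reference_energy=reference_energy, hul=hul,
                   density_classifiable=dc, zinc_tier=zinc_tier)

    @classmethod
    def default(cls, reference_energy: float = 2100.0, zinc_tier: str = "low"):
        return cls.from_table(
            datasets.load_requirement_table(), reference_energy, zinc_tier
        )

    def classifiable(self, nutrient: str) -> bool:
        return bool(self.density_classifiable.get(nutrient, True))


def critical_nutrient_density(req: RequirementSet, nutrient: str) -> float:
    """CND threshold: H-AR / reference energy, per 1000 kcal.

    Raises :class:`NotClassifiable` for nutrients (iron) whose density
    cut-point is undefined — callers must not receive a number there.
    """
    if not req.classifiable(nutrient):
        raise NotClassifiable(nutrient)
    return req.har[nutrient] / req.reference_energy * 1000.0


def compute_adequacy(
    supply: pd.DataFrame,
    household_afe: pd.Series,
    req: RequirementSet,
    scenario: str,
    nutrients: list[str] | None = None,
) -> pd.DataFrame:
    """Long adequacy table for one scenario's household supplies.

    One row per household x nutrient with density (per 1000 kcal),
    apparent intake per AFE per day, and the three flags.  Households with
    zero energy supply cannot have a defined density and are excluded
    (their ids are recoverable by comparing row counts).
    ``density_inadequate`` is a nullable boolean: ``pd.NA`` marks
    not-classifiable nutrients (iron).
    """
    nutrients = list(NUTRIENTS if nutrients is None else nutrients)
    s = supply.merge(household_afe.rename("afe"), left_on="household_id", right_index=True)
    if (s["afe"] <= 0).any():
        raise ConfigurationError("household AFE must be positive")
    s = s[s[ENERGY] > 0]

    frames = []
    for n in nutrients:
        density = s[n] / s[ENERGY] * 1000.0
        intake = s[n] / s["afe"]
        if req.classifiable(n):
            cnd = critical_nutrient_density(req, n)
            dens_flag = pd.array(density < cnd, dtype="boolean")
        else:
            dens_flag = pd.array([pd.NA] * len(s), dtype="boolean")
        intake_flag = intake < req.har[n]
        if n in req.hul:
            ul_flag = pd.array(intake > req.hul[n], dtype="boolean")
        else:
            ul_flag = pd.array([pd.NA] * len(s), dtype="boolean")
        frames.append(pd.DataFrame({
            "household_id": s["household_id"].to_numpy(),
            "scenario": scenario,
            "nutrient": n,
            "density_per_1000kcal": density.to_numpy(),
            "intake_per_afe": intake.to_numpy(),
            "density_inadequate": dens_flag,
            "intake_inadequate": pd.array(intake_flag, dtype="boolean"),
            "ul_exceeded": ul_flag,
        }))
    return pd.concat(frames, ignore_index=True)


def weighted_prevalence(
    flags, weights, mask=None
) -> tuple[float, int]:
    """Survey-weighted prevalence of a boolean flag.

    Returns ``(sum(w * flag) / sum(w), n)`` over the (optionally masked)
    rows; ``(nan, 0)`` for an empty stratum — absence, not zero.  Rows with
    missing flags (iron density) are excluded.
    """
    f = pd.array(flags, dtype="boolean")
    w = np.asarray(weights, dtype=float)
    keep = ~f.isna()
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    keep = np.asarray(keep, dtype=bool)
    if (w[keep] <= 0).any():
        raise ConfigurationError("weights must be positive")
    n = int(keep.sum())
    if n == 0:
        return float("nan"), 0
    fv = f.to_numpy(dtype=float, na_value=np.nan)[keep]
    return float(np.sum(w[keep] * fv) / np.sum(w[keep])), n


def percentile_curve(
    values, percentiles=None, weights=None
) -> pd.DataFrame:
    """Population percentile curve of a household-level quantity.

    Unweighted by default (``numpy`` linear interpolation, so p50 is the
    median); with survey weights, the weighted quantile interpolates the
    normalized cumulative weight.  Returns columns ``percentile, value``
    with value monotone nondecreasing in percentile.
    """
    p = np.arange(1, 100) if percentiles is None else np.asarray(percentiles, dtype=float)
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    if weights is None:
        out = np.percentile(v, p)
    else:
        w = np.asarray(weights, dtype=float)
        order = np.argsort(v, kind="stable")
        v_s, w_s = v[order], w[order]
        cw = np.cumsum(w_s) - 0.5 * w_s
        cw /= np.sum(w_s)
        out = np.interp(p / 100.0, cw, v_s)
    return pd.DataFrame({"percentile": p, "value": out})
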