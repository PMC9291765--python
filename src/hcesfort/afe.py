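"""Adult female equivalents (AFE).

Household food supplies are individualized by assuming food is shared in
proportion to each member's energy requirement.  Expressing supplies per
AFE — each member's requirement divided by that of a nonpregnant,
nonlactating 18-29-year-old woman — makes households of different
composition comparable, and makes the adult woman the natural reference
for adequacy thresholds.  The same machinery yields per-AME figures by
flagging a different reference row in the requirement table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .nutrients import ConfigurationError, DataError


@dataclass(frozen=True)
class EnergyRequirementTable:
    """Energy requirements (kcal/day) by sex and age band, plus increments.

    ``bands`` columns: sex, age_min, age_max, status, kcal_per_day,
    reference (0/1).  ``increments`` maps physiological status
    (``pregnant``, ``lactating``) to an additive kcal/day increment.
    """

    bands: pd.DataFrame
    increments: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = self.bands
        if (b["kcal_per_day"] <= 0).any():
            raise ConfigurationError("energy requirements must be positive")
        ref = b[b["reference"] == 1]
        if len(ref) != 1:
            raise ConfigurationError(
                f"exactly one reference row required, found {len(ref)}"
            )

    @property
    def reference_energy(self) -> float:
        """kcal/day of the reference member (adult female by default)."""
        return float(self.bands.loc[self.bands["reference"] == 1, "kcal_per_day"].iloc[0])

    @classmethod
    def default(cls) -> "EnergyRequirementTable":
        inc = datasets.load_energy_increments()
        return cls(
            bands=datasets.load_energy_requirement_table(),
            increments=dict(zip(inc["status"], inc["kcal_increment"].astype(float))),
        )


def member_energy_requirements(
    roster: pd.DataFrame, table: EnergyRequirementTable
) -> pd.Series:
    """kcal/day per roster row (age, sex, physiological status).

    Raises :class:`ConfigurationError` naming the first uncovered member if
    any (sex, age) falls outside the band table.
    """
    req = np.full(len(roster), np.nan)
    age = roster["age"].to_numpy(dtype=float)
    sex = roster["sex"].to_numpy()
    for _, band in table.bands.iterrows():
        m = (sex == band["sex"]) & (age >= band["age_min"]) & (age <= band["age_max"])
        req[m] = band["kcal_per_day"]
    if np.isnan(req).any():
        i = int(np.flatnonzero(np.isnan(req))[0])
        raise ConfigurationError(
            "no energy-requirement band covers member "
            f"(household={roster.iloc[i]['household_id']!r}, "
            f"sex={sex[i]!r}, age={age[i]})"
        )
    if "physiological_status" in roster:
        status = roster["physiological_status"].fillna("none").to_numpy()
        for name, inc in table.increments.items():
            req[status == name] += inc
    return pd.Series(req, index=roster.index, name="kcal_per_day")


def afe_factors(roster: pd.DataFrame, table: EnergyRequirementTable) -> pd.Series:
    """Dimensionless AFE factor per member (requirement / reference)."""
    return (member_energy_requirements(roster, table) / table.reference_energy).rename("afe")


def household_afe(roster: pd.DataFrame, table: EnergyRequirementTable) -> pd.Series:
    """Total AFE per household (sum of member factors; order-invariant)."""
    if len(roster) == 0:
        raise DataError("empty roster: household AFE undefined")
    f = afe_factors(roster, table)
    out = f.groupby(roster["household_id"]).sum()
    out.name = "afe"
    return out
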