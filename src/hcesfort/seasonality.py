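"""Loess seasonality curves.

Micronutrient density and apparent intake fluctuate over the survey year
as vitamin A-rich produce comes in and out of season.  The smoother is
classical loess: at each grid day a quadratic polynomial is fitted by
weighted least squares over the ceil(span * n) nearest observations, with
tricube distance weights optionally multiplied by survey weights.  The
default span is 0.75 with quadratic (degree 2) local fits.  Pointwise
95% bands come from the local fit's sandwich standard error with a
t-distribution reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nutrients import DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoessCurve:
    """Fitted seasonality curve on a day grid with pointwise 95% bands."""

    grid: np.ndarray
    fit: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    span: float
    degree: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.grid, "fit": self.fit,
            "lower95": self.lower95, "upper95": self.upper95,
        })


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_fit(
    day,
    value,
    weight=None,
    span: float = 0.75,
    degree: int = 2,
    grid=None,
    conf_level: float = 0.95,
) -> LoessCurve:
    """Weighted least-squares local polynomial regression.

    Parameters
    ----------
    day, value
        Observation abscissae (study day) and responses.
    weight
        Optional observation weights (survey weights), multiplied into
        the tricube distance weights.
    span
        Fraction of observations in each local window, in (0, 1].
    degree
        Local polynomial degree (2 = quadratic, the default).
    grid
        Evaluation days; defaults to 101 equispaced points over the
        observed range.
    """
    x = np.asarray(day, dtype=float)
    y = np.asarray(value, dtype=float)
    n = x.size
    p = degree + 1
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if n < degree + 2:
        raise DataError(f"need at least {degree + 2} points, got {n}")
    w_obs = np.ones(n) if weight is None else np.asarray(weight, dtype=float)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 101)
    grid = np.asarray(grid, dtype=float)

    k = max(math.ceil(span * n), degree + 2)
    k = min(k, n)

    fit = np.empty(grid.size)
    se = np.empty(grid.size)
    tval = stats.t.ppf(0.5 + conf_level / 2.0, df=max(k - p, 1))
    for j, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            # all k nearest points coincide with x0; widen to the nearest
            # distinct distance so the local fit is identifiable
            distinct = np.unique(d)
            if distinct.size > 1:
                h = distinct[1]
                logger.warning("degenerate loess window at day %g widened", x0)
            else:
                fit[j] = np.average(y, weights=w_obs)
                se[j] = 0.0
                continue
        w = _tricube(d / h) * w_obs
        use = w > 0
        m = int(use.sum())
        xc = x[use] - x0
        X = np.vander(xc, p, increasing=True)
        sw = np.sqrt(w[use])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[use] * sw, rcond=None)
        fit[j] = beta[0]
        resid = y[use] - X @ beta
        dof = max(m - p, 1)
        sigma2 = np.sum(w[use] * resid**2) / (np.sum(w[use]) * dof / m)
        XtWX = X.T @ (w[use, None] * X)
        XtW2X = X.T @ ((w[use] ** 2)[:, None] * X)
        Xinv = np.linalg.pinv(XtWX)
        var0 = sigma2 * (Xinv @ XtW2X @ Xinv)[0, 0] / np.sum(w[use])
        se[j] = math.sqrt(max(var0, 0.0))

    return LoessCurve(
        grid=grid, fit=fit, lower95=fit - tval * se, upper95=fit + tval * se,
        span=span, degree=degree,
    )


def peak_day(curve: LoessCurve, period: float = 365.0) -> float:
    """Grid day at which the fitted curve attains its maximum."""
    return float(curve.grid[int(np.argmax(curve.fit))] % period)


def seasonality_report(
    adequacy: pd.DataFrame,
    households: pd.DataFrame,
    strata: pd.DataFrame,
    thresholds: dict[str, dict[str, float]],
    nutrients=None,
    metrics=("density_per_1000kcal", "intake_per_afe"),
    span: float = 0.75,
    degree: int = 2,
    min_observations: int = 10,
    use_weights: bool = True,
    n_grid: int = 61,
) -> pd.DataFrame:
    """Loess curves per nutrient x metric x scenario x stratum.

    ``adequacy`` is the long table from :func:`~hcesfort.adequacy.compute_adequacy`
    (all scenarios concatenated); ``households`` carries ``survey_day`` and
    ``weight``; ``strata`` the residence x SEP assignment.  ``thresholds``
    maps metric name -> nutrient -> reference line (CND or H-AR); the line
    is attached to every curve row.  Strata with fewer than
    ``min_observations`` dated observations are omitted with a log message.
    Returns a long frame: nutrient, metric, scenario, residence,
    sep_quintile, day, fit, lower95, upper95, threshold.
    """
    hh = households[["household_id", "survey_day", "weight"]].merge(
        strata[["household_id", "residence", "sep_quintile"]], on="household_id"
    )
    df = adequacy.merge(hh, on="household_id")
    if nutrients is not None:
        df = df[df["nutrient"].isin(nutrients)]

    out = []
    group_cols = ["nutrient", "scenario", "residence", "sep_quintile"]
    for keys, grp in df.groupby(group_cols):
        nutrient, scenario, residence, sepq = keys
        if len(grp) < min_observations:
            logger.info("stratum %s omitted: %d dated observations", keys, len(grp))
            continue
        for metric in metrics:
            vals = grp[metric].to_numpy(dtype=float)
            days = grp["survey_day"].to_numpy(dtype=float)
            w = grp["weight"].to_numpy(dtype=float) if use_weights else None
            curve = loess_fit(days, vals, weight=w, span=span, degree=degree,
                              grid=np.linspace(days.min(), days.max(), n_grid))
            frame = curve.to_frame()
            frame["nutrient"] = nutrient
            frame["metric"] = metric
            frame["scenario"] = scenario
            frame["residence"] = residence
            frame["sep_quintile"] = sepq
            frame["threshold"] = thresholds.get(metric, {}).get(nutrient, np.nan)
            out.append(frame)
    if not out:
        return pd.DataFrame(columns=["day", "fit", "lower95", "upper95"] + group_cols)
    return pd.concat(out, ignore_index=True)
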