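"""Density/intake inadequacy metrics, prevalence, and percentile curves."""

import numpy as np
import pandas as pd
import pytest

from hcesfort.adequacy import (
    NotClassifiable,
    RequirementSet,
    compute_adequacy,
    critical_nutrient_density,
    percentile_curve,
    weighted_prevalence,
)
from hcesfort.nutrients import ENERGY, ConfigurationError


@pytest.fixture()
def req():
    return RequirementSet(
        har={"vita_rae_ug": 490.0, "iron_mg": 22.4, "zinc_mg": 10.2},
        reference_energy=2100.0,
        hul={"vita_rae_ug": 3000.0},
        density_classifiable={"vita_rae_ug": True, "iron_mg": False, "zinc_mg": True},
    )


def _supply(rows, nutrients=("vita_rae_ug", "iron_mg", "zinc_mg")):
    df = pd.DataFrame(rows, columns=["household_id", ENERGY, *nutrients])
    return df


def test_cnd_arithmetic(req):
    r = RequirementSet(har={"x": 420.0}, reference_energy=2100.0)
    assert critical_nutrient_density(r, "x") == pytest.approx(200.0)
    r2 = RequirementSet(har={"x": 840.0}, reference_energy=2100.0)
    assert critical_nutrient_density(r2, "x") == pytest.approx(400.0)  # linear in H-AR


def test_iron_density_is_not_classifiable(req):
    with pytest.raises(NotClassifiable):
        critical_nutrient_density(req, "iron_mg")
    supply = _supply([("h1", 2000.0, 100.0, 5.0, 3.0)])
    afe = pd.Series([1.0], index=["h1"], name="afe")
    out = compute_adequacy(supply, afe, req, "no_fortification",
                           nutrients=["vita_rae_ug", "iron_mg", "zinc_mg"])
    iron = out[out["nutrient"] == "iron_mg"]
    assert iron["density_inadequate"].isna().all()
    assert not iron["intake_inadequate"].isna().any()  # intake cut-point still applies


def test_density_values_and_boundary_convention(req):
    # 400 ug over 2000 kcal -> 200 per 1000 kcal; CND = 490/2100*1000 = 233.33
    supply = _supply([("h1", 2000.0, 400.0, 0.0, 0.0)])
    afe = pd.Series([1.0], index=["h1"])
    out = compute_adequacy(supply, afe, req, "s", nutrients=["vita_rae_ug"])
    assert out["density_per_1000kcal"].iloc[0] == pytest.approx(200.0)
    assert bool(out["density_inadequate"].iloc[0])

    # exactly at the threshold: adequate (strict less-than)
    cnd = critical_nutrient_density(req, "vita_rae_ug")
    at = _supply([("h1", 1000.0, cnd, 0.0, 0.0)])
    out2 = compute_adequacy(at, afe, req, "s", nutrients=["vita_rae_ug"])
    assert not bool(out2["density_inadequate"].iloc[0])


def test_density_scale_invariance_and_dilution(req):
    afe = pd.Series([1.0, 1.0], index=["h1", "h2"])
    base = _supply([("h1", 2000.0, 400.0, 0.0, 0.0), ("h2", 4000.0, 800.0, 0.0, 0.0)])
    out = compute_adequacy(base, afe, req, "s", nutrients=["vita_rae_ug"])
    d1, d2 = out["density_per_1000kcal"]
    assert d1 == pytest.approx(d2)  # doubling all quantities leaves density unchanged
    # adding pure-energy food strictly decreases density
    diluted = _supply([("h1", 2500.0, 400.0, 0.0, 0.0)])
    out3 = compute_adequacy(diluted, afe.loc[["h1"]], req, "s", nutrients=["vita_rae_ug"])
    assert out3["density_per_1000kcal"].iloc[0] < d1


def test_reference_woman_intake_flag_and_ul(req):
    afe = pd.Series([1.0], index=["h1"])
    just_below = _supply([("h1", 2100.0, 489.9, 0.0, 0.0)])
    out = compute_adequacy(just_below, afe, req, "s", nutrients=["vita_rae_ug"])
    assert bool(out["intake_inadequate"].iloc[0])
    high = _supply([("h1", 2100.0, 3500.0, 0.0, 0.0)])
    out2 = compute_adequacy(high, afe, req, "s", nutrients=["vita_rae_ug"])
    assert bool(out2["ul_exceeded"].iloc[0])


def test_density_and_intake_flags_coincide_at_reference_energy(req):
    """A one-reference-woman household eating exactly the reference energy
    has density < CND iff intake < H-AR."""
    afe = pd.Series([1.0] * 3, index=["h1", "h2", "h3"])
    supply = _supply([
        ("h1", 2100.0, 489.0, 0.0, 0.0),
        ("h2", 2100.0, 490.0, 0.0, 0.0),
        ("h3", 2100.0, 600.0, 0.0, 0.0),
    ])
    out = compute_adequacy(supply, afe, req, "s", nutrients=["vita_rae_ug"])
    assert out["density_inadequate"].tolist() == out["intake_inadequate"].tolist()


@pytest.mark.parametrize(
    "flags, weights, expected",
    [([1, 1, 0, 0], [1, 1, 1, 1], 0.5), ([1, 0], [1, 3], 0.25)],
)
def test_weighted_prevalence_examples(flags, weights, expected):
    prev, n = weighted_prevalence(flags, weights)
    assert prev == pytest.approx(expected)
    assert n == len(flags)


def test_weighted_prevalence_empty_stratum_is_absent():
    prev, n = weighted_prevalence([True, False], [1.0, 1.0], mask=[False, False])
    assert np.isnan(prev) and n == 0


def test_weighted_prevalence_rejects_nonpositive_weights():
    with pytest.raises(ConfigurationError):
        weighted_prevalence([True], [0.0])


def test_percentile_curve_basics():
    flat = percentile_curve([5.0] * 10)
    assert (flat["value"] == 5.0).all()
    p = percentile_curve([1.0, 2.0, 3.0], percentiles=[50])
    assert p["value"].iloc[0] == pytest.approx(2.0)
    curve = percentile_curve(np.random.default_rng(0).lognormal(size=200))
    assert (np.diff(curve["value"]) >= -1e-12).all()
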