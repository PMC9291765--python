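import pandas as pd
import pytest

from hcesfort import FortificationAdequacyModel, SyntheticConfig
from hcesfort.afe import EnergyRequirementTable


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_households=400, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    from hcesfort.synthetic import generate_dataset

    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_fit(small_config):
    model = FortificationAdequacyModel.from_synthetic(small_config)
    return model, model.fit()


@pytest.fixture(scope="session")
def big_fit():
    """One fitted 10,000-household survey shared by the heavier checks."""
    model = FortificationAdequacyModel.from_synthetic(
        SyntheticConfig(n_households=10_000, seed=7)
    )
    return model, model.fit()


@pytest.fixture()
def toy_energy_table():
    """Minimal requirement table: reference woman 2100, child band 1050."""
    bands = pd.DataFrame({
        "sex": ["f", "m", "f", "m"],
        "age_min": [18, 18, 0, 0],
        "age_max": [120, 120, 17, 17],
        "status": ["none"] * 4,
        "kcal_per_day": [2100, 2600, 1050, 1050],
        "reference": [1, 0, 0, 0],
    })
    return EnergyRequirementTable(
        bands=bands, increments={"pregnant": 285.0, "lactating": 500.0}
    )
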