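import dataclasses

import numpy as np
import pandas as pd
import pytest

import octmorph as om


@pytest.fixture(scope="session")
def default_config() -> om.GeneratorConfig:
    return om.GeneratorConfig()


@pytest.fixture()
def noiseless_config(default_config) -> om.GeneratorConfig:
    return default_config.noiseless()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_pit() -> om.PitGeometry:
    """Reference pit geometry: young-reference CFT / rim height / rim radius."""
    return om.PitGeometry(cft=230.3, rim_height=350.8, rim_radius_mm=1.134,
                          shape=2.0)


def make_effects_table(n_subjects: int, seed: int, *, mu: float = 300.0,
                       beta_age: float = 0.0, beta_age2: float = 0.0,
                       beta_sex: float = 0.0, beta_sf: float = 0.0,
                       intercept_sd: float = 0.0, resid_sd: float = 0.0,
                       both_eyes: bool = True,
                       parameter: str = "p") -> pd.DataFrame:
    """Direct simulation of an eye-level parameter table from the linear
    mixed model (age centered at 40), bypassing the imaging stages."""
    r = np.random.default_rng(seed)
    age = r.uniform(21, 88, n_subjects)
    male = r.random(n_subjects) < 0.37
    sf = r.normal(0, 1.5, n_subjects)
    b = r.normal(0, intercept_sd, n_subjects) if intercept_sd else np.zeros(n_subjects)
    rows = []
    for i in range(n_subjects):
        a = age[i] - 40.0
        mean = (mu + beta_age * a + beta_age2 * a * a + beta_sex * male[i]
                + beta_sf * sf[i] + b[i])
        eyes = ("OD", "OS") if both_eyes else ("OD",)
        for eye in eyes:
            y = mean + (r.normal(0, resid_sd) if resid_sd else 0.0)
            rows.append({"subject_id": f"S{i:04d}", "eye": eye, "age": age[i],
                         "sex": "M" if male[i] else "F", "scan_focus": sf[i],
                         "parameter": parameter, "value": y})
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_cohort_config(default_config) -> om.GeneratorConfig:
    return dataclasses.replace(default_config, n_subjects=8, seed=3)
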