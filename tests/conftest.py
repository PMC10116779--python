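import numpy as np
import pandas as pd
import pytest

from bmineq import SyntheticConfig, generate_population


@pytest.fixture(scope="session")
def hse_config() -> SyntheticConfig:
    """HSE-like generating config without quota distortion (clean gradients)."""
    return SyntheticConfig.hse_default(n_individuals=20_000, seed=42,
                                       quota_distortion=None)


@pytest.fixture(scope="session")
def population(hse_config) -> pd.DataFrame:
    return generate_population(hse_config)


@pytest.fixture(scope="session")
def responders_weighted(population) -> pd.DataFrame:
    """Complete-BMI table with unit weights, trimmed for decomposition tests."""
    t = population.head(6000).reset_index(drop=True).copy()
    t["combined_weight"] = 1.0
    return t


def make_survey_frame(rows: list[dict]) -> pd.DataFrame:
    """Minimal valid survey rows; fields default to legal level codes."""
    base = dict(bmi=27.0, region=1, age_group=3, gender=1, ethnicity=1,
                education=2, occupation=2, imd_quintile=3, limiting_illness=0,
                marital_status=1, urbanicity=1, design_weight=1.0, responded=1)
    out = []
    for r in rows:
        d = dict(base)
        d.update(r)
        out.append(d)
    df = pd.DataFrame(out)
    df.loc[df["responded"] == 0, "bmi"] = np.nan
    return df
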