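import numpy as np
import pandas as pd
import pytest

from cosgpp import SyntheticScenario, generate
from cosgpp.datamodel import MEASURED, NUMERIC_COLUMNS


def make_day_frame(date="2017-06-01", n=48, **overrides):
    """One day of plausible, fully measured half-hourly rows."""
    idx = pd.date_range(date, periods=n, freq="30min")
    hour = idx.hour + idx.minute / 60
    par = np.maximum(0.0, 1400 * np.sin(np.pi * (hour - 4) / 16))
    df = pd.DataFrame(
        {
            "nee": -5.0 + 0.0 * par,
            "fcos": -20.0,
            "ustar": 0.5,
            "t_air": 15.0,
            "t_soil": 11.0,
            "par": par,
            "vpd": 0.8,
            "swc": 0.28,
            "co2_ppm": 415.0,
            "cos_ppt": 500.0,
        },
        index=idx,
    ).rename_axis("timestamp")
    for k, v in overrides.items():
        df[k] = v
    df["nee_flag"] = MEASURED
    df["fcos_flag"] = MEASURED
    return df


@pytest.fixture
def day_frame():
    return make_day_frame()


@pytest.fixture(scope="session")
def summer_frame():
    """One noisy synthetic summer with gaps (the default study conditions)."""
    return generate(SyntheticScenario(seed=11))


@pytest.fixture(scope="session")
def clean_summer_frame():
    """One noise-free, gap-free synthetic summer (truth is exact)."""
    return generate(
        SyntheticScenario(
            seed=12, sd_nee=0.0, sd_fcos=0.0,
            gap_fraction_nee=0.0, gap_fraction_fcos=0.0,
        )
    )
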