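import pandas as pd
import pytest

from csehealth.indicators import INDICATOR_NAMES
from csehealth.synthetic import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """300 areas under default study conditions."""
    return generate(SimulationConfig(n_areas=300, seed=11))


@pytest.fixture(scope="session")
def recovery_dataset():
    """1000 areas, default strong loadings, for parameter-recovery checks."""
    return generate(SimulationConfig(n_areas=1000, seed=42))


@pytest.fixture(scope="session")
def null_dataset():
    """1000 areas with no disadvantage effect on hospitalisations or deaths."""
    return generate(
        SimulationConfig(
            n_areas=1000,
            seed=42,
            pph_disadvantage_slope=0.0,
            pph_remote_excess=(0.0,) * 5,
            death_disadvantage_slope=0.0,
        )
    )


def make_area_frame(child_pops, nonresponse=None):
    """Minimal area table: child populations plus per-indicator non-response.

    ``nonresponse`` maps row position -> {indicator: fraction}; unset fractions
    are 0.
    """
    n = len(child_pops)
    df = pd.DataFrame(
        {
            "area_id": [f"A{i:04d}" for i in range(1, n + 1)],
            "child_pop_0_15": child_pops,
        }
    )
    for name in INDICATOR_NAMES:
        df[f"nr_{name}"] = 0.0
    if nonresponse:
        for row, overrides in nonresponse.items():
            for name, frac in overrides.items():
                df.loc[row, f"nr_{name}"] = frac
    return df
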