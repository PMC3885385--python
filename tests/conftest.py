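import numpy as np
import pandas as pd
import pytest

import thermocomm as tc


@pytest.fixture(scope="session")
def butterfly_pool():
    return tc.generate_species_pool(200, (8.0, 13.0), seed=11)


@pytest.fixture(scope="session")
def shift_dataset(butterfly_pool):
    """One simulated campaign with a +40 m shift at 500 m fading to 0 at 2350 m."""
    scenario = tc.ShiftScenario(
        shift_at_reference=40.0,
        shift_gradient=-40.0 / 1850.0,
        n_squares=214,
        altitude_range=(250.0, 2850.0),
        seed=13,
    )
    return tc.generate_surveys(butterfly_pool, scenario)


@pytest.fixture(scope="session")
def butterfly_indices(butterfly_pool, shift_dataset):
    sti = tc.StiTable(butterfly_pool.sti_table("butterflies"))
    return tc.index_table(shift_dataset, sti, "butterflies")


@pytest.fixture(scope="session")
def butterfly_changes(butterfly_indices):
    changes, slope = tc.standardized_changes(butterfly_indices, kind="cti")
    return changes, slope


def linear_index_records(b=-0.001, intercept=5.0, downhill_m=0.0, n=40,
                         altitudes=None, richness=30):
    """Index records whose survey-2 community sits exactly `downhill_m` m downhill
    on the fitted first-survey line (noise-free)."""
    if altitudes is None:
        altitudes = np.linspace(300, 2700, n)
    altitudes = np.asarray(altitudes, dtype=float)
    rows = []
    for i, a in enumerate(altitudes):
        for survey, alt_eff in ((1, a), (2, a - downhill_m)):
            rows.append(
                {"square_id": f"s{i:03d}", "survey_index": survey, "group": "toy",
                 "cti": intercept + b * alt_eff, "ctv": 1.0, "richness": richness,
                 "altitude_m": a, "altitudinal_range_m": 100.0}
            )
    return pd.DataFrame(rows)
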