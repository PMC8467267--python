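import numpy as np
import pandas as pd
import pytest

from crashcausal.cohort import CohortSpec
from crashcausal.simulate import GeneratorParams, simulate_sample


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams(seed=20210908)


@pytest.fixture(scope="session")
def small_params() -> GeneratorParams:
    """Desk-scale population: quick to generate, sparse above 50 mph."""
    return GeneratorParams(n_population=20_000, seed=20210908)


@pytest.fixture(scope="session")
def small_sample(small_params):
    sample, design, truth = simulate_sample(small_params)
    return sample, design, truth


@pytest.fixture(scope="session")
def frontal_cohort_spec() -> CohortSpec:
    """Left-frontal driver cohort: PDOF 9 to 11 o'clock, years 2001-2015."""
    return CohortSpec()


@pytest.fixture(scope="session")
def wide_cohort_spec() -> CohortSpec:
    """Frontal cohort matching the generator's default 10-to-2 o'clock arc."""
    return CohortSpec(pdof_window=((10, 0), (2, 0)))


def make_two_point_frame(
    n_per_cell: int = 100,
    p_belted: float = 0.10,
    p_unbelted: float = 0.30,
    delta_vs: tuple[float, float] = (20.0, 30.0),
) -> pd.DataFrame:
    """Deterministic four-cell table with exact outcome proportions.

    Two delta V levels x two belt states, each cell holding ``n_per_cell``
    drivers with exactly ``p * n`` deaths, so a saturated logistic fit
    reproduces the cell probabilities exactly.
    """
    rows = []
    rid = 0
    for dv in delta_vs:
        for belt, p in (("used", p_belted), ("not_used", p_unbelted)):
            n_dead = round(p * n_per_cell)
            for i in range(n_per_cell):
                rows.append(
                    {
                        "record_id": f"T{rid:05d}",
                        "year": 2010,
                        "delta_v_mph": dv,
                        "pdof_deg": 300.0,
                        "belt_used": belt,
                        "airbag_deployed": "deployed",
                        "rollover": False,
                        "ejected": False,
                        "role": "driver",
                        "body_type": "car",
                        "model_year": 2008,
                        "died_30day": i < n_dead,
                        "injury_codes": "",
                        "weight": 1.0,
                        "stratum": "S0",
                        "psu": f"P{rid % 8}",
                    }
                )
                rid += 1
    return pd.DataFrame(rows)


@pytest.fixture()
def two_point_frame() -> pd.DataFrame:
    return make_two_point_frame()


@pytest.fixture(autouse=True)
def _seed_numpy_legacy():
    # some oracles use the legacy global stream; keep them reproducible
    np.random.seed(0)
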