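import numpy as np
import pandas as pd
import pytest

from mammorisk.schema import (
    CategoricalVariable,
    CovariateSchema,
    HazardSpec,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150924)


@pytest.fixture(scope="session")
def tiny_schema():
    """Two binary risk factors with known marginals."""
    return CovariateSchema(
        (
            CategoricalVariable("exposure", ("no", "yes"), (0.7, 0.3)),
            CategoricalVariable("group", ("a", "b"), (0.5, 0.5)),
        )
    )


@pytest.fixture(scope="session")
def tiny_hazard_spec():
    return HazardSpec(
        log_hazard_ratios={
            "exposure": {"yes": np.log(2.0)},
            "group": {"b": 0.0},
        },
        baseline_rate=0.01,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 1/12-scale synthetic cohort shared across tests."""
    from mammorisk.cohort import generate_cohort

    return generate_cohort(n=2000, target_events=56, seed=11)


@pytest.fixture(scope="session")
def full_cohort():
    """The default-scale synthetic cohort (24,161 women, ~680 events)."""
    from mammorisk.cohort import generate_cohort

    return generate_cohort(seed=7)


def make_exponential_cohort(
    n: int, rate_per_day: float, censor_day: float, seed: int, lp: np.ndarray | None = None
) -> pd.DataFrame:
    """Simple exponential survival data without the covariate machinery."""
    rng = np.random.default_rng(seed)
    rate = rate_per_day * (np.exp(lp) if lp is not None else 1.0)
    raw = rng.exponential(1.0, size=n) / rate
    event = (raw <= censor_day).astype(int)
    time = np.where(event == 1, raw, censor_day)
    return pd.DataFrame({"time": time, "event": event})
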