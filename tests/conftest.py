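import numpy as np
import pytest
from hypothesis import settings

from phenocpt import RunConfig, SyntheticSpec, TimeSeries, recovery_experiment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_series():
    """Six noisy observations on a declining line; gaps included."""
    rng = np.random.default_rng(42)
    years = np.array([1901, 1902, 1904, 1905, 1907, 1908])
    values = 50.0 - 0.8 * (years - years[0]) + rng.normal(0, 2.0, len(years))
    return TimeSeries(years, values, variable_kind="temperature", label="toy")


@pytest.fixture
def hockey_series():
    """One draw of the default hockey-stick record (break 1985)."""
    from phenocpt import generate_piecewise_series

    series, truth = generate_piecewise_series(SyntheticSpec(seed=11))
    return series, truth


@pytest.fixture(scope="session")
def hockey_recovery():
    """200 replicates of the hockey-stick generator at N = 110, analyzed.

    Two of the 112 years are missing, giving the 110-observation records
    typical of the century-long station series.  Shared by the
    model-selection and parameter-recovery checks.
    """
    spec = SyntheticSpec(missing_frac=2 / 112)
    return recovery_experiment(spec, 200, RunConfig(seed=1234))


@pytest.fixture(scope="session")
def linear_recovery():
    """200 replicates of a linear temperature-like generator (0.01 C/yr, sd 1)."""
    spec = SyntheticSpec(
        breakpoints=(),
        slopes=(0.01,),
        level_at_start=4.0,
        noise_sd=1.0,
        variable_kind="temperature",
        missing_frac=0.0,
    )
    return recovery_experiment(spec, 200, RunConfig(seed=1235))
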