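import numpy as np
import pytest

from tfpikinetics import table1_median_rates, table2_median_rates
from tfpikinetics.inference import LogLikelihood, ParameterSpace
from tfpikinetics.protocols import Dataset, MeasurementSeries
from tfpikinetics.synthetic import generate_dataset, make_reference_design


@pytest.fixture(scope="session")
def table1():
    return table1_median_rates()


@pytest.fixture(scope="session")
def table2():
    return table2_median_rates()


@pytest.fixture(scope="session")
def reference_design():
    return make_reference_design()


@pytest.fixture(scope="session")
def reference_dataset(reference_design):
    return generate_dataset(reference_design)


@pytest.fixture(scope="session")
def param_space():
    return ParameterSpace(variant="full")


@pytest.fixture(scope="session")
def noise_free_dataset(reference_design, param_space):
    """Dataset whose values equal the model predictions exactly."""
    noisy = generate_dataset(reference_design)
    ll = LogLikelihood(noisy, param_space)
    theta = reference_design.theta_full()
    series = []
    for s in noisy.series:
        mu = ll.predict(theta, s.condition, s.times)
        series.append(MeasurementSeries(s.condition, s.times, mu))
    return Dataset(tuple(series))
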