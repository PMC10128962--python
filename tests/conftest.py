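import numpy as np
import pytest

from gliopred import (
    MeasurementDesign,
    build_prior,
    fit_powerlaw,
    table1_ensemble,
)


@pytest.fixture(scope="session")
def ensemble():
    """The packaged 20-patient reference ensemble."""
    return table1_ensemble()


@pytest.fixture(scope="session")
def by_id(ensemble):
    return {e.patient_id: e for e in ensemble}


@pytest.fixture(scope="session")
def prior(ensemble):
    return build_prior(ensemble, powerlaw=fit_powerlaw(ensemble))


@pytest.fixture(scope="session")
def design_3mo():
    """Sparse clinical schedule: MRIs at -6, 0 and +3 months, 1 mm noise."""
    return MeasurementDesign.from_months([-6, 0, 3])


@pytest.fixture(scope="session")
def design_12mo():
    """Sparse schedule with the extra 1-year MRI: -6, 0, 3, 12 months."""
    return MeasurementDesign.from_months([-6, 0, 3, 12])


@pytest.fixture()
def rng():
    return np.random.default_rng(20230331)


def random_valid_params(rng, n, shrinking=False):
    """Sample physically valid parameter vectors (optionally only shrinking
    models, i.e. k/(tau*v) > 1)."""
    from gliopred import ModelParams

    out = []
    while len(out) < n:
        R0 = rng.uniform(10, 45)
        v = rng.uniform(0.5, 4)
        k = rng.uniform(0.5, 0.9 * R0)
        tau = rng.uniform(0.05, 5)
        if shrinking and k / (tau * v) <= 1.05:
            continue
        out.append(ModelParams(R0, v, k, tau))
    return out
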