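import numpy as np
import pytest

from fireattr.synthetic import SyntheticTruth, gen_observed_series


@pytest.fixture(scope="session")
def truth():
    return SyntheticTruth(master_seed=7)


@pytest.fixture(scope="session")
def analysis_years(truth):
    return np.arange(truth.analysis_years[0], truth.analysis_years[1] + 1)


@pytest.fixture(scope="session")
def observed(truth, analysis_years):
    return gen_observed_series(truth, analysis_years)
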