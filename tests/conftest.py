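import numpy as np
import pytest

from metapower import MetaAnalysisData, TestSpec


@pytest.fixture
def spec() -> TestSpec:
    return TestSpec()  # za = 1.96, alpha ~ 0.05


@pytest.fixture
def two_unit_studies() -> MetaAnalysisData:
    """y = (0, 2), sigma = (1, 1): Q = 2, DL tau2 = 1, pooled mu = 1."""
    return MetaAnalysisData.from_arrays([0.0, 2.0], [1.0, 1.0])


@pytest.fixture
def mixed_sigma_data() -> MetaAnalysisData:
    rng = np.random.default_rng(42)
    se = rng.uniform(0.2, 1.5, size=6)
    y = rng.normal(0.3, 0.5, size=6)
    return MetaAnalysisData.from_arrays(y, se)
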