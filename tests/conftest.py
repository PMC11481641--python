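import numpy as np
import pytest

from gwquality.standards import default_specs


#: Published per-year mean parameter vectors of the study campaign (the same
#: calibration targets shipped in data/barand_like.yaml).
YEAR_MEANS = {
    2013: dict(pH=8.25, EC=3032.65, NH4=0.69, NO2=0.31, NO3=187.83, PO4=1.22,
               COD=6.85, Na=237.91),
    2017: dict(pH=7.51, EC=2845.78, NH4=0.53, NO2=0.20, NO3=142.65, PO4=0.39,
               COD=7.65, Na=377.94),
    2018: dict(pH=8.00, EC=2637.8, NH4=0.65, NO2=0.21, NO3=109.76, PO4=0.65,
               COD=7.16, Na=352.37),
    2019: dict(pH=7.21, EC=2773.43, NH4=0.52, NO2=0.26, NO3=170.73, PO4=0.48,
               COD=7.68, Na=383.68),
    2021: dict(pH=7.23, EC=4128.92, NH4=0.47, NO2=0.24, NO3=164.52, PO4=0.37,
               COD=4.21, Na=319.88),
    2022: dict(pH=7.27, EC=3664.21, NH4=0.64, NO2=0.20, NO3=296.1, PO4=0.24,
               COD=2.19, Na=153.51),
}

#: Published per-year mean WQI values of the same campaign.
PUBLISHED_MEAN_WQI = {
    2013: 147.31, 2017: 78.54, 2018: 102.92,
    2019: 86.72, 2021: 72.48, 2022: 72.23,
}


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture(scope="session")
def spec_by_code(specs):
    return {s.code: s for s in specs}


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
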