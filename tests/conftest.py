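import pytest

import loxsim as lx


@pytest.fixture(scope="session")
def default_config() -> lx.ModelConfig:
    return lx.default_parameters()


@pytest.fixture(scope="session")
def wt_timecourse(default_config) -> lx.TimeCourse:
    return lx.simulate(default_config)


@pytest.fixture(scope="session")
def scan(default_config) -> lx.GenotypeScanResult:
    return lx.genotype_scan(default_config)


#: Relative peak n-hexanal per genotype predicted with default
#: parameters (2-decimal reporting precision).
MODEL_RELATIVES = {
    "L123": 1.00,
    "L1": 0.80,
    "L2": 1.06,
    "L3": 0.07,
    "L12": 1.04,
    "L13": 0.70,
    "L23": 1.00,
    "L0": 0.00,
}
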