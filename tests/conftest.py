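import pytest

from fpcea.costs import CostAssumptions, service_mix_from_values
from fpcea.effects import load_anchors
from fpcea.model import DecisionModel
from fpcea.params import load_parameters

# printed arm-level reference values the implementation must reproduce
TABLE_COSTS = {
    "provider": {"intervention": 4079.74, "control": -1625.20},
    "user": {"intervention": 15906.83, "control": 13451.28},
    "total": {"intervention": 19986.56, "control": 11826.07},
}
TABLE_EFFECTS = {
    "cyps": {"intervention": 1350.6, "control": 832.6},
    "pregnancies_averted": {"intervention": 441.0, "control": 260.0},
    "abortions_averted": {"intervention": 251.0, "control": 148.0},
    "dalys_averted": {"intervention": 241.6, "control": 142.8},
}
TABLE_ICERS = {
    "cyps": 15.75,
    "pregnancies_averted": 45.22,
    "abortions_averted": 79.33,
    "dalys_averted": 82.57,
}
SCENARIO_PROVIDER_DALY_ICERS = {1.0: 57.72, 0.5: 67.65, 0.0: 77.58}
SCENARIO_USER_TOTALS = {
    "intervention": {1.0: 15906.83, 0.5: 12339.41, 0.0: 8772.00},
    "control": {1.0: 13451.28, 0.5: 10864.97, 0.0: 8278.66},
}
DELTA_COST_SOCIETAL = 8160.49
SERVICE_CIS = {
    "intervention": {
        "ocp_cycles": (2013, 2330),
        "injectable_doses": (512, 604),
        "implant_insertions": (123, 220),
        "iud_insertions": (72, 153),
        "repeat_abortions": (21, 91),
    },
    "control": {
        "ocp_cycles": (3112, 3499),
        "injectable_doses": (291, 358),
        "implant_insertions": (42, 109),
        "iud_insertions": (32, 93),
        "repeat_abortions": (35, 120),
    },
}


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def anchors():
    return load_anchors()


@pytest.fixture(scope="session")
def assumptions():
    return CostAssumptions()


@pytest.fixture(scope="session")
def model():
    return DecisionModel()


@pytest.fixture(scope="session")
def base_mixes(params):
    base = params.base_values()
    return {arm: service_mix_from_values(base, arm) for arm in ("intervention", "control")}
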