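import pytest
from hypothesis import HealthCheck, settings

import butyflux as bf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return bf.load_pathway()


@pytest.fixture(scope="session")
def lysine_equation(model):
    return bf.balance_equation(
        [model.metabolite("lysine"), model.metabolite("water")],
        [
            model.metabolite("butyrate"),
            model.metabolite("acetate"),
            model.metabolite("ammonia"),
        ],
        reference="lysine",
    )


@pytest.fixture(scope="session")
def label6(model):
    return bf.LabelingState.from_positions("lysine", [6], 6)
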