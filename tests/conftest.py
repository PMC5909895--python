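import pytest
from cobra import Metabolite, Model, Reaction
from hypothesis import HealthCheck, settings

from cofswap import core_acetate_model, loopy_toy_model

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_chain_model() -> Model:
    """Uptake (≤10) → conversion → sink; hand-solvable optimum of 10."""
    model = Model("chain")
    a, b = Metabolite("A", compartment="c"), Metabolite("B", compartment="c")
    model.add_metabolites([a, b])
    up = Reaction("UPTAKE", lower_bound=0, upper_bound=10)
    conv = Reaction("CONV", lower_bound=0, upper_bound=1000)
    sink = Reaction("SINK", lower_bound=0, upper_bound=1000)
    model.add_reactions([up, conv, sink])
    up.add_metabolites({a: 1})
    conv.add_metabolites({a: -1, b: 1})
    sink.add_metabolites({b: -1})
    model.objective = "SINK"
    return model


def build_segment_model(length: float = 10.0) -> Model:
    """One metabolite, source and drain: flux space is a 1-D segment [0, length]."""
    model = Model("segment")
    a = Metabolite("A", compartment="c")
    model.add_metabolites([a])
    src = Reaction("SRC", lower_bound=0, upper_bound=length)
    drain = Reaction("DRAIN", lower_bound=0, upper_bound=length)
    model.add_reactions([src, drain])
    src.add_metabolites({a: 1})
    drain.add_metabolites({a: -1})
    model.objective = "DRAIN"
    return model


@pytest.fixture
def chain_model() -> Model:
    return build_chain_model()


@pytest.fixture
def segment_model() -> Model:
    return build_segment_model()


@pytest.fixture
def core_model() -> Model:
    return core_acetate_model()


@pytest.fixture
def loopy_model() -> Model:
    return loopy_toy_model()
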