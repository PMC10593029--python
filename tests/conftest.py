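import numpy as np
import pytest

from param_lab import scenarios
from param_lab.outcome_space import EventChain, default_chain, strict_chain
from param_lab.scm import sample_population


@pytest.fixture(scope="session")
def chain():
    return default_chain()


@pytest.fixture(scope="session")
def small_chain():
    """Three-event strict chain for cheap exhaustive checks."""
    return strict_chain(("I", "S", "H"))


@pytest.fixture(scope="session")
def skip_chain():
    """Four events where the last may skip its immediate predecessor."""
    return EventChain(
        ("I", "S", "H", "M"),
        frozenset((("I", "S"), ("S", "H"), ("S", "M"))),
    )


@pytest.fixture(scope="session")
def effect_pop():
    """One moderate population under the shipped effect scenario."""
    return sample_population(scenarios.effect_scenario(seed=11), 50_000)


@pytest.fixture(scope="session")
def null_pop():
    return sample_population(scenarios.null_scenario(seed=12), 50_000)
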