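"""Shared fixtures: tiny rate specs, reduced AM configurations, toy trees."""

import numpy as np
import pytest

from clonesim.bdt import EngineState, Genealogy, RateSpec, RateTerm, identity_factory
from clonesim.am import reduced_config
from clonesim.trees import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def constant_spec(b: float = 0.0, d: float = 0.0, t: float = 0.0) -> RateSpec:
    """Single-slot spec with constant per-entity rates (slot 0 fixed at 1)."""
    return RateSpec(
        birth=(RateTerm(b, 0),) if b else (),
        death=(RateTerm(d, 0),) if d else (),
        transform=(RateTerm(t, 0),) if t else (),
    )


def single_slot_state(weights) -> tuple[EngineState, Genealogy]:
    """State with one entity per weight, slot 0 holding the weight."""
    state = EngineState(1, capacity=8)
    gen = Genealogy()
    for w in weights:
        eid = gen.append(None, 0.0)
        state.add(eid, np.array([w], dtype=np.float64))
    return state, gen


@pytest.fixture
def reduced_cfg():
    return reduced_config()


@pytest.fixture
def tree_abc():
    """((a,b),c) with unit branch lengths."""
    return parse_newick("((a:1,b:1):1,c:1);")


@pytest.fixture
def tree_acb():
    return parse_newick("((a:1,c:1):1,b:1);")


@pytest.fixture
def tree_star():
    return parse_newick("(a:1,b:1,c:1);")
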