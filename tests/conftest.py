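import numpy as np
import pytest

from hostcycle import SimulationSettings, WormGrowthParams
from hostcycle.params import DEFAULT_TRAIT_BOUNDS


@pytest.fixture
def wg():
    return WormGrowthParams()


@pytest.fixture
def settings():
    return SimulationSettings()


def draw_traits(rng, n, **overrides):
    """Log-uniform trait draws from the default trait-space bounds."""
    from hostcycle import LifeCycleTraits

    out = []
    for _ in range(n):
        kwargs = {}
        for name, (lo, hi) in DEFAULT_TRAIT_BOUNDS.items():
            kwargs[name] = 10.0 ** rng.uniform(lo, hi)
        kwargs.update(overrides)
        out.append(LifeCycleTraits(**kwargs))
    return out
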