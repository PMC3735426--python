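import math

import numpy as np
import pytest

import streetmorph as sm


@pytest.fixture(scope="session")
def small_town():
    """A compact town exercising every layer, cheap enough for many tests."""
    cfg = sm.TownConfig(
        seed=5, grid_nx=7, grid_ny=7, spacing=200.0, n_diagonals=8,
        n_dwellings=500, n_areas=8, n_respondents=120, respondents_max=40,
    )
    return sm.simulate_town(cfg)


@pytest.fixture(scope="session")
def study_town():
    """A town at the default (study) scale: 687 respondents in 34 areas."""
    return sm.simulate_town(sm.TownConfig(seed=7))


@pytest.fixture()
def chain_graph():
    """Five collinear 100 m segments."""
    lines = [[(1000.0 + 100 * i, 0.0), (1100.0 + 100 * i, 0.0)] for i in range(5)]
    return sm.build_segment_graph(lines)


@pytest.fixture()
def plus_graph():
    """Four arms meeting at one crossing node."""
    c = (1000.0, 500.0)
    arms = [(1100.0, 500.0), (900.0, 500.0), (1000.0, 600.0), (1000.0, 400.0)]
    return sm.build_segment_graph([[c, a] for a in arms])
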