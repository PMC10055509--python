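import numpy as np
import pytest

import neurosgm as ns


@pytest.fixture(scope="session")
def graph8() -> ns.ConnectomeGraph:
    return ns.synth_connectome(8, seed=11)


@pytest.fixture(scope="session")
def graph6() -> ns.ConnectomeGraph:
    return ns.synth_connectome(6, seed=4)


@pytest.fixture(scope="session")
def grid() -> ns.FrequencyGrid:
    return ns.FrequencyGrid.default()


@pytest.fixture(scope="session")
def coarse_grid() -> ns.FrequencyGrid:
    """1-Hz spacing: cheap forward evaluations for optimizer-heavy tests."""
    return ns.FrequencyGrid.default(step=1.0)


@pytest.fixture
def params() -> ns.SGMParameters:
    return ns.SGMParameters()


def random_stable_params(rng: np.random.Generator) -> ns.SGMParameters:
    """Rejection-sample a parameter set inside stage-1 bounds that passes
    the stability check."""
    bounds = ns.stage_bounds(1)
    for _ in range(1000):
        draw = {
            name: rng.uniform(lo, hi) for name, (lo, hi) in bounds.items()
        }
        p = ns.SGMParameters(**draw)
        if ns.stability_check(p, stage=1)[0]:
            return p
    raise RuntimeError("could not draw a stable parameter set")
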