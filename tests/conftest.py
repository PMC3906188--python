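import numpy as np
import pytest

from redoxplane import set_uptake, toy_cerevisiae, toy_stipitis


@pytest.fixture(scope="session")
def sc():
    return toy_cerevisiae()


@pytest.fixture(scope="session")
def ss():
    return toy_stipitis()


@pytest.fixture(scope="session")
def random_uptakes():
    """Five seeded (glc, o2) uptake settings, feasible for both toys."""
    rng = np.random.default_rng(42)
    return [
        (float(rng.uniform(3.0, 12.0)), float(rng.uniform(1.0, 18.0)))
        for _ in range(5)
    ]


def with_uptakes(model, glc, o2):
    m = set_uptake(model, "EX_glc", glc)
    return set_uptake(m, "EX_o2", o2)
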