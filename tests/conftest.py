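import numpy as np
import pytest

from its2repeats.detect import find_repeat_array
from its2repeats.simulate import barbirostris_like_config, generate_dataset


@pytest.fixture(scope="session")
def fig1_dataset():
    """One five-species synthetic dataset under the default study conditions."""
    config = barbirostris_like_config(seed=1)
    records, truth = generate_dataset(config)
    return config, records, truth


@pytest.fixture(scope="session")
def fig1_arrays(fig1_dataset):
    """Detected repeat arrays for the session dataset, keyed by record id."""
    _, records, _ = fig1_dataset
    return {r.id: find_repeat_array(r) for r in records}


@pytest.fixture(scope="session")
def fig1_units(fig1_arrays):
    units = []
    for rid in ("A1", "A2", "A3", "A4", "ca"):
        units.extend(fig1_arrays[rid].units)
    return units


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_seq(rng, n):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=n)])
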