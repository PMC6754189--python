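import itertools

import numpy as np
import pytest

from curtail.instrument import Instrument, ItemSpec, builtin_instrument
from curtail.score_model import ItemProbabilityModel
from curtail.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def soappr24():
    return builtin_instrument("soappr24")


@pytest.fixture(scope="session")
def toy3():
    """3 items scored 0-2, cutoff 4: small enough for exhaustive oracles."""
    return Instrument("toy3", tuple(ItemSpec(0, 2) for _ in range(3)), 4)


@pytest.fixture(scope="session")
def toy4():
    """4 items scored 0-2, cutoff 4: 81 possible response vectors."""
    return Instrument("toy4", tuple(ItemSpec(0, 2) for _ in range(4)), 4)


def uniform_model(instrument: Instrument) -> ItemProbabilityModel:
    return ItemProbabilityModel(
        instrument_name=instrument.name,
        pmfs=tuple(
            np.full(it.n_categories, 1.0 / it.n_categories) for it in instrument.items
        ),
        smoothing_alpha=0.0,
        n_train=0,
    )


@pytest.fixture
def toy3_uniform_model(toy3):
    return uniform_model(toy3)


@pytest.fixture
def toy4_uniform_model(toy4):
    return uniform_model(toy4)


@pytest.fixture(scope="session")
def cohort_seed42(soappr24):
    """Default-parameter labelled cohort used across evaluation tests."""
    return generate_cohort(SimulationConfig(n=2000, seed=42), soappr24)


def all_vectors(instrument: Instrument):
    """Exhaustive enumeration of every possible response vector."""
    ranges = [range(it.min_score, it.max_score + 1) for it in instrument.items]
    return itertools.product(*ranges)


def brute_force_remaining_pmf(model: ItemProbabilityModel, instrument: Instrument, k: int):
    """Oracle: enumerate every outcome combination of items k+1..N.

    Returns (support_min, probability vector) computed without any
    convolution, for cross-checking the dynamic-programming path.
    """
    items = instrument.items[k:]
    pmfs = model.pmfs[k:]
    lo = sum(it.min_score for it in items)
    hi = sum(it.max_score for it in items)
    probs = np.zeros(hi - lo + 1)
    ranges = [range(it.min_score, it.max_score + 1) for it in items]
    for combo in itertools.product(*ranges):
        p = 1.0
        for s, it, pmf in zip(combo, items, pmfs):
            p *= pmf[s - it.min_score]
        probs[sum(combo) - lo] += p
    return lo, probs
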