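import numpy as np
import pytest

import cloneviz as cv


@pytest.fixture
def linear_chain():
    """NORMAL -> A -> B -> C, all present at both time points."""
    return cv.build_evolution(
        {"A": [90, 95], "B": [60, 70], "C": [20, 40]},
        {"A": "normal", "B": "A", "C": "B"},
    )


@pytest.fixture
def branched():
    """A with children B and C; D an independent founder."""
    return cv.build_evolution(
        {"A": [80, 80], "B": [20, 30], "C": [20, 25], "D": [10, 15]},
        {"A": "normal", "B": "A", "C": "A", "D": "normal"},
    )


@pytest.fixture
def single_clone():
    return cv.build_evolution([[100, 100]], ["normal"], clone_labels=["A"])


def random_instance(seed, max_clones=7, max_timepoints=6, **kwargs):
    """Seeded random valid evolution with randomized size and model."""
    rng = np.random.default_rng(seed)
    spec = cv.SimulationSpec(
        n_clones=int(rng.integers(1, max_clones + 1)),
        n_timepoints=int(rng.integers(1, max_timepoints + 1)),
        model=["linear", "branched_dependent", "mixed"][int(rng.integers(0, 3))],
        seed=int(rng.integers(0, 2**31)),
        **kwargs,
    )
    return cv.simulate_evolution(spec)


def corrupt(evo, seed):
    """Randomly break one of the validity rules; returns (ccf, kind)."""
    rng = np.random.default_rng(seed)
    ccf = evo.ccf.copy()
    n, m = ccf.shape
    kind = int(rng.integers(0, 3))
    k = int(rng.integers(0, n))
    t = int(rng.integers(0, m))
    if kind == 0:  # child exceeds parent / founder overflow
        ccf[k, t] = 140.0
    elif kind == 1 and m >= 3:  # reappearance
        ccf[k, :] = 10.0
        ccf[k, int(rng.integers(1, m - 1))] = 0.0
    else:  # zero out a parent under a positive child where possible
        ccf[k, t] = 0.0
    return ccf


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
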