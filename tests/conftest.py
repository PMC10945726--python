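import numpy as np
import pytest

from motifselect import (
    Coupling,
    CVConfig,
    DependencySpec,
    LearnApfaHyperparams,
    TFBSSample,
    generate_genome,
    generate_sample,
    uniform_null,
)
from motifselect.synthetic_data import IDENTITY_MAPPING, dirichlet_marginals


@pytest.fixture(scope="session")
def null():
    return uniform_null()


@pytest.fixture(scope="session")
def genome(null):
    """A 200 kb uniform-composition synthetic background genome."""
    return generate_genome(200_000, null, seed=5)


@pytest.fixture(scope="session")
def small_grid():
    """Two-point hyperparameter grid for fast end-to-end runs."""
    return (LearnApfaHyperparams(0.3, 2, 0.5), LearnApfaHyperparams(1.0, 10, 0.5))


@pytest.fixture
def worked_sample():
    """The four-sequence sample whose V and U values are hand-derived."""
    return TFBSSample(("AA", "AA", "CC", "CC"))


def coupled_sample(l, n, seed, rho=1.0, source=2, target=3):  # noqa: E741
    """Sample with one deterministic-ish coupling and perturbed marginals."""
    rng = np.random.default_rng(seed)
    spec = DependencySpec(
        dirichlet_marginals(l, rng),
        (Coupling(source, target, rho, IDENTITY_MAPPING),),
    )
    return generate_sample(l, n, spec, seed=seed + 1000)


def independent_sample(l, n, seed):  # noqa: E741
    rng = np.random.default_rng(seed)
    spec = DependencySpec(dirichlet_marginals(l, rng))
    return generate_sample(l, n, spec, seed=seed + 1000)


def random_sample(rng, n=None, l=None):  # noqa: E741
    """A uniformly random valid sample for oracle comparisons."""
    n = n or int(rng.integers(2, 51))
    l = l or int(rng.integers(2, 11))
    mat = rng.integers(0, 4, size=(n, l))
    return TFBSSample(tuple("".join("ACGT"[c] for c in row) for row in mat))
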