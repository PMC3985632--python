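import numpy as np
import pytest

from chromo3d import (
    ModelParameters,
    OptimizerOptions,
    apply_cutoff,
    make_instance,
    normalize_matrix,
)
from chromo3d.io import ContactMatrix
from chromo3d.normalize import ConstraintSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def binary_instance():
    """Noiseless 20-bin random-walk instance with exact binary contacts."""
    return make_instance(n=20, seed=11)


@pytest.fixture(scope="session")
def binary_constraints(binary_instance):
    N = normalize_matrix(binary_instance.matrix)
    return apply_cutoff(N, 0.1)


@pytest.fixture(scope="session")
def reconstructed(binary_constraints):
    """One optimized model of the session fixture (shared, ~0.3 s)."""
    from chromo3d import reconstruct

    return reconstruct(binary_constraints, opts=OptimizerOptions(seed=42))


def two_block_matrix(n: int, intra: float = 5.0, inter: float = 1.0) -> ContactMatrix:
    """Normalized-scale matrix with two equally sized enriched blocks."""
    half = n // 2
    V = np.full((n, n), inter, dtype=float)
    V[:half, :half] = intra
    V[half:, half:] = intra
    np.fill_diagonal(V, 0.0)
    return ContactMatrix(values=V, normalized=True)


def random_constraint_set(n: int, rng: np.random.Generator) -> ConstraintSet:
    """Random partition of pairs into contacts / non-contacts with random
    positive weights; used by the gradient and scoring oracles."""
    iu, ju = np.triu_indices(n, k=1)
    adjacent = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    keep = ju - iu > 1
    iu, ju = iu[keep], ju[keep]
    is_contact = rng.random(len(iu)) < 0.5
    if not np.any(is_contact):
        is_contact[0] = True
    return ConstraintSet(
        n=n,
        cutoff=0.5,
        contacts=np.column_stack([iu[is_contact], ju[is_contact]]),
        contact_weights=rng.uniform(0.6, 5.0, int(is_contact.sum())),
        noncontacts=np.column_stack([iu[~is_contact], ju[~is_contact]]),
        adjacent=adjacent,
    )


def random_parameters(rng: np.random.Generator) -> ModelParameters:
    dmin2 = rng.uniform(0.01, 0.1)
    dmaxadj2 = dmin2 + rng.uniform(0.5, 2.0)
    dc2 = dmin2 + rng.uniform(2.0, 8.0)
    dmax2 = dc2 + rng.uniform(5.0, 20.0)
    return ModelParameters(
        dc2=dc2, dmin2=dmin2, dmax2=dmax2, dmaxadj2=dmaxadj2,
        W1=rng.uniform(0.2, 2.0), W2=rng.uniform(0.2, 2.0),
        W3=rng.uniform(0.2, 2.0), W4=rng.uniform(0.2, 2.0),
    )
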