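import numpy as np
import pytest

from dictpair import (
    PDPLParams,
    SubspaceSpec,
    make_subspace_dataset,
)
from dictpair.evaluation import group_by_class
from dictpair.pdpl import TrainingSet


@pytest.fixture(scope="session")
def subspace_dataset():
    """Well-separated, low-noise multi-subject subspace data (K=3, r=4)."""
    spec = SubspaceSpec(
        K=3, p=30, r=4, n_per_class_per_subject=20, N_subjects=4,
        subject_shift_scale=0.0, noise_sigma=0.05, class_separation=0.5, seed=11,
    )
    return make_subspace_dataset(spec)


@pytest.fixture(scope="session")
def small_training_set(subspace_dataset):
    ds = subspace_dataset
    X = np.hstack([s.X for s in ds.subjects])
    y = np.concatenate([s.labels for s in ds.subjects])
    return group_by_class(X, y, ds.K)


@pytest.fixture(scope="session")
def small_params():
    return PDPLParams(m=4, tau=0.03, lam=0.003, gam=1e-4, seed=3)


def random_instance(rng, p=8, m=4, K=2, n=10):
    """A random (TrainingSet, D_blocks, P_blocks, A_blocks) tuple."""
    F = TrainingSet([rng.standard_normal((p, n)) for _ in range(K)])
    D = [rng.standard_normal((p, m)) for _ in range(K)]
    P = [rng.standard_normal((m, p)) for _ in range(K)]
    A = [rng.standard_normal((m, n)) for _ in range(K)]
    return F, D, P, A
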