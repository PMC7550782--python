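import numpy as np
import pandas as pd
import pytest

import ftirblup as fb
from ftirblup.mixed_models import ModelSpec, TraitModel, VarianceComponents


@pytest.fixture(scope="session")
def small_config():
    return fb.SimConfig(
        n_founders=40,
        n_generations=2,
        n_sires_per_gen=6,
        daughters_per_sire_lab=3,
        daughters_per_sire_field=5,
        n_markers=60,
        n_wavelengths=40,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return fb.simulate_dataset(small_config)


@pytest.fixture
def trio_pedigree():
    """Sire (1), dam (2), offspring (3)."""
    return fb.Pedigree(
        animal=np.array([1, 2, 3]),
        sire=np.array([0, 0, 1]),
        dam=np.array([0, 0, 2]),
        generation=np.array([0, 0, 1]),
    )


@pytest.fixture
def lab_spec():
    return ModelSpec(traits=[TraitModel("LAB", "LAB", fixed=("htd", "dim_class"))])


@pytest.fixture
def unit_vc():
    return VarianceComponents(
        trait_names=["LAB"], sigma_a=[[1.0]], sigma_e=[1.0], sigma_pe=[0.0]
    )


def path_counting_kinship(ped) -> np.ndarray:
    """Independent oracle: additive relationships by recursive kinship.

    A[i, j] = 2 * f(i, j) with the textbook coancestry recursion; no
    tabular shortcuts shared with the implementation.
    """
    animal = list(ped.animal)
    pos = {a: i for i, a in enumerate(animal)}
    parents = {
        a: (s if s else None, d if d else None)
        for a, s, d in zip(ped.animal, ped.sire, ped.dam)
    }
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(a, b):
        if a is None or b is None:
            return 0.0
        ia, ib = pos[a], pos[b]
        if ia < ib:  # recurse through the younger animal
            a, b = b, a
        if a == b:
            s, d = parents[a]
            return 0.5 * (1.0 + f(s, d))
        s, d = parents[a]
        return 0.5 * (f(s, b) + f(d, b))

    n = len(animal)
    A = np.zeros((n, n))
    for i, a in enumerate(animal):
        for j, b in enumerate(animal):
            A[i, j] = 2.0 * f(a, b)
    return A


def dense_blup_oracle(y, X, Z, A, sigma_a2, sigma_e2):
    """GLS/BLUP on the variance of the data: independent of the MME path."""
    V = Z @ A @ Z.T * sigma_a2 + np.eye(len(y)) * sigma_e2
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = sigma_a2 * A @ Z.T @ Vi @ (y - X @ b)
    return b, u
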