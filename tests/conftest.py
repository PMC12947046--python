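"""Shared fixtures: small random structures and compact model setups."""

from __future__ import annotations

import numpy as np
import pytest

from molrank.gnn import RBFConfig, init_parameters
from molrank.moldata import Structure


def random_structure(rng: np.random.Generator, n_atoms: int = None,
                     group_id: str = "g", structure_id: str = "s",
                     min_dist: float = 0.8) -> Structure:
    """A random point-cloud structure with enforced minimum distance."""
    if n_atoms is None:
        n_atoms = int(rng.integers(2, 7))
    for _ in range(500):
        pos = rng.uniform(0.0, 4.0, size=(n_atoms, 3))
        if n_atoms == 1:
            break
        diff = pos[:, None] - pos[None, :]
        d = np.sqrt((diff ** 2).sum(-1))
        if d[~np.eye(n_atoms, dtype=bool)].min() >= min_dist:
            break
    z = rng.choice([1, 6, 7, 8], size=n_atoms)
    return Structure(structure_id, group_id, z, pos)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_rbf():
    """A compact RBF grid (16 centres on [0, 8)) for fast tests."""
    return RBFConfig.uniform(0.0, 8.0, 0.5)


@pytest.fixture
def small_params(small_rbf):
    """A tiny scorer: 8 features, 2 interaction steps."""
    return init_parameters(n_features=8, n_interactions=2, cfg=small_rbf,
                           z_max=10, r_cut_init=6.0, seed=7)
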