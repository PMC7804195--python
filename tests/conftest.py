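"""Shared fixtures.

The expensive session-scoped pool (130 featurized water dimer/trimer frames
with surrogate labels) reproduces the standard study conditions of the
learning-curve experiments and is shared by the model-recovery and
acceptance tests; it is only built when a test requests it.
"""

from __future__ import annotations

import numpy as np
import pytest

from kdfa.basis import builtin_basis
from kdfa.fixtures import featurize_ensemble, make_geometries, synthetic_labels
from kdfa.grids import GridSpec
from kdfa.model import TrainingSet
from kdfa.units import MEV_TO_HARTREE

POOL_SEEDS = (101, 102)
POOL_LABEL_SEED = 7
POOL_SIZE_EACH = 65  # dimers + trimers -> 130 frames


@pytest.fixture(scope="session")
def aux_basis():
    return builtin_basis()


@pytest.fixture(scope="session")
def default_grid():
    return GridSpec()


@pytest.fixture(scope="session")
def coarse_grid():
    return GridSpec(n_radial=25, n_theta=10, n_phi=20)


@pytest.fixture(scope="session")
def converged_grid():
    """Resolution at which quadrature anisotropy drops below 1e-6 relative."""
    return GridSpec(n_radial=70, n_theta=24, n_phi=48)


@pytest.fixture(scope="session")
def water_monomer():
    return make_geometries("water_cluster", 1, 1, jitter_sigma=0.0, seed=1).geometries[0]


@pytest.fixture(scope="session")
def monomer_features(aux_basis, coarse_grid):
    """Twelve jittered water monomers, featurized on the coarse grid."""
    ens = make_geometries("water_cluster", 1, 12, jitter_sigma=0.05, seed=5)
    return featurize_ensemble(ens, aux_basis, coarse_grid)


@pytest.fixture(scope="session")
def mixed_features(aux_basis, coarse_grid):
    """Twelve frames spanning four system kinds; the feature diversity keeps
    the Gram matrix well-conditioned for the interpolation checks."""
    feats = []
    for kind, n_mono, seed in [
        ("water_cluster", 1, 5),
        ("water_cluster", 2, 6),
        ("alkane", 2, 7),
        ("protonated_water", 1, 8),
    ]:
        ens = make_geometries(kind, n_mono, 3, jitter_sigma=0.05, seed=seed)
        feats += featurize_ensemble(ens, aux_basis, coarse_grid)
    return feats


@pytest.fixture(scope="session")
def cluster_pool(aux_basis, default_grid) -> TrainingSet:
    """130 water dimer/trimer frames at the standard study conditions.

    Jitter 0.05 Angstrom (thermal snapshots), default production grid,
    surrogate labels with 1 meV noise.
    """
    feats = []
    for n_mono, seed in zip((2, 3), POOL_SEEDS):
        ens = make_geometries(
            "water_cluster", n_mono, POOL_SIZE_EACH, jitter_sigma=0.05, seed=seed
        )
        feats += featurize_ensemble(ens, aux_basis, default_grid)
    labels = synthetic_labels(
        feats, noise_sigma=1.0 * MEV_TO_HARTREE, seed=POOL_LABEL_SEED
    )
    return TrainingSet(feats, labels, metadata={"reference_method": "synthetic"})
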