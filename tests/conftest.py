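"""Shared fixtures: small synthetic spaces and planted-phenotype datasets."""

import numpy as np
import pytest
from hypothesis import settings

from phenolearn.simspace import make_ground_truth

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_space():
    """4x4 latent space, 2 clone / 2 drug groups, 3 phenotypes, duplicated."""
    return make_ground_truth(
        n_latent_targets=4,
        n_latent_conditions=4,
        n_clone_groups=2,
        n_drug_groups=2,
        n_phenotypes=3,
        feature_dim=3,
        min_separation=8.0,
        seed=42,
    )


def planted_point_sets(seed, k=4, per_phenotype=3, n_images=40, dim=3, sep=8.0):
    """Well-separated planted phenotypes: ``per_phenotype`` experiments each.

    Experiment ids are (phenotype, replicate); images are i.i.d. unit-spread
    Gaussians around phenotype means drawn with spread ``sep``.
    """
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, sep, (k, dim))
    return {
        (p, e): means[p] + rng.normal(0.0, 1.0, (n_images, dim))
        for p in range(k)
        for e in range(per_phenotype)
    }


@pytest.fixture
def planted_four():
    return planted_point_sets(seed=0)
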