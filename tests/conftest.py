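import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import microqtl as mq


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study reused across read-only tests."""
    cfg = mq.StudyConfig(
        n_individuals=120,
        n_chromosomes=3,
        markers_per_chromosome=12,
        n_asvs=40,
        library_size_mean=8000.0,
        seed=11,
    )
    return mq.make_study(cfg)


@pytest.fixture()
def four_leaf_tree():
    return TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture()
def balanced_covariates():
    """2x2 sex/diet balanced design over 200 samples."""
    n = 200
    samples = [f"s{i}" for i in range(n)]
    sex = np.where(np.arange(n) % 2 == 0, "male", "female")
    diet = np.where(np.arange(n) % 4 < 2, "American", "ketogenic")
    return mq.CovariateTable(
        pd.DataFrame({"sex": sex, "diet": diet}, index=pd.Index(samples, name="sample_id"))
    )


def random_count_table(rng, n_samples=6, n_asvs=10, zero_fraction=0.3):
    counts = rng.poisson(20, (n_samples, n_asvs))
    counts[rng.random(counts.shape) < zero_fraction] = 0
    # make sure every sample keeps at least one taxon
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_asvs)] = 5
    return mq.CountTable(
        [f"s{i}" for i in range(n_samples)],
        [f"t{j}" for j in range(n_asvs)],
        counts.astype(np.int64),
    )
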