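import numpy as np
import pytest

import monster as ms


@pytest.fixture
def small_dataset():
    """A harmonized 60-gene / 6-TF dataset with one swapped driver pair."""
    expr, prior, truth = ms.generate(
        p=60, m=6, targets_per_gene=2, n_per_group=(15, 15),
        effect_size=1.0, noise_sd=0.5, n_drivers=1, rewire_mode="swap", seed=11)
    expr, prior = ms.harmonize(expr, prior)
    return expr, prior, truth


@pytest.fixture
def tsv_inputs(tmp_path):
    """Simulated dataset written out in the pipeline's input dialects."""
    expr, prior, truth = ms.generate(
        p=40, m=5, targets_per_gene=2, n_per_group=(8, 8),
        effect_size=1.0, noise_sd=0.5, n_drivers=1, seed=4)
    paths = ms.write_dataset(expr, prior, tmp_path)
    return paths, truth


def random_full_rank(p, m, rng):
    """A genes x TFs matrix that is full column rank with probability 1."""
    return rng.standard_normal((p, m))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
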