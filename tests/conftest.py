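import numpy as np
import pytest

from coexstream.synthetic import FixtureSpec, generate_module_matrix


@pytest.fixture(scope="session")
def module_matrix():
    """The reference planted-module corpus: 5 modules x 20 genes,
    200 background genes, 50 samples, 10% multiplicative noise."""
    spec = FixtureSpec(n_genes=300, n_samples=50, n_modules=5,
                       genes_per_module=20, noise_sd=0.1, seed=42)
    matrix, truth = generate_module_matrix(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def organ_matrix():
    """Organ-planted corpus: each module's latent profile is elevated in
    one organ's samples."""
    organ_plan = {"root": 10, "leaf": 10, "flower": 10, "shoot": 10,
                  "stem": 10}
    spec = FixtureSpec(n_genes=160, n_samples=50, n_modules=5,
                       genes_per_module=12, noise_sd=0.1, seed=7,
                       organ_plan=organ_plan)
    matrix, truth = generate_module_matrix(spec)
    return spec, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
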