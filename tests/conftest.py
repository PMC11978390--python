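import numpy as np
import pytest

from badger import synthetic_world as sw
from badger.network import Badger, ModelConfig


TINY_WORLD = dict(n_drugs=8, n_cells=4, n_pathways=4, n_genes=20,
                  v_fragments=10, sparsity=0.2, noise_sd=0.05)


@pytest.fixture(scope="session")
def tiny_world():
    return sw.generate_world(seed=7, **TINY_WORLD)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_world):
    return sw.generate_dataset(tiny_world, n_instances=60, seed=7)


@pytest.fixture(scope="session")
def tiny_model_config(tiny_world):
    return ModelConfig(embed_dim=16, n_heads=2, mlp_hidden=32, head_hidden=4,
                       n_genes=tiny_world.n_genes,
                       n_pathways=tiny_world.n_pathways,
                       n_anchors=len(tiny_world.cell_ids),
                       n_bits=tiny_world.n_bits, seed=3)


@pytest.fixture()
def tiny_model(tiny_model_config):
    model = Badger(tiny_model_config)
    model.eval()
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
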