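import numpy as np
import pytest

from dtitwins.barlow import BTConfig, build_model
from dtitwins.data import DTIDataset, DTIRecord
from dtitwins.featurize import FeatureBundle


@pytest.fixture(scope="session")
def tiny_bt_config():
    return BTConfig(enc_n_neurons=16, enc_n_layers=1, proj_n_neurons=8,
                    proj_n_layers=1, embedding_dim=4, batch_size=8,
                    epochs=5, patience=10, seed=0)


@pytest.fixture()
def tiny_model(tiny_bt_config):
    return build_model(mol_dim=12, prot_dim=10, config=tiny_bt_config)


@pytest.fixture(scope="session")
def random_bundle():
    """Random paired features where the protein vector is a fixed linear
    map of the molecule vector, so a learnable cross-correlation exists."""
    rng = np.random.default_rng(42)
    mol = rng.normal(size=(48, 12))
    W = rng.normal(size=(12, 10))
    prot = mol @ W + 0.05 * rng.normal(size=(48, 10))
    ids = [f"r{i:03d}" for i in range(48)]
    return FeatureBundle(mol, prot, ids)


def make_dataset(n=10, task="classification"):
    rng = np.random.default_rng(0)
    records = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12))
        smiles = "C" * (2 + i % 5)
        records.append(DTIRecord(f"r{i:03d}", smiles, seq, float(i % 2)))
    return DTIDataset(records, task=task)


@pytest.fixture()
def small_dataset():
    return make_dataset(10)
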