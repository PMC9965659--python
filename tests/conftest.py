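import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_records():
    """Small noise-free planted-signal dataset shared across tests."""
    from dtafuse.data import SyntheticSpec, generate_synthetic

    spec = SyntheticSpec(n_records=60, noise_sd=0.0, seed=7)
    records, meta = generate_synthetic(spec)
    return spec, records, meta


@pytest.fixture(scope="session")
def tiny_model_config():
    from dtafuse.model import ModelConfig

    return ModelConfig(
        max_smiles_len=48, max_protein_len=56, embedding_dim=8,
        smiles_filters=(6, 8), protein_filters=(6, 8), smiles_kernel=3,
        protein_kernel=5, se_reduction=2, gin_depth=3, gin_hidden=16,
        gin_out=16, attn_dim=16, heads=2, mlp_hidden=(32, 32, 16),
        dropout=0.1, seed=0,
    )
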