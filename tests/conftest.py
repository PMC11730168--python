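import numpy as np
import pytest

from powerdta import (SyntheticSpec, generate_dataset,
                      train_embedding_dictionary)
from powerdta.dta_model import ModelConfig


@pytest.fixture(scope="session")
def tiny_model_config():
    """Smallest config that still exercises every block."""
    return ModelConfig(
        drug_feature_dim=78, powers=(1, 2, 3),
        gcn_block_dims={1: (4, 4, 8), 2: (4, 8), 3: (8,)},
        protein_channels=4, protein_rows=8,
        protein_conv_filters=(4, 4, 4), protein_kernel_sizes=(3, 3, 3),
        fusion_dims=(8, 4), dropout_rate=0.2)


@pytest.fixture(scope="session")
def small_dictionary():
    rng = np.random.default_rng(11)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    corpus = ["".join(rng.choice(letters, size=40)) for _ in range(20)]
    return train_embedding_dictionary(corpus, d=8, seed=11, epochs=2)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale planted-signal dataset for pipeline tests."""
    spec = SyntheticSpec(n_drugs=12, n_proteins=6, n_pairs=60,
                         seq_len_range=(40, 60), seed=5)
    return generate_dataset(spec)
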