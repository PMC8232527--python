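import numpy as np
import pytest
from hypothesis import settings

from aptasearch import (
    InteractionClassifier,
    SyntheticConfig,
    aptamer_encoder,
    generate_train_test,
    protein_encoder,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_splits():
    """A small, fast, fully learnable synthetic train/test split."""
    cfg = SyntheticConfig(
        n_pos=24,
        n_neg=72,
        aptamer_length_range=(20, 40),
        protein_length_range=(30, 60),
        n_proteins=3,
        seed=11,
    )
    train, test, truth = generate_train_test(cfg)
    return train, test, truth


def split_xy(records):
    pairs = [(a, p) for a, p, _ in records]
    labels = np.array([l for _, _, l in records], dtype=int)
    return pairs, labels


@pytest.fixture(scope="session")
def tiny_model(tiny_splits):
    """One fitted interaction classifier shared across tests."""
    train, _test, _truth = tiny_splits
    pairs, labels = split_xy(train)
    return InteractionClassifier(
        apt_encoder=aptamer_encoder("iCTF"),
        prot_encoder=protein_encoder("AAC"),
        n_trees=60,
        seed=7,
    ).fit(pairs, labels)
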