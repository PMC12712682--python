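import numpy as np
import pytest

import enzadapt as ez


@pytest.fixture(scope="session")
def small_corpus():
    """Family-structured corpus: 6 families x 8 sequences, 2 reactions each."""
    spec = ez.SyntheticSpec(
        n_families=6,
        sequences_per_family=8,
        length_range=(15, 45),
        reaction_templates_per_family=2,
        mutation_rate=0.05,
        seed=42,
    )
    return ez.generate_corpus(spec)


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return ez.build_vocabulary(
        [ez.tokenize(p.reaction.smiles) for p in small_corpus], min_frequency=1
    )


@pytest.fixture(scope="session")
def tiny_config(small_vocab):
    return ez.FusionModelConfig(
        vocab_size=len(small_vocab),
        reaction_hidden=32,
        reaction_heads=2,
        reaction_ffn=64,
        protein_hidden=32,
        protein_layers=2,
        protein_heads=2,
        protein_ffn=64,
        max_reaction_positions=128,
        max_protein_positions=128,
    )


@pytest.fixture()
def tiny_model(tiny_config):
    return ez.FusionMLM(tiny_config, seed=0)


@pytest.fixture()
def tiny_train_config():
    return ez.TrainConfig(
        micro_batch_size=8,
        max_steps=10,
        augment=False,
        trainable_protein_layers=2,
        seed=1,
    )


def encode_batch(pairs, vocab):
    """Encode a batch of pairs to a common width (no augmentation)."""
    token_lists = [ez.tokenize(p.reaction.smiles).tokens for p in pairs]
    width = max(len(t) for t in token_lists) + 2
    ids = np.stack([np.array(ez.encode(t, vocab, width)) for t in token_lists])
    return [p.sequence for p in pairs], ids
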