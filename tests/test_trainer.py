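import numpy as np
import pytest

import enzadapt as ez
from enzadapt import autograd as ag
from enzadapt.model import mask_tokens
from enzadapt.training import (
    AdamW,
    TrainConfig,
    clip_global_norm,
    make_optimizer,
    partition_parameters,
)

from conftest import encode_batch


def deep_model(vocab, protein_layers=6, pretrained=True):
    """Fusion model whose protein encoder is deep enough to freeze layers."""
    config = ez.FusionModelConfig(
        vocab_size=len(vocab), reaction_hidden=16, reaction_heads=2,
        reaction_ffn=32, protein_hidden=16, protein_layers=protein_layers,
        protein_heads=2, protein_ffn=32, max_reaction_positions=128,
        max_protein_positions=128,
    )
    encoder = ez.TinyProteinEncoder(
        hidden=16, layers=protein_layers, heads=2, ffn=32,
        max_positions=128, seed=3, pretrained=pretrained,
    )
    return ez.FusionMLM(config, protein_encoder=encoder, seed=0)


class TestPartitionParameters:
    def test_all_but_last_k_protein_layers_frozen(self, small_vocab):
        model = deep_model(small_vocab, protein_layers=6)
        groups = partition_parameters(model, trainable_protein_layers=4)
        frozen_names = {n for n, _ in groups["frozen"]}
        assert any("layers.0." in n for n in frozen_names)
        assert any("layers.1." in n for n in frozen_names)
        assert not any("layers.5." in n for n in frozen_names)
        # embeddings feed only frozen layers -> frozen too
        assert "protein_encoder.token_embedding" in frozen_names

    def test_encoder_with_exactly_k_layers_has_nothing_frozen(self, small_vocab):
        model = deep_model(small_vocab, protein_layers=4)
        groups = partition_parameters(model, trainable_protein_layers=4)
        assert groups["frozen"] == []

    def test_too_shallow_encoder_rejected(self, small_vocab):
        model = deep_model(small_vocab, protein_layers=3)
        with pytest.raises(ValueError):
            partition_parameters(model, trainable_protein_layers=4)

    def test_reaction_side_and_pool_projection_are_new(self, small_vocab):
        model = deep_model(small_vocab, protein_layers=6)
        groups = partition_parameters(model, trainable_protein_layers=4)
        new_names = {n for n, _ in groups["new_trainable"]}
        assert any(n.startswith("pooler") for n in new_names)
        assert any(n.startswith("projection") for n in new_names)
        assert any(n.startswith("reaction_layers") for n in new_names)
        assert "token_embedding" in new_names

    def test_untrained_encoder_counts_as_new(self, small_vocab):
        model = deep_model(small_vocab, protein_layers=6, pretrained=False)
        groups = partition_parameters(model, trainable_protein_layers=4)
        assert groups["pretrained_trainable"] == []


class TestOptimizer:
    def test_exactly_two_learning_rates(self, small_vocab):
        model = deep_model(small_vocab)
        config = TrainConfig(trainable_protein_layers=4)
        optimizer, _ = make_optimizer(model, config)
        assert optimizer.learning_rates == sorted([5e-5, 2e-4])

    def test_clip_scales_to_max_norm(self):
        p = ag.Parameter(np.zeros((4,)))
        p.grad = np.full(4, 5.0)  # norm 10
        norm = clip_global_norm([p], max_norm=1.0)
        assert norm == pytest.approx(10.0)
        assert np.linalg.norm(p.grad) == pytest.approx(1.0)

    def test_clip_leaves_small_gradients_alone(self):
        p = ag.Parameter(np.zeros((4,)))
        p.grad = np.full(4, 0.1)
        clip_global_norm([p], max_norm=1.0)
        assert np.allclose(p.grad, 0.1)

    def test_weight_decay_skips_biases_and_norm_parameters(self):
        w = ag.Parameter(np.ones((2, 2)))
        b = ag.Parameter(np.ones(2))
        w.grad = np.zeros((2, 2))
        b.grad = np.zeros(2)
        opt = AdamW([([("w", w), ("b", b)], 0.1)], weight_decay=0.5)
        opt.step()
        assert (w.data < 1).all()  # decayed
        assert np.allclose(b.data, 1.0)  # not decayed

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_new=0.0)
        with pytest.raises(ValueError):
            TrainConfig(clip_norm=0.0)
        with pytest.raises(ValueError):
            TrainConfig(mixed_precision=True)


class TestTraining:
    def test_frozen_parameters_bit_identical_after_training(
        self, small_vocab, small_corpus
    ):
        model = deep_model(small_vocab, protein_layers=6)
        groups = partition_parameters(model, trainable_protein_layers=4)
        before = {n: p.data.tobytes() for n, p in groups["frozen"]}
        config = TrainConfig(
            micro_batch_size=8, max_steps=8, augment=False,
            trainable_protein_layers=4, seed=2,
        )
        ez.train(model, list(small_corpus), small_vocab, config)
        for name, p in groups["frozen"]:
            assert p.data.tobytes() == before[name], name

    def test_gradient_accumulation_equals_full_batch(
        self, tiny_config, small_vocab, small_corpus
    ):
        """Weighted micro-batch backward passes reproduce the pooled gradient."""
        seqs, ids = encode_batch(small_corpus[:8], small_vocab)
        batch = mask_tokens(ids, small_vocab, rate=0.3, seed=9)

        full = ez.FusionMLM(tiny_config, seed=0)
        _, loss = full.forward_mlm(seqs, batch)
        ag.backward(loss)
        full_grads = {n: p.grad.copy() for n, p in full.named_parameters()
                      if p.grad is not None}

        accum = ez.FusionMLM(tiny_config, seed=0)
        total = batch.n_masked
        for lo in range(0, 8, 2):
            sub = ez.model.MaskedBatch(
                input_ids=batch.input_ids[lo:lo + 2],
                labels=batch.labels[lo:lo + 2],
                attention_mask=batch.attention_mask[lo:lo + 2],
                mask_positions=batch.mask_positions[lo:lo + 2],
                unmaskable=batch.unmaskable[lo:lo + 2],
            )
            _, sub_loss = accum.forward_mlm(seqs[lo:lo + 2], sub)
            ag.backward(ag.mul(sub_loss, sub.n_masked / total))
        for name, p in accum.named_parameters():
            if p.grad is None:
                continue
            ref = full_grads[name]
            denom = max(np.abs(ref).max(), 1e-12)
            assert np.abs(p.grad - ref).max() / denom < 1e-5, name

    def test_same_seed_same_loss_trace(self, tiny_config, small_vocab, small_corpus):
        config = TrainConfig(
            micro_batch_size=8, max_steps=6, augment=False,
            trainable_protein_layers=2, seed=11,
        )
        traces = []
        for _ in range(2):
            model = ez.FusionMLM(tiny_config, seed=1)
            result = ez.train(model, list(small_corpus), small_vocab, config)
            traces.append([loss for _, _, loss in result.loss_trace])
        assert traces[0] == traces[1]

    def test_empty_corpus_rejected(self, tiny_model, small_vocab):
        with pytest.raises(ValueError):
            ez.train(tiny_model, [], small_vocab, TrainConfig())

    def test_validation_checkpointing(self, tiny_config, small_vocab, small_corpus):
        model = ez.FusionMLM(tiny_config, seed=1)
        config = TrainConfig(
            micro_batch_size=8, max_steps=6, eval_every=3, augment=False,
            trainable_protein_layers=2, seed=4,
        )
        result = ez.train(
            model, list(small_corpus[:32]), small_vocab, config,
            val_pairs=list(small_corpus[32:40]),
        )
        assert result.best_state is not None
        assert any(split == "validation" for _, split, _ in result.loss_trace)
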