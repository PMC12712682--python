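"""Optimization protocol for the fusion MLM.

Two-tier constant learning rates (5e-5 for parameters loaded from a
pretrained checkpoint, 2e-4 for newly initialized ones), AdamW with
beta1 = 0.9, beta2 = 0.999, eps = 1e-8 and decoupled weight decay 0.01,
global gradient-norm clipping at 1.0, gradient accumulation across
micro-batches, and partial freezing of the protein encoder (all but its
last four layers by default).  No warm-up and no schedule.

Accumulated micro-batch losses are weighted by their masked-token counts,
so an accumulated update equals the update a single full batch would have
produced.  All arithmetic is float64, making loss traces bit-reproducible
given a seed; a mixed-precision flag is accepted for interface parity but
the NumPy backend runs full precision only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Parameter
from .dataset import EnzymeReactionPair
from .model import FusionMLM, MaskedBatch, mask_tokens
from .simulate import augment_reaction
from .tokenizer import TokenVocabulary, encode, tokenize


@dataclass
class TrainConfig:
    lr_pretrained: float = 5e-5
    lr_new: float = 2e-4
    betas: tuple[float, float] = (0.9, 0.999)
    epsilon: float = 1e-8
    weight_decay: float = 0.01
    clip_norm: float = 1.0
    accumulation_steps: int = 1
    micro_batch_size: int = 8
    max_steps: int = 200
    eval_every: int = 50
    trainable_protein_layers: int = 4
    mask_rate: float = 0.30
    mask_scheme: str = "bert"
    augment: bool = True
    mixed_precision: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.lr_pretrained <= 0 or self.lr_new <= 0:
            raise ValueError("learning rates must be positive")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if self.accumulation_steps < 1:
            raise ValueError("accumulation_steps must be >= 1")
        if self.mixed_precision:
            raise ValueError(
                "mixed precision is not supported by the NumPy backend; "
                "training runs in full precision"
            )


def partition_parameters(
    model: FusionMLM, trainable_protein_layers: int = 4
) -> dict[str, list[tuple[str, Parameter]]]:
    """Split parameters into frozen / pretrained-trainable / new-trainable.

    Protein-encoder layers before the last ``trainable_protein_layers`` are
    frozen together with the protein embeddings; the last layers train at
    the pretrained rate if the encoder was loaded from a checkpoint, else
    at the new rate.  Everything on the reaction side, the pooling and
    projection layers, and the output head are newly initialized and train
    at the new rate.
    """
    encoder = model.protein_encoder
    n_layers = len(encoder.layers)
    if n_layers < trainable_protein_layers:
        raise ValueError(
            f"protein encoder has {n_layers} layers, fewer than "
            f"trainable_protein_layers={trainable_protein_layers}"
        )
    frozen_layers = encoder.layers[: n_layers - trainable_protein_layers]
    frozen_ids = set()
    for layer in frozen_layers:
        frozen_ids.update(id(p) for p in layer.parameters())
    if frozen_layers:
        # embeddings feed only frozen layers first; freeze them too
        for name, p in encoder.named_parameters():
            if "layers" not in name:
                frozen_ids.add(id(p))
    protein_ids = {id(p) for p in encoder.parameters()}

    groups: dict[str, list[tuple[str, Parameter]]] = {
        "frozen": [],
        "pretrained_trainable": [],
        "new_trainable": [],
    }
    for name, p in model.named_parameters():
        if id(p) in frozen_ids:
            groups["frozen"].append((name, p))
        elif id(p) in protein_ids and encoder.pretrained:
            groups["pretrained_trainable"].append((name, p))
        else:
            groups["new_trainable"].append((name, p))
    return groups


def clip_global_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class AdamW:
    """Decoupled-weight-decay Adam over named parameter groups.

    Weight decay is skipped for biases and normalization parameters
    (rank-0/1 tensors), following the usual convention.
    """

    def __init__(
        self,
        groups: list[tuple[list[tuple[str, Parameter]], float]],
        betas: tuple[float, float] = (0.9, 0.999),
        epsilon: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.groups = [(list(params), lr) for params, lr in groups]
        self.betas = betas
        self.epsilon = epsilon
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    @property
    def learning_rates(self) -> list[float]:
        return sorted({lr for _, lr in self.groups})

    def zero_grad(self):
        for params, _ in self.groups:
            for _, p in params:
                p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for params, lr in self.groups:
            for _, p in params:
                if p.grad is None:
                    continue
                m = self._m.setdefault(id(p), np.zeros_like(p.data))
                v = self._v.setdefault(id(p), np.zeros_like(p.data))
                m[:] = b1 * m + (1 - b1) * p.grad
                v[:] = b2 * v + (1 - b2) * p.grad**2
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p.data -= lr * mhat / (np.sqrt(vhat) + self.epsilon)
                if self.weight_decay and p.data.ndim > 1:
                    p.data -= lr * self.weight_decay * p.data


def make_optimizer(model: FusionMLM, config: TrainConfig) -> tuple[AdamW, dict]:
    groups = partition_parameters(model, config.trainable_protein_layers)
    optimizer = AdamW(
        [
            (groups["pretrained_trainable"], config.lr_pretrained),
            (groups["new_trainable"], config.lr_new),
        ],
        betas=config.betas,
        epsilon=config.epsilon,
        weight_decay=config.weight_decay,
    )
    return optimizer, groups


def _encode_batch(
    pairs: list[EnzymeReactionPair],
    vocab: TokenVocabulary,
    augment: bool,
    seed: int,
) -> tuple[list[str], np.ndarray]:
    sequences = [p.sequence for p in pairs]
    token_lists = []
    for i, p in enumerate(pairs):
        rxn = augment_reaction(p.reaction, seed + 7919 * i) if augment else p.reaction
        token_lists.append(tokenize(rxn.smiles).tokens)
    width = max(len(t) for t in token_lists) + 2
    ids = np.stack([np.array(encode(t, vocab, width)) for t in token_lists])
    return sequences, ids


def mlm_step_loss(
    model: FusionMLM,
    pairs: list[EnzymeReactionPair],
    vocab: TokenVocabulary,
    config: TrainConfig,
    seed: int,
    use_protein: bool = True,
    train: bool = True,
) -> float:
    """One accumulated step: forward/backward over micro-batches.

    Micro-batch losses are weighted by masked-token count so that the
    accumulated gradient equals the gradient of the pooled full batch.
    Returns the pooled mean masked cross-entropy.
    """
    micro = [
        pairs[i : i + config.micro_batch_size]
        for i in range(0, len(pairs), config.micro_batch_size)
    ]
    encoded: list[tuple[list[str], MaskedBatch]] = []
    total_masked = 0
    for j, chunk in enumerate(micro):
        seqs, ids = _encode_batch(chunk, vocab, config.augment and train, seed + 31 * j)
        mb = mask_tokens(
            ids, vocab, rate=config.mask_rate, seed=seed + 101 * j,
            scheme=config.mask_scheme,
        )
        if mb.n_masked == 0:
            continue
        encoded.append((seqs, mb))
        total_masked += mb.n_masked
    if total_masked == 0:
        raise ValueError("no maskable tokens in batch")
    pooled_loss = 0.0
    for seqs, mb in encoded:
        _, loss = model.forward_mlm(seqs, mb, use_protein=use_protein)
        weight = mb.n_masked / total_masked
        pooled_loss += float(loss.data) * weight
        if train:
            ag.backward(ag.mul(loss, weight))
    return pooled_loss


def evaluate_mlm(
    model: FusionMLM,
    pairs: list[EnzymeReactionPair],
    vocab: TokenVocabulary,
    config: TrainConfig,
    seed: int = 12345,
    use_protein: bool = True,
) -> dict[str, float]:
    """Deterministic masked-token loss and perplexity on held-out pairs."""
    loss = 0.0
    n_batches = 0
    batch = config.micro_batch_size * config.accumulation_steps
    eval_config = TrainConfig(
        **{**vars(config), "augment": False}
    )
    for i in range(0, len(pairs), batch):
        chunk = pairs[i : i + batch]
        loss += mlm_step_loss(
            model, chunk, vocab, eval_config, seed=seed + i,
            use_protein=use_protein, train=False,
        )
        n_batches += 1
    mean = loss / max(n_batches, 1)
    return {"loss": mean, "perplexity": float(np.exp(mean))}


@dataclass
class TrainResult:
    loss_trace: list[tuple[int, str, float]] = field(default_factory=list)
    best_val_loss: float = float("inf")
    best_state: dict | None = None
    final_state: dict | None = None


def train(
    model: FusionMLM,
    train_pairs: list[EnzymeReactionPair],
    vocab: TokenVocabulary,
    config: TrainConfig,
    val_pairs: list[EnzymeReactionPair] | None = None,
    use_protein: bool = True,
) -> TrainResult:
    """Run the optimization protocol; returns the loss trace and checkpoints.

    Each update draws ``accumulation_steps x micro_batch_size`` pairs
    (with replacement when the corpus is smaller), applies per-step
    augmentation and masking with step-derived seeds, clips the global
    gradient norm at ``clip_norm``, and takes one AdamW step with constant
    two-tier learning rates.  Aborts on a non-finite loss.
    """
    if not train_pairs:
        raise ValueError("training corpus is empty")
    optimizer, groups = make_optimizer(model, config)
    trainable = [p for _, p in groups["pretrained_trainable"] + groups["new_trainable"]]
    rng = np.random.default_rng(config.seed)
    batch = config.micro_batch_size * config.accumulation_steps
    result = TrainResult()
    for step in range(1, config.max_steps + 1):
        idx = rng.choice(len(train_pairs), size=min(batch, len(train_pairs)), replace=False) \
            if len(train_pairs) >= batch else rng.integers(0, len(train_pairs), size=batch)
        chunk = [train_pairs[int(i)] for i in idx]
        optimizer.zero_grad()
        step_seed = int(rng.integers(0, 2**31 - 1))
        loss = mlm_step_loss(
            model, chunk, vocab, config, seed=step_seed, use_protein=use_protein
        )
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at step {step}: loss={loss}")
        clip_global_norm(trainable, config.clip_norm)
        optimizer.step()
        result.loss_trace.append((step, "train", loss))
        if val_pairs and step % config.eval_every == 0:
            val = evaluate_mlm(
                model, val_pairs, vocab, config, use_protein=use_protein
            )["loss"]
            result.loss_trace.append((step, "validation", val))
            if val < result.best_val_loss:
                result.best_val_loss = val
                result.best_state = model.state_dict()
    result.final_state = model.state_dict()
    return result


def write_loss_trace(trace: list[tuple[int, str, float]], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "split", "loss"])
        writer.writerows(trace)
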