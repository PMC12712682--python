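"""Multi-encoder masked-language model over reaction SMILES.

Architecture: a protein encoder reads the amino-acid sequence and its
sequence-start ([CLS]) summary state is passed through a pooling layer
(dense + tanh) and a linear projection into the reaction hidden size.  A
BERT-style reaction encoder (2 layers, 4 heads, hidden 512, feed-forward
2048 at reference scale) embeds the tokenized reaction; the projected
protein vector is added uniformly to every reaction token's hidden state
(additive fusion, no new parameters), and two further self-attention
layers of the same width predict the masked reaction tokens through an
output head tied to the token embedding matrix.

Masking selects 30 % of non-special reaction tokens by default; selected
positions get the mask token with probability 0.8, a random vocabulary
token with 0.1 and are kept unchanged with 0.1 (an ``all_mask`` scheme is
available).  The loss is mean cross-entropy over masked positions only.

The shipped protein encoder is a small randomly initialized transformer
with the same interface a large pretrained encoder would expose (ordered
layer list, per-head attention maps, a summary position), so the full
pipeline runs at desk scale; real pretrained encoders plug in behind
:class:`ProteinEncoderInterface`.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import (
    LayerNorm,
    Linear,
    Module,
    Parameter,
    Tensor,
)
from .tokenizer import TokenVocabulary

IGNORE_INDEX = ag.IGNORE_INDEX

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FusionModelConfig:
    """Dimensions and rates of the fusion model.

    Reference values: hidden 512, 2 reaction layers, 4 heads, feed-forward
    2048, 2 post-fusion layers of the same width, 30 % masking.  Tests use
    a scaled-down copy of the same shape.
    """

    vocab_size: int
    reaction_hidden: int = 512
    reaction_layers: int = 2
    reaction_heads: int = 4
    reaction_ffn: int = 2048
    post_fusion_layers: int = 2
    protein_hidden: int = 32
    protein_layers: int = 4
    protein_heads: int = 2
    protein_ffn: int = 64
    max_reaction_positions: int = 448
    max_protein_positions: int = 1024
    mask_rate: float = 0.30
    mask_scheme: str = "bert"  # "bert" = 80/10/10, "all_mask" = always mask token

    def __post_init__(self):
        if self.reaction_hidden % self.reaction_heads:
            raise ValueError("reaction_hidden must be divisible by reaction_heads")
        if self.protein_hidden % self.protein_heads:
            raise ValueError("protein_hidden must be divisible by protein_heads")
        if not (0.0 < self.mask_rate < 1.0):
            raise ValueError("mask_rate must lie in (0, 1)")
        if self.mask_scheme not in ("bert", "all_mask"):
            raise ValueError("mask_scheme must be 'bert' or 'all_mask'")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FusionModelConfig":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# masking

@dataclass
class MaskedBatch:
    """Encoded reaction ids after masking.

    ``labels`` equals the original ids exactly at masked positions and the
    ignore marker elsewhere; ``mask_positions`` is the selection matrix;
    ``unmaskable`` flags sequences that had no maskable token and were
    returned unmasked.
    """

    input_ids: np.ndarray
    labels: np.ndarray
    attention_mask: np.ndarray
    mask_positions: np.ndarray
    unmaskable: np.ndarray

    @property
    def n_masked(self) -> int:
        return int(self.mask_positions.sum())


def mask_tokens(
    ids: np.ndarray,
    vocab: TokenVocabulary,
    rate: float = 0.30,
    seed: int = 0,
    scheme: str = "bert",
) -> MaskedBatch:
    """Apply MLM masking to a batch of encoded reactions.

    Each non-special position is selected independently with probability
    ``rate``.  Under the ``bert`` scheme a selected position becomes the
    mask token with probability 0.8, a uniform random non-special
    vocabulary token with 0.1, and stays unchanged with 0.1; ``all_mask``
    always writes the mask token.  Special tokens are never selected.
    """
    if not (0.0 < rate < 1.0):
        raise ValueError("rate must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.asarray(ids, dtype=np.int64)
    special = np.isin(ids, sorted(vocab.special_ids))
    maskable = ~special
    selected = maskable & (rng.random(ids.shape) < rate)

    unmaskable = ~maskable.any(axis=1)
    labels = np.full_like(ids, IGNORE_INDEX)
    labels[selected] = ids[selected]

    input_ids = ids.copy()
    if scheme == "all_mask":
        input_ids[selected] = vocab.mask_id
    else:
        roll = rng.random(ids.shape)
        to_mask = selected & (roll < 0.8)
        to_random = selected & (roll >= 0.8) & (roll < 0.9)
        input_ids[to_mask] = vocab.mask_id
        n_special = len(vocab.special_tokens)
        n_regular = len(vocab) - n_special
        if n_regular > 0 and to_random.any():
            input_ids[to_random] = rng.integers(
                n_special, len(vocab), size=int(to_random.sum())
            )
    attention_mask = (ids != vocab.pad_id).astype(np.float64)
    return MaskedBatch(
        input_ids=input_ids,
        labels=labels,
        attention_mask=attention_mask,
        mask_positions=selected,
        unmaskable=unmaskable,
    )


# ---------------------------------------------------------------------------
# transformer blocks

class MultiHeadSelfAttention(Module):
    def __init__(self, hidden: int, heads: int, rng: np.random.Generator):
        self.heads = heads
        self.head_dim = hidden // heads
        self.query = Linear(hidden, hidden, rng)
        self.key = Linear(hidden, hidden, rng)
        self.value = Linear(hidden, hidden, rng)
        self.output = Linear(hidden, hidden, rng)
        self.last_attention: np.ndarray | None = None
        self.record_attention = False

    def __call__(self, x: Tensor, attention_mask: np.ndarray) -> Tensor:
        b, t, h = x.shape
        def split(z):  # (B,T,H) -> (B,heads,T,head_dim)
            z = ag.reshape(z, (b, t, self.heads, self.head_dim))
            return ag.transpose(z, (0, 2, 1, 3))

        q, k, v = split(self.query(x)), split(self.key(x)), split(self.value(x))
        scores = ag.mul(
            ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))),
            1.0 / math.sqrt(self.head_dim),
        )
        # additive mask: 0 where attendable, -inf-ish where padding
        add_mask = (1.0 - attention_mask[:, None, None, :]) * -1e9
        probs = ag.softmax(scores, additive_mask=add_mask)
        if self.record_attention:
            self.last_attention = probs.data.copy()
        ctx = ag.matmul(probs, v)
        ctx = ag.reshape(ag.transpose(ctx, (0, 2, 1, 3)), (b, t, h))
        return self.output(ctx)


class TransformerLayer(Module):
    """Post-layer-norm transformer block (BERT convention)."""

    def __init__(self, hidden: int, heads: int, ffn: int, rng: np.random.Generator):
        self.attention = MultiHeadSelfAttention(hidden, heads, rng)
        self.ln1 = LayerNorm(hidden)
        self.ffn_in = Linear(hidden, ffn, rng)
        self.ffn_out = Linear(ffn, hidden, rng)
        self.ln2 = LayerNorm(hidden)

    def __call__(self, x: Tensor, attention_mask: np.ndarray) -> Tensor:
        x = self.ln1(ag.add(x, self.attention(x, attention_mask)))
        x = self.ln2(ag.add(x, self.ffn_out(ag.gelu(self.ffn_in(x)))))
        return x


# ---------------------------------------------------------------------------
# protein encoder

class ProteinEncoderInterface(Module):
    """What the fusion model needs from a protein encoder.

    Implementations expose ``tokenize`` (residues to ids with a summary
    [CLS] position first), ``__call__`` (ids, mask -> per-position hidden
    states), an ordered ``layers`` list for partial freezing, and per-head
    attention maps of the final layer via ``record_attention``.
    """

    hidden: int
    layers: list
    pretrained: bool = False

    def tokenize(self, sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def __call__(self, ids: np.ndarray, attention_mask: np.ndarray) -> Tensor:
        raise NotImplementedError


class TinyProteinEncoder(ProteinEncoderInterface):
    """A small transformer over amino-acid tokens with a [CLS] summary slot.

    Token ids: 0 pad, 1 cls, 2 eos, 3 unk, then the 20 standard residues.
    """

    PAD, CLS, EOS, UNK = 0, 1, 2, 3

    def __init__(
        self,
        hidden: int = 32,
        layers: int = 4,
        heads: int = 2,
        ffn: int = 64,
        max_positions: int = 1024,
        seed: int = 0,
        pretrained: bool = False,
    ):
        rng = np.random.default_rng(seed)
        self.hidden = hidden
        self.max_positions = max_positions
        self.pretrained = pretrained
        n_tokens = 4 + len(AA_ALPHABET)
        self.aa_to_id = {aa: 4 + i for i, aa in enumerate(AA_ALPHABET)}
        self.token_embedding = Parameter(rng.normal(0, 0.02, (n_tokens, hidden)))
        self.position_embedding = Parameter(rng.normal(0, 0.02, (max_positions, hidden)))
        self.embed_ln = LayerNorm(hidden)
        self.layers = [TransformerLayer(hidden, heads, ffn, rng) for _ in range(layers)]

    def tokenize(self, sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
        lengths = [len(s) + 2 for s in sequences]
        t = max(lengths)
        if t > self.max_positions:
            offender = max(sequences, key=len)
            raise ValueError(
                f"sequence of length {len(offender)} exceeds encoder limit "
                f"{self.max_positions - 2}"
            )
        ids = np.full((len(sequences), t), self.PAD, dtype=np.int64)
        for i, seq in enumerate(sequences):
            ids[i, 0] = self.CLS
            for j, aa in enumerate(seq):
                ids[i, j + 1] = self.aa_to_id.get(aa, self.UNK)
            ids[i, len(seq) + 1] = self.EOS
        mask = (ids != self.PAD).astype(np.float64)
        # pad id 0 == PAD is also CLS-safe: CLS/EOS are non-pad
        return ids, mask

    def __call__(self, ids: np.ndarray, attention_mask: np.ndarray) -> Tensor:
        t = ids.shape[1]
        x = ag.add(
            ag.embedding(ids, self.token_embedding),
            ag.embedding(np.arange(t), self.position_embedding),
        )
        x = self.embed_ln(x)
        for layer in self.layers:
            x = layer(x, attention_mask)
        return x

    def set_record_attention(self, flag: bool) -> None:
        for layer in self.layers:
            layer.attention.record_attention = flag

    def final_layer_attention(self) -> np.ndarray:
        """(B, heads, T, T) attention probabilities of the last layer."""
        att = self.layers[-1].attention.last_attention
        if att is None:
            raise RuntimeError("run a forward pass with record_attention first")
        return att


# ---------------------------------------------------------------------------
# fusion model

class FusionMLM(Module):
    """Protein-conditioned masked-language model over reaction tokens."""

    def __init__(
        self,
        config: FusionModelConfig,
        protein_encoder: ProteinEncoderInterface | None = None,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed + 1)
        self.config = config
        self.protein_encoder = protein_encoder or TinyProteinEncoder(
            hidden=config.protein_hidden,
            layers=config.protein_layers,
            heads=config.protein_heads,
            ffn=config.protein_ffn,
            max_positions=config.max_protein_positions,
            seed=seed,
        )
        if self.protein_encoder.hidden != config.protein_hidden:
            raise ValueError(
                f"protein encoder hidden size {self.protein_encoder.hidden} "
                f"!= config protein_hidden {config.protein_hidden}"
            )
        h = config.reaction_hidden
        self.token_embedding = Parameter(
            rng.normal(0, 0.02, (config.vocab_size, h))
        )
        self.position_embedding = Parameter(
            rng.normal(0, 0.02, (config.max_reaction_positions, h))
        )
        self.embed_ln = LayerNorm(h)
        self.reaction_layers = [
            TransformerLayer(h, config.reaction_heads, config.reaction_ffn, rng)
            for _ in range(config.reaction_layers)
        ]
        self.post_fusion_layers = [
            TransformerLayer(h, config.reaction_heads, config.reaction_ffn, rng)
            for _ in range(config.post_fusion_layers)
        ]
        # pooling (dense+tanh on the [CLS] state) then projection to H
        self.pooler = Linear(config.protein_hidden, config.protein_hidden, rng)
        self.projection = Linear(config.protein_hidden, h, rng)
        # prediction head tied to token embedding; free bias
        self.output_bias = Parameter(np.zeros(config.vocab_size))

    # -- pieces -----------------------------------------------------------
    def pool_protein(self, hidden_states: Tensor) -> Tensor:
        """[CLS] state -> dense+tanh pooling -> projection to reaction size."""
        if hidden_states.shape[-1] != self.config.protein_hidden:
            raise ValueError(
                f"hidden size {hidden_states.shape[-1]} does not match "
                f"config protein_hidden {self.config.protein_hidden}"
            )
        cls = ag.reshape(
            ag.matmul(
                ag.transpose(hidden_states, (0, 2, 1)),
                _one_hot_first(hidden_states.shape[1]),
            ),
            (hidden_states.shape[0], self.config.protein_hidden),
        )
        return self.projection(ag.tanh(self.pooler(cls)))

    def encode_protein(self, sequences: list[str]) -> Tensor:
        ids, mask = self.protein_encoder.tokenize(sequences)
        return self.pool_protein(self.protein_encoder(ids, mask))

    @staticmethod
    def fuse(reaction_hidden_states: Tensor, protein_vec: Tensor) -> Tensor:
        """Add the protein vector uniformly to every token position."""
        rh = reaction_hidden_states
        if rh.shape[-1] != protein_vec.shape[-1]:
            raise ValueError(
                f"hidden size mismatch: reaction {rh.shape[-1]} vs "
                f"protein {protein_vec.shape[-1]}"
            )
        return ag.add(rh, ag.reshape(protein_vec, (protein_vec.shape[0], 1, protein_vec.shape[-1])))

    def encode_reaction(self, input_ids: np.ndarray, attention_mask: np.ndarray) -> Tensor:
        t = input_ids.shape[1]
        if t > self.config.max_reaction_positions:
            raise ValueError("reaction batch longer than max_reaction_positions")
        x = ag.add(
            ag.embedding(input_ids, self.token_embedding),
            ag.embedding(np.arange(t), self.position_embedding),
        )
        x = self.embed_ln(x)
        for layer in self.reaction_layers:
            x = layer(x, attention_mask)
        return x

    def forward_mlm(
        self,
        sequences: list[str],
        batch: MaskedBatch,
        use_protein: bool = True,
    ) -> tuple[Tensor, Tensor]:
        """Full pipeline; returns (logits, mean masked cross-entropy loss).

        ``use_protein=False`` replaces the protein vector with zeros (the
        conditioning ablation); the rest of the network is unchanged.
        """
        x = self.encode_reaction(batch.input_ids, batch.attention_mask)
        if use_protein:
            pvec = self.encode_protein(sequences)
        else:
            pvec = Tensor(np.zeros((len(sequences), self.config.reaction_hidden)))
        x = self.fuse(x, pvec)
        for layer in self.post_fusion_layers:
            x = layer(x, batch.attention_mask)
        logits = ag.add(
            ag.matmul(x, ag.transpose(self.token_embedding, (1, 0))),
            self.output_bias,
        )
        loss = ag.cross_entropy_logits(logits, batch.labels)
        return logits, loss

    # -- persistence ------------------------------------------------------
    def save_checkpoint(self, directory: str | Path, vocab: TokenVocabulary) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(self.config.to_json())
        vocab.save(directory / "vocab.txt")
        np.savez(directory / "weights.npz", **self.state_dict())

    @classmethod
    def load_checkpoint(
        cls, directory: str | Path
    ) -> tuple["FusionMLM", TokenVocabulary]:
        directory = Path(directory)
        config = FusionModelConfig.from_json((directory / "config.json").read_text())
        vocab = TokenVocabulary.load(directory / "vocab.txt")
        model = cls(config)
        with np.load(directory / "weights.npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model, vocab


def _one_hot_first(t: int) -> np.ndarray:
    sel = np.zeros((t, 1))
    sel[0, 0] = 1.0
    return sel


def expected_uniform_loss(vocab_size: int) -> float:
    """Cross-entropy of a uniform predictor: ln(vocab size)."""
    return math.log(vocab_size)
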