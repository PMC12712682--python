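"""Reaction-SMILES tokenization and vocabulary construction.

Reactions are written as ``reactants>>products`` with molecules separated by
``.``.  Tokenization uses a fixed regular expression over SMILES syntax
(bracket atoms, two-letter halogens, ring-bond digits, bond symbols, the
reaction arrow); the matches partition the input string exactly, so joining
the tokens reproduces the source.  Vocabularies are built from a corpus with
a minimum-frequency cutoff (default 5): rarer tokens are dropped and encode
to the unknown token.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

# Two ambiguously typeset alternatives (a leading escaped space before "(" and
# ".") are read as plain "\(" and "\.".  Note "Br?"/"Cl?" precede the
# single-letter organic-subset atoms, so bare "B" and "C" match through them.
REACTION_TOKEN_PATTERN = (
    r"(\%\([0-9]{3}\)|\[[^\]]+]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\||\(|\)|\."
    r"|=|#|-|\+|\\|\/|:|~|@|\?|>>?|\*|\$|\%[0-9]{2}|[0-9])"
)
_TOKEN_RE = re.compile(REACTION_TOKEN_PATTERN)

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
START_TOKEN = "<s>"
END_TOKEN = "</s>"
MASK_TOKEN = "<mask>"
SPECIAL_TOKENS = (PAD_TOKEN, UNK_TOKEN, START_TOKEN, END_TOKEN, MASK_TOKEN)


class TokenizationError(ValueError):
    """A span of the input is not matched by the token pattern."""

    def __init__(self, source: str, position: int):
        self.position = position
        super().__init__(
            f"cannot tokenize {source!r}: unmatched character "
            f"{source[position]!r} at position {position}"
        )


class LengthError(ValueError):
    """Encoded sequence exceeds the configured maximum length."""

    def __init__(self, n_tokens: int, max_length: int):
        self.n_tokens = n_tokens
        super().__init__(
            f"{n_tokens} tokens exceed the encoding budget "
            f"(max_length={max_length}, 2 positions reserved for start/end)"
        )


@dataclass(frozen=True)
class TokenizedReaction:
    """Ordered regex tokens of one reaction SMILES plus the source text."""

    tokens: tuple[str, ...]
    source: str

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(reaction_smiles: str) -> TokenizedReaction:
    """Split a reaction SMILES into tokens.

    The matches are non-overlapping and contiguous; every character must be
    consumed, otherwise :class:`TokenizationError` points at the first
    offending position.
    """
    if reaction_smiles is None:
        raise TypeError("reaction_smiles must be text, not None")
    tokens: list[str] = []
    pos = 0
    for match in _TOKEN_RE.finditer(reaction_smiles):
        if match.start() != pos:
            raise TokenizationError(reaction_smiles, pos)
        tokens.append(match.group(0))
        pos = match.end()
    if pos != len(reaction_smiles):
        raise TokenizationError(reaction_smiles, pos)
    return TokenizedReaction(tokens=tuple(tokens), source=reaction_smiles)


@dataclass(frozen=True)
class TokenVocabulary:
    """Token-to-id map with fixed special tokens.

    Ids are contiguous from 0: the five special tokens first (pad, unk,
    start, end, mask), then corpus tokens in lexicographic order.  Every
    non-special token occurred at least ``min_frequency`` times in the
    building corpus.
    """

    token_to_id: dict[str, int]
    min_frequency: int = 5
    special_tokens: tuple[str, ...] = SPECIAL_TOKENS

    id_to_token: dict[int, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("token ids must be contiguous from 0")
        for i, tok in enumerate(self.special_tokens):
            if self.token_to_id.get(tok) != i:
                raise ValueError(f"special token {tok!r} must have id {i}")
        object.__setattr__(
            self, "id_to_token", {i: t for t, i in self.token_to_id.items()}
        )

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD_TOKEN]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK_TOKEN]

    @property
    def start_id(self) -> int:
        return self.token_to_id[START_TOKEN]

    @property
    def end_id(self) -> int:
        return self.token_to_id[END_TOKEN]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK_TOKEN]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(self.token_to_id[t] for t in self.special_tokens)

    def save(self, path: str | Path) -> None:
        """One token per line, line number = id; header records min_frequency."""
        lines = [f"# min_frequency={self.min_frequency}"]
        lines += [self.id_to_token[i] for i in range(len(self))]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocabulary":
        min_freq = 5
        lines = Path(path).read_text().splitlines()
        # only the first line may be a header ("#" alone is a valid token)
        if lines and lines[0].startswith("# min_frequency="):
            min_freq = int(lines[0].split("=", 1)[1])
            lines = lines[1:]
        tokens = list(lines)
        return cls(
            token_to_id={t: i for i, t in enumerate(tokens)},
            min_frequency=min_freq,
        )


def build_vocabulary(
    corpus: Iterable[TokenizedReaction | Sequence[str]],
    min_frequency: int = 5,
) -> TokenVocabulary:
    """Build a vocabulary from tokenized reactions.

    Tokens occurring fewer than ``min_frequency`` times are excluded and will
    encode to the unknown token.  An empty corpus yields the special tokens
    only.
    """
    if min_frequency < 1:
        raise ValueError("min_frequency must be >= 1")
    counts: Counter[str] = Counter()
    for item in corpus:
        tokens = item.tokens if isinstance(item, TokenizedReaction) else item
        counts.update(tokens)
    kept = sorted(
        t for t, c in counts.items()
        if c >= min_frequency and t not in SPECIAL_TOKENS
    )
    token_to_id = {t: i for i, t in enumerate(SPECIAL_TOKENS)}
    for t in kept:
        token_to_id[t] = len(token_to_id)
    return TokenVocabulary(token_to_id=token_to_id, min_frequency=min_frequency)


def encode(
    reaction: TokenizedReaction | Sequence[str],
    vocab: TokenVocabulary,
    max_length: int,
) -> list[int]:
    """Encode tokens as ``[start] ids [end]`` right-padded to ``max_length``.

    Out-of-vocabulary tokens map to the unknown id.  Sequences whose encoded
    length would exceed ``max_length`` are rejected with :class:`LengthError`
    rather than truncated, mirroring the dataset length filter.
    """
    if max_length < 2:
        raise ValueError("max_length must be >= 2 (start and end tokens)")
    tokens = reaction.tokens if isinstance(reaction, TokenizedReaction) else list(reaction)
    if len(tokens) + 2 > max_length:
        raise LengthError(len(tokens), max_length)
    ids = [vocab.start_id]
    ids += [vocab.token_to_id.get(t, vocab.unk_id) for t in tokens]
    ids.append(vocab.end_id)
    ids += [vocab.pad_id] * (max_length - len(ids))
    return ids


def decode(ids: Sequence[int], vocab: TokenVocabulary) -> str:
    """Concatenate the tokens of non-special ids (round trip for in-vocab input)."""
    specials = vocab.special_ids
    return "".join(vocab.id_to_token[i] for i in ids if i not in specials)
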