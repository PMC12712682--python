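"""Seeded synthetic enzyme-reaction corpora and training-time augmentations.

The generator emulates the structure of curated enzyme-reaction pair data:
families of related amino-acid sequences (a founder plus point-mutated
descendants) that share a small set of valid reaction SMILES, with a
family-level EC-like label.  Sequence lengths span the 11-1022 residue
range of real pair datasets; reactions are assembled from a fragment
grammar of small organic molecules and are chemically valid by
construction.

Two augmentations used during training are implemented here: rewriting
every molecule as a randomized (non-canonical) SMILES, and shuffling the
order of molecules within the reactant and product sides.  Neither changes
the chemistry: canonicalizing the output recovers the input molecules and
no molecule crosses the reaction arrow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolfiles

from .dataset import DirectedReaction, EnzymeReactionPair

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# small valid molecules used as reaction building blocks
_FRAGMENTS = (
    "CCO", "CC=O", "CC(=O)O", "OCC(O)CO", "c1ccccc1O", "c1ccccc1N",
    "CC(N)C(=O)O", "NC(=O)C", "O=C(O)c1ccccc1", "CNC", "CCOC(C)=O",
    "OC1CCCCC1", "CC(C)O", "N#CC", "OCc1ccccc1", "CC(=O)N",
    "O=S(=O)(O)O", "OP(=O)(O)O", "C1CCOC1", "ClCCCl", "BrCC(=O)O",
    "CSC", "OCC=O", "CC(O)C(=O)O", "Cc1ccc(O)cc1", "NCCO",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic corpus.

    ``mutation_rate`` is the per-residue substitution probability applied
    independently to each descendant of a family founder; 0.05 keeps family
    members well above typical clustering identity thresholds while making
    them non-identical.  Default sizes give a corpus large enough for
    vocabulary construction and smoke training while staying desk-scale.
    """

    n_families: int = 20
    sequences_per_family: int = 25
    length_range: tuple[int, int] = (11, 1022)
    reaction_templates_per_family: int = 2
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if not (11 <= lo <= hi <= 1022):
            raise ValueError("length_range must lie within [11, 1022]")
        if not (0 <= self.mutation_rate < 1):
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.n_families < 1 or self.sequences_per_family < 1:
            raise ValueError("need at least one family and one sequence per family")
        if self.reaction_templates_per_family < 1:
            raise ValueError("need at least one reaction template per family")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    chars = list(seq)
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        chars[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(chars)


def _random_reaction(rng: np.random.Generator, reaction_id: str) -> DirectedReaction:
    """Assemble a valid reaction whose two sides differ."""
    for _ in range(100):
        n_r = int(rng.integers(1, 4))
        n_p = int(rng.integers(1, 4))
        reactants = tuple(str(rng.choice(_FRAGMENTS)) for _ in range(n_r))
        products = tuple(str(rng.choice(_FRAGMENTS)) for _ in range(n_p))
        if sorted(reactants) != sorted(products):
            return DirectedReaction(reaction_id, reactants, products)
    raise RuntimeError("could not draw a non-degenerate reaction")


def generate_corpus(spec: SyntheticSpec) -> list[EnzymeReactionPair]:
    """Generate a family-structured corpus, deterministic given ``spec.seed``.

    Each family has one founder sequence, ``sequences_per_family - 1``
    mutated descendants, and ``reaction_templates_per_family`` reactions
    shared by all members; every member is paired with every family
    reaction.  The family id doubles as an EC-like label of the form
    ``f.<family>.0``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    pairs: list[EnzymeReactionPair] = []
    for fam in range(spec.n_families):
        length = int(rng.integers(lo, hi + 1))
        founder = _random_sequence(rng, length)
        reactions = [
            _random_reaction(rng, f"fam{fam}_rxn{j}")
            for j in range(spec.reaction_templates_per_family)
        ]
        label = f"f.{fam}.0"
        for s in range(spec.sequences_per_family):
            seq = founder if s == 0 else _mutate(rng, founder, spec.mutation_rate)
            for rxn in reactions:
                pairs.append(
                    EnzymeReactionPair(
                        sequence=seq,
                        reaction=rxn,
                        label_ec=label,
                        accession=f"F{fam:03d}S{s:03d}",
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# augmentations

def randomize_reaction_smiles(
    reaction: DirectedReaction, seed: int
) -> DirectedReaction:
    """Rewrite every molecule as an atom-order-randomized SMILES.

    Canonicalizing each output molecule recovers the same canonical form as
    the input molecule; side membership and the reaction arrow are
    untouched.  Unparsable molecules raise rather than being dropped.
    """
    rng = np.random.default_rng(seed)

    def _randomize(smi: str) -> str:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable molecule SMILES: {smi!r}")
        variants = rdmolfiles.MolToRandomSmilesVect(
            mol, 1, randomSeed=int(rng.integers(1, 2**31 - 1))
        )
        return variants[0]

    return DirectedReaction(
        reaction_id=reaction.reaction_id,
        reactants=tuple(_randomize(s) for s in reaction.reactants),
        products=tuple(_randomize(s) for s in reaction.products),
    )


def shuffle_sides(reaction: DirectedReaction, seed: int) -> DirectedReaction:
    """Permute molecule order within each side; nothing crosses the arrow."""
    rng = np.random.default_rng(seed)
    reactants = list(reaction.reactants)
    products = list(reaction.products)
    rng.shuffle(reactants)
    rng.shuffle(products)
    return DirectedReaction(
        reaction_id=reaction.reaction_id,
        reactants=tuple(reactants),
        products=tuple(products),
    )


def augment_reaction(
    reaction: DirectedReaction, seed: int, allow_side_swap: bool = False
) -> DirectedReaction:
    """Apply both augmentations (randomized writings, shuffled side order).

    ``allow_side_swap`` additionally swaps the whole reactant and product
    sides with probability 1/2; off by default because swapping changes
    the reaction direction.
    """
    out = shuffle_sides(randomize_reaction_smiles(reaction, seed), seed + 1)
    if allow_side_swap:
        rng = np.random.default_rng(seed + 2)
        if rng.random() < 0.5:
            out = out.reversed()
    return out
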