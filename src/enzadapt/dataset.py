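"""Enzyme sequence-reaction pair dataset construction.

Builds pair datasets from local snapshot tables: catalytic-activity records
referencing reaction identifiers, a directed-reaction lookup, and an
external direction database for reactions whose primary annotation carries
no direction.  Records that resolve to no directed reaction are excluded
with a reason code.  Admitted pairs are filtered on protein length
(<= 1022 residues), reaction token count (<= 446) and on degenerate
reactions whose reactant and product sides are identical.  Sequences are
clustered (80 % identity by default) and clusters are split as whole units
into train/validation/test at 90/5/5.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .tokenizer import TokenizationError, tokenize

RDLogger.DisableLog("rdApp.*")

MAX_PROTEIN_TOKENS = 1022
MAX_REACTION_TOKENS = 446
SPLIT_PROPORTIONS = (0.90, 0.05, 0.05)
SPLIT_NAMES = ("train", "validation", "test")


@dataclass(frozen=True)
class DirectedReaction:
    """A reaction with fixed direction: reactants >> products."""

    reaction_id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]

    def __post_init__(self):
        if not self.reactants or not self.products:
            raise ValueError("reactant and product lists must be non-empty")

    @property
    def smiles(self) -> str:
        return ".".join(self.reactants) + ">>" + ".".join(self.products)

    @classmethod
    def from_smiles(cls, reaction_id: str, smiles: str) -> "DirectedReaction":
        try:
            lhs, rhs = smiles.split(">>")
        except ValueError as exc:
            raise ValueError(f"not a reaction SMILES: {smiles!r}") from exc
        return cls(
            reaction_id=reaction_id,
            reactants=tuple(lhs.split(".")),
            products=tuple(rhs.split(".")),
        )

    def reversed(self) -> "DirectedReaction":
        return DirectedReaction(
            reaction_id=self.reaction_id,
            reactants=self.products,
            products=self.reactants,
        )


@dataclass(frozen=True)
class CatalyticActivityRecord:
    """One catalytic-activity annotation of a protein entry.

    ``sequence_ref`` selects which sequence the annotation applies to:
    ``("canonical",)``, ``("isoform", iso_id)`` or ``("chain", a, b)`` with a
    1-based inclusive residue interval on the canonical sequence.
    """

    accession: str
    sequence_ref: tuple = ("canonical",)
    reaction_ids: tuple[str, ...] = ()
    physiological_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class EnzymeReactionPair:
    sequence: str
    reaction: DirectedReaction
    label_ec: str | None = None
    accession: str | None = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")


def resolve_direction(
    record: CatalyticActivityRecord,
    directed_lookup: Mapping[str, DirectedReaction],
    direction_db: Mapping[str, str],
) -> list[DirectedReaction]:
    """Resolve a record's annotations to directed reactions.

    Physiological identifiers are already directed and resolve directly
    (``id`` forward, ``id:rev`` reversed).  Otherwise the primary identifier
    is resolved through ``direction_db`` mapping reaction id to
    ``"forward"``, ``"reverse"`` or ``"bidirectional"``; a bidirectional
    reaction yields two directed reactions.  Identifiers resolvable by
    neither path yield nothing (the record is excluded upstream).
    """
    resolved: list[DirectedReaction] = []
    if record.physiological_ids:
        for rid in record.physiological_ids:
            reverse = rid.endswith(":rev")
            base = rid[:-4] if reverse else rid
            rxn = directed_lookup.get(base)
            if rxn is None:
                continue
            resolved.append(rxn.reversed() if reverse else rxn)
        return resolved
    for rid in record.reaction_ids:
        rxn = directed_lookup.get(rid)
        if rxn is None:
            continue
        direction = direction_db.get(rid)
        if direction == "forward":
            resolved.append(rxn)
        elif direction == "reverse":
            resolved.append(rxn.reversed())
        elif direction == "bidirectional":
            resolved.append(rxn)
            resolved.append(rxn.reversed())
        # unknown direction: excluded
    return resolved


def select_sequence(
    record: CatalyticActivityRecord,
    canonical: str,
    isoforms: Mapping[str, str] | None = None,
) -> str:
    """Pick the sequence an annotation applies to.

    Non-canonical references win over the canonical sequence: isoform
    references resolve through ``isoforms``; chain references extract the
    annotated 1-based inclusive residue interval from the canonical
    sequence.
    """
    kind = record.sequence_ref[0]
    if kind == "canonical":
        return canonical
    if kind == "isoform":
        iso_id = record.sequence_ref[1]
        if isoforms is None or iso_id not in isoforms:
            raise KeyError(f"isoform {iso_id!r} not found for {record.accession}")
        return isoforms[iso_id]
    if kind == "chain":
        a, b = record.sequence_ref[1], record.sequence_ref[2]
        if not (1 <= a <= b <= len(canonical)):
            raise ValueError(
                f"chain range ({a}, {b}) out of bounds for "
                f"{record.accession} (length {len(canonical)})"
            )
        return canonical[a - 1 : b]
    raise ValueError(f"unknown sequence_ref kind {kind!r}")


def _canonical_side(molecules: Sequence[str]) -> tuple[str, ...] | None:
    """Sorted multiset of canonical molecule SMILES (stereochemistry kept)."""
    out = []
    for smi in molecules:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            return None
        out.append(Chem.MolToSmiles(mol))
    return tuple(sorted(out))


def filter_pair(
    pair: EnzymeReactionPair,
    max_protein_tokens: int = MAX_PROTEIN_TOKENS,
    max_reaction_tokens: int = MAX_REACTION_TOKENS,
) -> str | None:
    """Return a rejection reason, or None if the pair is admitted.

    Reasons: ``protein_length`` (> 1022 residues), ``reaction_length``
    (> 446 reaction tokens), ``parse`` (untokenizable or chemically
    unparsable reaction), ``identity`` (reactant and product sides are the
    same multiset of canonical molecules; chirality inversion keeps the
    sides distinct because stereochemistry is encoded in the SMILES).
    """
    if len(pair.sequence) > max_protein_tokens:
        return "protein_length"
    try:
        tok = tokenize(pair.reaction.smiles)
    except TokenizationError:
        return "parse"
    if len(tok) > max_reaction_tokens:
        return "reaction_length"
    lhs = _canonical_side(pair.reaction.reactants)
    rhs = _canonical_side(pair.reaction.products)
    if lhs is None or rhs is None:
        return "parse"
    if lhs == rhs:
        return "identity"
    return None


def filter_pairs(
    pairs: Iterable[EnzymeReactionPair],
    max_protein_tokens: int = MAX_PROTEIN_TOKENS,
    max_reaction_tokens: int = MAX_REACTION_TOKENS,
) -> tuple[list[EnzymeReactionPair], Counter]:
    """Apply :func:`filter_pair` to a collection; admitted pairs + reason tally."""
    admitted: list[EnzymeReactionPair] = []
    reasons: Counter = Counter()
    for pair in pairs:
        reason = filter_pair(pair, max_protein_tokens, max_reaction_tokens)
        if reason is None:
            admitted.append(pair)
        else:
            reasons[reason] += 1
    return admitted, reasons


# ---------------------------------------------------------------------------
# sequence clustering (built-in fallback for external identity clustering)

def _kmers(seq: str, k: int) -> set[str]:
    if len(seq) < k:
        return {seq}
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_sequences(
    sequences: Sequence[str],
    identity: float = 0.8,
    k: int = 5,
) -> dict[str, int]:
    """Greedy star clustering on k-mer containment identity.

    Sequences are visited longest-first; each joins the first existing
    cluster whose representative shares at least ``identity`` of the shorter
    sequence's k-mers, else founds a new cluster.  A coarse stand-in for
    external identity-clustering tools; identical sequences always share a
    cluster.
    """
    order = sorted(set(sequences), key=lambda s: (-len(s), s))
    reps: list[tuple[str, set[str]]] = []
    assignment: dict[str, int] = {}
    for seq in order:
        mers = _kmers(seq, k)
        for cid, (rep, rep_mers) in enumerate(reps):
            denom = min(len(mers), len(rep_mers))
            if denom and len(mers & rep_mers) / denom >= identity:
                assignment[seq] = cid
                break
        else:
            assignment[seq] = len(reps)
            reps.append((seq, mers))
    return assignment


@dataclass
class SplitAssignment:
    """Cluster-level train/validation/test assignment."""

    cluster_of: dict[str, int]
    split_of_cluster: dict[int, str]
    proportions: tuple[float, float, float] = SPLIT_PROPORTIONS

    def split_of(self, sequence: str) -> str:
        return self.split_of_cluster[self.cluster_of[sequence]]

    def counts(self, pairs: Sequence[EnzymeReactionPair]) -> Counter:
        return Counter(self.split_of(p.sequence) for p in pairs)


def split_by_cluster(
    pairs: Sequence[EnzymeReactionPair],
    clusters: Mapping[str, int],
    proportions: tuple[float, float, float] = SPLIT_PROPORTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole clusters to train/validation/test.

    Clusters are shuffled by ``seed`` and assigned greedily: each goes to the
    split whose pair-count deficit against its target proportion is largest,
    so no cluster ever spans splits and realized proportions approach the
    targets as the number of clusters grows.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    for p in pairs:
        if p.sequence not in clusters:
            raise KeyError(f"no cluster id for sequence of {p.accession or p.sequence[:12]}")
    sizes: Counter = Counter(clusters[p.sequence] for p in pairs)
    cluster_ids = sorted(sizes)
    rng = random.Random(seed)
    rng.shuffle(cluster_ids)
    total = sum(sizes.values())
    filled = {name: 0 for name in SPLIT_NAMES}
    split_of_cluster: dict[int, str] = {}
    for cid in cluster_ids:
        # deficit of each split against its final target, in pairs
        name = max(
            SPLIT_NAMES,
            key=lambda s: proportions[SPLIT_NAMES.index(s)] * total - filled[s],
        )
        split_of_cluster[cid] = name
        filled[name] += sizes[cid]
    # clusters with no pairs still get a split (stable for lookups)
    for seq, cid in clusters.items():
        split_of_cluster.setdefault(cid, "train")
    return SplitAssignment(
        cluster_of=dict(clusters),
        split_of_cluster=split_of_cluster,
        proportions=proportions,
    )


# ---------------------------------------------------------------------------
# table I/O

PAIRS_COLUMNS = ["accession", "sequence", "reaction_smiles", "ec", "split"]


def write_pairs_table(
    pairs: Sequence[EnzymeReactionPair],
    path: str | Path,
    assignment: SplitAssignment | None = None,
) -> None:
    rows = []
    for i, p in enumerate(pairs):
        rows.append(
            {
                "accession": p.accession or f"SYN{i:06d}",
                "sequence": p.sequence,
                "reaction_smiles": p.reaction.smiles,
                "ec": p.label_ec or "",
                "split": assignment.split_of(p.sequence) if assignment else "",
            }
        )
    pd.DataFrame(rows, columns=PAIRS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(PAIRS_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    return df


def pairs_from_table(df: pd.DataFrame) -> list[EnzymeReactionPair]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EnzymeReactionPair(
                sequence=row.sequence,
                reaction=DirectedReaction.from_smiles(
                    getattr(row, "accession", "r"), row.reaction_smiles
                ),
                label_ec=(getattr(row, "ec", "") or None),
                accession=getattr(row, "accession", None),
            )
        )
    return out


def read_cluster_table(path: str | Path) -> dict[str, int]:
    """TSV of sequence-id (or sequence) to cluster-id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    key_col, cid_col = df.columns[:2]
    return {row[key_col]: int(row[cid_col]) for _, row in df.iterrows()}
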