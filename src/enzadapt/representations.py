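"""Adapted protein representations and EC-label clustering diagnostics.

After domain adaptation the protein encoder is used on its own: a sequence
maps either to its sequence-start ([CLS]) summary state or to the mean of
its final-layer residue states (special positions excluded).  Agreement
between the embedding space and enzyme-function labels is quantified with
three standard clustering metrics over EC level-3 classes: Davies-Bouldin
index (lower is better), Calinski-Harabasz index (higher is better), and
the mean per-cluster silhouette score (silhouettes averaged within each
class, then averaged over classes, unweighted).  Classes with fewer than
three members and unlabeled entries are dropped before scoring.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_samples,
)

from .model import FusionMLM, ProteinEncoderInterface


@dataclass
class RepresentationMatrix:
    ids: list[str]
    vectors: np.ndarray  # (n, d)
    pooling_mode: str

    def __post_init__(self):
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("one vector per id required")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.vectors)
        df.insert(0, "id", self.ids)
        return df

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path, pooling_mode: str = "unknown") -> "RepresentationMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(
            ids=df["id"].astype(str).tolist(),
            vectors=df.drop(columns=["id"]).to_numpy(dtype=float),
            pooling_mode=pooling_mode,
        )


def embed(
    sequences: dict[str, str] | list[tuple[str, str]],
    encoder: ProteinEncoderInterface | FusionMLM,
    pooling_mode: str = "summary",
    batch_size: int = 16,
    normalize: bool = False,
) -> RepresentationMatrix:
    """Embed sequences with the (adapted) protein encoder.

    ``summary`` returns the final-layer [CLS] state; ``mean`` averages the
    final-layer residue states, excluding the summary and end special
    positions and padding.  Deterministic: the encoder runs in evaluation
    mode with no randomness.
    """
    if pooling_mode not in ("summary", "mean"):
        raise ValueError("pooling_mode must be 'summary' or 'mean'")
    if isinstance(encoder, FusionMLM):
        encoder = encoder.protein_encoder
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    ids = [i for i, _ in items]
    vectors = []
    for start in range(0, len(items), batch_size):
        chunk = [s for _, s in items[start : start + batch_size]]
        tok_ids, mask = encoder.tokenize(chunk)
        hidden = encoder(tok_ids, mask).data
        if pooling_mode == "summary":
            vectors.append(hidden[:, 0, :])
        else:
            for row, seq in zip(range(hidden.shape[0]), chunk):
                states = hidden[row, 1 : 1 + len(seq), :]
                vectors.append(states.mean(axis=0, keepdims=True))
    matrix = np.concatenate(vectors, axis=0)
    if normalize:
        norms = np.linalg.norm(matrix, axis=1, keepdims=True)
        matrix = matrix / np.where(norms == 0, 1.0, norms)
    return RepresentationMatrix(ids=ids, vectors=matrix, pooling_mode=pooling_mode)


def ec_level(label: str, level: int = 3) -> str:
    """Truncate an EC-like dotted label to its first ``level`` fields."""
    return ".".join(label.split(".")[:level])


def filter_label_classes(
    labels: dict[str, str | None],
    level: int = 3,
    min_members: int = 3,
) -> dict[str, str]:
    """Keep labeled entries whose level-``level`` class has >= min_members.

    Unlabeled entries (None or empty) are dropped first; classes are formed
    by truncating labels to the requested EC level.
    """
    truncated = {
        k: ec_level(v, level) for k, v in labels.items() if v
    }
    counts = Counter(truncated.values())
    return {k: v for k, v in truncated.items() if counts[v] >= min_members}


def mean_per_cluster_silhouette(vectors: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted mean over clusters of within-cluster mean silhouettes."""
    samples = silhouette_samples(vectors, labels, metric="euclidean")
    return float(
        np.mean([samples[labels == c].mean() for c in np.unique(labels)])
    )


def clustering_metrics(
    matrix: RepresentationMatrix, labels: dict[str, str]
) -> dict[str, float]:
    """Davies-Bouldin, Calinski-Harabasz and mean per-cluster silhouette.

    Euclidean distance throughout.  Requires at least two classes with at
    least two members each after filtering.
    """
    keep = [i for i, sid in enumerate(matrix.ids) if sid in labels]
    x = matrix.vectors[keep]
    y = np.array([labels[matrix.ids[i]] for i in keep])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two label classes for clustering metrics")
    if counts.min() < 2:
        raise ValueError("every class needs at least two members (silhouette)")
    return {
        "davies_bouldin": float(davies_bouldin_score(x, y)),
        "calinski_harabasz": float(calinski_harabasz_score(x, y)),
        "mean_per_cluster_silhouette": mean_per_cluster_silhouette(x, y),
    }
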