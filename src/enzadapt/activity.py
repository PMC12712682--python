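"""Family-wide enzyme-substrate activity prediction.

Rows of (enzyme, substrate, binary activity) are featurized as the
concatenation of an enzyme representation vector and a Morgan fingerprint
of the substrate (radius 2, 1024 bits).  Evaluation follows nested
cross-validation in the enzyme-discovery scenario: outer folds partition
enzymes (never rows), the inner split is random, hyperparameters are
searched on the inner folds, the top-k configurations by mean inner
validation PR-AUC are retrained on all inner data and ensembled by
averaging predicted probabilities, and the ensemble is scored on the outer
test fold.  The whole procedure is repeated with distinct seeds.

PR-AUC is the area under the precision-recall step curve pooled over all
rows (not per sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from . import autograd as ag
from .autograd import Linear, Module, Tensor


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Circular-substructure fingerprint as a 0/1 vector."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable substrate SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=float)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def pr_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall step curve over all points.

    Computed as sum over descending-score thresholds of
    (recall_i - recall_{i-1}) * precision_i, grouping tied scores at one
    threshold.  Requires both classes present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("PR-AUC undefined with a single class")
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    tp = np.cumsum(y)
    n_pred = np.arange(1, len(y) + 1)
    # threshold boundaries: last index of each tied-score block
    boundary = np.r_[s[1:] != s[:-1], True]
    precision = tp[boundary] / n_pred[boundary]
    recall = tp[boundary] / tp[-1]
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


@dataclass
class ActivityDataset:
    enzyme_ids: list[str]
    substrate_ids: list[str]
    labels: np.ndarray
    enzyme_features: dict[str, np.ndarray]
    substrate_features: dict[str, np.ndarray]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not set(self.labels) <= {0, 1}:
            raise ValueError("labels must be binary")
        for eid in self.enzyme_ids:
            if eid not in self.enzyme_features:
                raise KeyError(f"no enzyme features for {eid!r}")
        for sid in self.substrate_ids:
            if sid not in self.substrate_features:
                raise KeyError(f"no substrate features for {sid!r}")

    def __len__(self):
        return len(self.labels)

    def features(self, rows: np.ndarray | None = None) -> np.ndarray:
        idx = np.arange(len(self)) if rows is None else np.asarray(rows)
        return np.stack(
            [
                np.concatenate(
                    [
                        self.enzyme_features[self.enzyme_ids[i]],
                        self.substrate_features[self.substrate_ids[i]],
                    ]
                )
                for i in idx
            ]
        )

    @classmethod
    def from_rows(
        cls,
        rows: list[tuple[str, str, int]],
        enzyme_features: dict[str, np.ndarray],
        substrate_smiles: dict[str, str] | None = None,
        substrate_features: dict[str, np.ndarray] | None = None,
    ) -> "ActivityDataset":
        if substrate_features is None:
            substrate_features = {
                sid: morgan_fingerprint(smi) for sid, smi in (substrate_smiles or {}).items()
            }
        return cls(
            enzyme_ids=[r[0] for r in rows],
            substrate_ids=[r[1] for r in rows],
            labels=np.array([r[2] for r in rows]),
            enzyme_features=enzyme_features,
            substrate_features=substrate_features,
        )


def enzyme_discovery_split(
    enzyme_ids: Sequence[str], n_folds: int, seed: int
) -> np.ndarray:
    """Fold index per row, grouping by enzyme (all rows of an enzyme share a fold).

    Enzymes are shuffled and dealt round-robin, so fold sizes differ by at
    most one enzyme.
    """
    unique = sorted(set(enzyme_ids))
    if len(unique) < n_folds:
        raise ValueError(f"{len(unique)} enzymes cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = list(unique)
    rng.shuffle(order)
    fold_of_enzyme = {e: i % n_folds for i, e in enumerate(order)}
    return np.array([fold_of_enzyme[e] for e in enzyme_ids])


# ---------------------------------------------------------------------------
# the feed-forward classifier

@dataclass
class MLPConfig:
    hidden_layers: int = 1
    hidden_dim: int = 64
    learning_rate: float = 1e-3
    dropout: float = 0.0
    weight_decay: float = 1e-3
    max_steps: int = 2000
    batch_size: int = 64
    eval_every: int = 50

    def __post_init__(self):
        if self.hidden_layers not in (1, 2):
            raise ValueError("hidden_layers must be 1 or 2")
        if not (0.0 <= self.dropout <= 0.5):
            raise ValueError("dropout out of range")


class MLPClassifier(Module):
    """1-2 hidden-layer ReLU network with dropout, trained with AdamW on BCE.

    When a validation set is given, the parameters with the best validation
    PR-AUC (checked every ``eval_every`` steps) are restored after training.
    """

    def __init__(self, n_features: int, config: MLPConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        dims = [n_features] + [config.hidden_dim] * config.hidden_layers + [1]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims, dims[1:])]
        self._rng = rng

    def logits(self, x: np.ndarray, training: bool = False) -> Tensor:
        h: Tensor = Tensor(x)
        for layer in self.layers[:-1]:
            h = ag.relu(layer(h))
            h = ag.dropout(h, self.config.dropout, self._rng, training)
        return ag.reshape(self.layers[-1](h), (x.shape[0],))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits(x, training=False).data))

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "MLPClassifier":
        cfg = self.config
        params = self.parameters()
        m = {id(p): np.zeros_like(p.data) for p in params}
        v = {id(p): np.zeros_like(p.data) for p in params}
        best_score, best_state = -np.inf, None
        t = 0
        for step in range(1, cfg.max_steps + 1):
            idx = self._rng.integers(0, len(x), size=min(cfg.batch_size, len(x)))
            loss = ag.binary_cross_entropy_logits(
                self.logits(x[idx], training=True), y[idx]
            )
            for p in params:
                p.zero_grad()
            ag.backward(loss)
            t += 1
            for p in params:
                if p.grad is None:
                    continue
                m[id(p)] = 0.9 * m[id(p)] + 0.1 * p.grad
                v[id(p)] = 0.999 * v[id(p)] + 0.001 * p.grad**2
                mhat = m[id(p)] / (1 - 0.9**t)
                vhat = v[id(p)] / (1 - 0.999**t)
                p.data -= cfg.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
                if p.data.ndim > 1:
                    p.data -= cfg.learning_rate * cfg.weight_decay * p.data
            if x_val is not None and step % cfg.eval_every == 0:
                try:
                    score = pr_auc(y_val, self.predict_proba(x_val))
                except ValueError:
                    score = 0.0
                if score > best_score:
                    best_score = score
                    best_state = self.state_dict()
        if best_state is not None:
            self.load_state_dict(best_state)
        return self


ModelFactory = Callable[[int, MLPConfig, int], MLPClassifier]


def default_model_factory(n_features: int, config: MLPConfig, seed: int) -> MLPClassifier:
    return MLPClassifier(n_features, config, seed=seed)


# ---------------------------------------------------------------------------
# hyperparameter search space and nested CV

@dataclass
class NestedCVConfig:
    outer_folds: int = 4
    inner_folds: int = 3
    top_k: int = 5
    repeats: int = 10
    trials: int = 50
    hidden_dims: tuple[int, ...] = tuple(range(16, 193, 16))
    lr_range: tuple[float, float] = (1e-4, 2e-2)
    dropout_range: tuple[float, float] = (0.0, 0.2)
    weight_decay_range: tuple[float, float] = (1e-4, 1e-2)
    max_steps: int = 2000
    batch_size: int = 64
    eval_every: int = 50

    def __post_init__(self):
        if self.top_k > self.trials:
            raise ValueError("top_k cannot exceed trials")

    def sample(self, rng: np.random.Generator) -> MLPConfig:
        lo, hi = self.lr_range
        return MLPConfig(
            hidden_layers=int(rng.integers(1, 3)),
            hidden_dim=int(rng.choice(self.hidden_dims)),
            learning_rate=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            dropout=float(rng.uniform(*self.dropout_range)),
            weight_decay=float(
                np.exp(rng.uniform(*np.log(self.weight_decay_range)))
            ),
            max_steps=self.max_steps,
            batch_size=self.batch_size,
            eval_every=self.eval_every,
        )


@dataclass
class NestedCVResult:
    fold_scores: list[float]
    repeat_scores: list[float]
    fold_audit: list[dict] = field(default_factory=list)

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.repeat_scores))


def _run_one_repeat(
    dataset: ActivityDataset,
    config: NestedCVConfig,
    factory: ModelFactory,
    seed: int,
    audit: list[dict],
) -> list[float]:
    rng = np.random.default_rng(seed)
    x_all = dataset.features()
    y_all = dataset.labels
    folds = enzyme_discovery_split(
        dataset.enzyme_ids, config.outer_folds, seed=int(rng.integers(2**31 - 1))
    )
    fold_scores = []
    for fold in range(config.outer_folds):
        test_rows = np.flatnonzero(folds == fold)
        train_rows = np.flatnonzero(folds != fold)
        audit.append(
            {
                "seed": seed,
                "fold": fold,
                "test_enzymes": {dataset.enzyme_ids[i] for i in test_rows},
                "train_enzymes": {dataset.enzyme_ids[i] for i in train_rows},
            }
        )
        # inner random (row-level) partition of the outer-train rows
        inner_assign = rng.integers(0, config.inner_folds, size=len(train_rows))
        trial_configs = [config.sample(rng) for _ in range(config.trials)]
        trial_scores = []
        for cfg in trial_configs:
            inner_scores = []
            for inner in range(config.inner_folds):
                tr = train_rows[inner_assign != inner]
                va = train_rows[inner_assign == inner]
                if len(va) == 0 or len(set(y_all[va])) < 2:
                    continue
                model = factory(x_all.shape[1], cfg, int(rng.integers(2**31 - 1)))
                model.fit(x_all[tr], y_all[tr], x_all[va], y_all[va])
                inner_scores.append(pr_auc(y_all[va], model.predict_proba(x_all[va])))
            trial_scores.append(np.mean(inner_scores) if inner_scores else -np.inf)
        top = np.argsort(-np.asarray(trial_scores), kind="stable")[: config.top_k]
        # retrain the top-k configurations on all inner data, ensemble by mean
        member_preds = []
        for trial_index in top:
            model = factory(
                x_all.shape[1], trial_configs[trial_index], int(rng.integers(2**31 - 1))
            )
            model.fit(x_all[train_rows], y_all[train_rows])
            member_preds.append(model.predict_proba(x_all[test_rows]))
        ensemble = np.mean(member_preds, axis=0)
        fold_scores.append(pr_auc(y_all[test_rows], ensemble))
    return fold_scores


def nested_cv(
    dataset: ActivityDataset,
    config: NestedCVConfig,
    factory: ModelFactory = default_model_factory,
    seed: int = 0,
) -> NestedCVResult:
    """Repeated nested cross-validation in the enzyme-discovery scenario.

    Returns per-fold and per-repeat outer-test PR-AUC scores plus an audit
    trail of train/test enzyme sets for every outer fold (for leakage
    checks).
    """
    audit: list[dict] = []
    all_fold_scores: list[float] = []
    repeat_scores: list[float] = []
    for rep in range(config.repeats):
        scores = _run_one_repeat(dataset, config, factory, seed + 1000 * rep, audit)
        all_fold_scores.extend(scores)
        repeat_scores.append(float(np.mean(scores)))
    return NestedCVResult(
        fold_scores=all_fold_scores, repeat_scores=repeat_scores, fold_audit=audit
    )
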