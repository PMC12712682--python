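# enzadapt

Self-supervised domain adaptation of enzyme sequence encoders from
**positive enzyme–reaction pairs only**.

Public biochemical databases almost exclusively record enzyme activities
that *worked*; negative examples are rare and quantitative kinetics rarer
still. Methods that manufacture synthetic negatives by recombining
enzymes and substrates risk labeling merely-unobserved activities as
inactive. `enzadapt` takes the alternative route: adapt a pretrained
protein sequence encoder with a self-supervised objective that needs
positives only, then reuse the adapted representations for downstream
enzyme tasks (function-aware clustering, binding-site inspection,
activity classification).

## The model

A multi-encoder masked-language model over reaction SMILES
(`reactants>>products`):

```
protein sequence ──▶ protein encoder ──▶ [CLS] state ──▶ pool (dense+tanh) ──▶ project
                                                                                  │
reaction tokens ──▶ reaction encoder (2 layers) ──▶ h_t  ──▶  h_t + p  (∀t) ──▶ 2 post-fusion
   (30 % masked)                                                                layers ──▶ masked-token logits
```

The pooled protein vector **p** is added uniformly to every reaction
token's hidden state — no cross-attention, no extra parameters — so the
only way the model can beat an unconditional reaction language model is
by concentrating reaction-relevant information into the protein
representation. Training uses AdamW (β₁ = 0.9, β₂ = 0.999, ε = 1e-8,
weight decay 0.01), constant two-tier learning rates (5e-5 pretrained /
2e-4 new parameters), gradient clipping at 1.0, gradient accumulation,
partial freezing (last four protein layers train), and two
label-preserving augmentations of each reaction (randomized SMILES
writings; shuffled molecule order within each side).

The package also implements the surrounding machinery: the reaction
tokenizer (fixed regex, minimum-frequency-5 vocabulary), the
dataset-construction rules (reaction direction resolution,
isoform/chain sequence selection, 1022-residue and 446-token filters,
identity-reaction exclusion, cluster-aware 90/5/5 splitting), a seeded
synthetic corpus generator with family structure, and three evaluation
procedures: EC level-3 clustering diagnostics (Davies-Bouldin,
Calinski-Harabasz, mean per-cluster silhouette), attention-based
binding-site scoring (overlap score and segment-level false positive
rate under a matched residue budget), and nested-CV enzyme–substrate
activity prediction with top-k ensembling and pooled PR-AUC.

Everything runs on CPU: the transformer stack and its training loop are
implemented on a small float64 reverse-mode autodiff engine included in
the package, and the shipped protein encoder is a compact transformer
with the same interface a large pretrained encoder would expose (real
checkpoints plug in behind `ProteinEncoderInterface`).

## Worked example

Train the fusion MLM on a synthetic corpus whose reaction is a
deterministic function of the enzyme family, then inspect the adapted
embeddings:

```python
import numpy as np
import enzadapt as ez
from enzadapt.training import TrainConfig

spec = ez.SyntheticSpec(n_families=8, sequences_per_family=12,
                        length_range=(20, 50),
                        reaction_templates_per_family=1,
                        mutation_rate=0.05, seed=11)
pairs = ez.generate_corpus(spec)
vocab = ez.build_vocabulary(
    [ez.tokenize(p.reaction.smiles) for p in pairs], min_frequency=1)

cfg = ez.FusionModelConfig(vocab_size=len(vocab), reaction_hidden=32,
                           reaction_heads=2, reaction_ffn=64,
                           protein_hidden=32, protein_layers=2, protein_ffn=64,
                           max_reaction_positions=128, max_protein_positions=128)
model = ez.FusionMLM(cfg, seed=0)
tc = TrainConfig(micro_batch_size=16, max_steps=400, augment=False,
                 trainable_protein_layers=2, seed=1)
result = ez.train(model, pairs[:80], vocab, tc)
ev = ez.evaluate_mlm(model, pairs[80:], vocab, tc)

seqs = {p.accession: p.sequence for p in pairs}
labels = ez.filter_label_classes({p.accession: p.label_ec for p in pairs})
matrix = ez.embed(seqs, model, pooling_mode="summary")
print(ez.clustering_metrics(matrix, labels))
```

Output:

```
96 pairs, vocabulary of 19 tokens, ln|V| = 2.944
train loss: step 1 = 2.955, step 400 = 1.532
held-out masked-token perplexity = 8.251
clustering vs family labels: {'davies_bouldin': 0.225,
 'calinski_harabasz': 1607.957, 'mean_per_cluster_silhouette': 0.845}
```

The training loss starts at ln|V| (a fresh model predicts uniformly) and
halves as the model learns family-specific reactions; the adapted
summary embeddings cluster tightly by family (silhouette 0.85 versus
0.64 for the untrained encoder), showing the MLM objective routed enzyme
identity through the pooled protein vector.

A CLI mirrors the library (`enzadapt simulate`, `build-vocab`,
`build-dataset`, `train`, `embed`, `eval-cluster`, `eval-binding`,
`eval-activity`); see `enzadapt --help`.

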