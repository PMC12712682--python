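# Methods

`enzadapt` implements self-supervised domain adaptation of a protein
sequence encoder trained solely on positive enzyme–reaction pairs, plus
the evaluation procedures used to probe the adapted representations.
This note documents the model, the data rules, the numerical choices, and
what the synthetic corpora do and do not establish.

## The model

The training objective is masked language modeling (MLM) over reaction
SMILES, conditioned on the enzyme sequence. The architecture has two
encoders with no token-level cross-attention between them:

1. **Protein encoder.** A transformer over amino-acid tokens with a
   sequence-start summary position ([CLS]). The reference design plugs in
   a large pretrained protein language model (per-residue hidden size
   1280); the package ships a small randomly initialized transformer with
   the identical interface (ordered layer list for partial freezing,
   per-head attention maps, summary position) so the full pipeline runs
   on a single CPU. The final [CLS] hidden state is passed through a
   pooling layer (dense + tanh) and a linear projection into the reaction
   hidden size.
2. **Reaction encoder.** A BERT-style transformer over reaction-SMILES
   tokens: 2 layers, 4 attention heads, hidden size 512, feed-forward
   2048 at reference scale, learned absolute position embeddings,
   post-layer-norm blocks with tanh-approximation GELU.
3. **Additive fusion.** The projected protein vector is added uniformly
   to the hidden state of every reaction token. Fusion introduces no
   parameters; padding positions receive the offset too but are excluded
   downstream by the attention mask.
4. **Post-fusion layers.** Two further self-attention layers of the same
   width, followed by a prediction head whose weight matrix is tied to
   the reaction token embedding (with a free bias). Tying is a design
   choice the architecture description leaves open; it reduces parameters
   with no observed cost at this scale.

**Masking.** 30 % of non-special reaction tokens are selected per
sequence (the commonly used 15 % is deliberately doubled: reactant and
product sides are similar, so harder corruption is needed for a useful
signal). Selected positions receive the mask token with probability 0.8,
a uniform random vocabulary token with 0.1, and stay unchanged with 0.1;
an `all_mask` scheme is available. The loss is mean cross-entropy over
selected positions only; the ignore marker is an out-of-vocabulary
sentinel (−100), never a real token id.

**Tokenization.** Reaction SMILES are split by a fixed regular
expression over SMILES syntax (bracket atoms, two-letter halogens before
single-letter atoms — so bare `B`/`C` match through the `Br?`/`Cl?`
alternatives — ring-closure digits and `%nn`/`%(nnn)` forms, bond and
stereo symbols, the `>>` arrow). Two alternatives are ambiguously typeset
in the source of the expression (a leading escaped space before `(` and
`.`); they are read as plain `\(` and `\.`, which is the only reading
under which the matches partition real reaction SMILES. The vocabulary
keeps tokens occurring at least 5 times in the building corpus; rarer
tokens encode to the unknown id. Ids are deterministic: five special
tokens first (pad, unk, start, end, mask), then corpus tokens in
lexicographic order. Byte-pair encoding is intentionally not used.

## Optimization protocol

AdamW with β₁ = 0.9, β₂ = 0.999, ε = 1e-8, decoupled weight decay 0.01
(applied to matrices only, not biases or layer-norm parameters), global
gradient-norm clipping at 1.0, no warm-up, no schedule. Two constant
learning rates: 5e-5 for parameters loaded from a pretrained checkpoint,
2e-4 for newly initialized parameters. The pooling and projection layers
are randomly initialized and therefore train at the new-parameter rate.
Only the last four protein-encoder layers train by default; earlier
layers and the protein embeddings are frozen. An encoder with exactly
four layers has nothing frozen; fewer layers than the trainable count is
an error.

Gradient accumulation pools micro-batches before each update. Because
the loss is a mean over masked positions, each micro-batch loss is
weighted by its masked-token count over the pool's total, which makes the
accumulated gradient exactly equal to the full-batch gradient (the
engine is float64 throughout, so this holds to round-off and training
traces are bit-reproducible given a seed). A mixed-precision flag exists
for interface parity but the NumPy backend runs full precision only and
rejects it.

Batch size, step budget and stopping are not dictated by the method;
defaults are an effective batch of 8–32 via accumulation, a fixed step
budget, and best-checkpoint selection by validation MLM loss.

**Augmentation.** Two label-preserving rewrites are applied on the fly
with step-derived seeds, so every step sees fresh writings: (i) each
molecule is rewritten as an atom-order-randomized SMILES (canonicalizing
recovers the input molecule), and (ii) the order of molecules is shuffled
within each side. Shuffling never moves a molecule across the reaction
arrow: swapping whole sides would reverse the reaction direction, which
the dataset rules go out of their way to fix; an `allow_side_swap` flag
exists but defaults off. Whether augmentation is best applied per epoch
or once at preprocessing is an open choice; per-step application was
chosen as the stronger regularizer.

## Dataset construction rules

Pairs are built from local snapshot tables, never live downloads.
Direction resolution: identifiers from the physiological-reaction field
are already directed and used as-is; primary identifiers resolve through
an external direction table (forward / reverse / bidirectional);
bidirectional reactions become two independent directed reactions;
unresolvable records are excluded with a reason code. Sequence
selection: annotations on isoforms or processed chains use those
sequences (chains are 1-based inclusive ranges on the canonical
sequence). Filters: proteins longer than 1022 residues and reactions
longer than 446 tokens are excluded (both bounds inclusive on the keep
side), as are reactions whose two sides are the same multiset of
canonicalized molecule SMILES — stereochemistry retained, so
chirality-inverting reactions stay in.

Splitting is cluster-aware: sequences are clustered at 80 % identity and
clusters are assigned as whole units to train/validation/test at
90/5/5. The assignment is greedy by pair count — each shuffled cluster
goes to the split with the largest remaining deficit — because the
original procedure does not state its balancing rule; balancing by pair
count rather than cluster count keeps realized pair proportions closest
to the targets. The built-in clustering is greedy star clustering on
k-mer (k = 5) containment identity, a coarse stand-in adequate for
grouping near-identical sequences; tables derived from external identity
clustering tools are accepted as TSV.

## Synthetic corpora

The generator emulates the structure of curated enzyme–reaction data:
families of related sequences (founder plus descendants with independent
per-residue substitutions, default rate 0.05) sharing a small set of
valid reactions assembled from a fragment grammar of ~25 small organic
molecules; the family id doubles as an EC-like label. Sequence lengths
are drawn uniformly from a configurable range within [11, 1022], the
span of real pair datasets. Everything is deterministic given the spec
seed.

What the synthetic corpora do **not** emulate: real evolutionary
divergence (substitutions are uniform and independent), chemical realism
of reactions (fragment recombination, not mechanism), the long-tailed
family-size and EC-class imbalance of curated data, and any genuine
sequence–function coupling beyond the family→reaction assignment.
Passing tests therefore demonstrate that the machinery is correct and
that the objective can route protein information into reaction
prediction — not that desk-scale training yields biologically meaningful
representations.

## Evaluation procedures

**Clustering diagnostics.** Embeddings (summary-state or mean-over-
residues pooling; both provided since the adapted representation can be
read out either way) are scored against EC level-3 labels with the
Davies-Bouldin index, Calinski-Harabasz index, and the mean per-cluster
silhouette — silhouettes averaged within each class, then unweighted
across classes. Euclidean distance throughout; vectors are not length-
normalized by default (flag available). Unlabeled entries and classes
with fewer than three members are dropped first.

**Binding-site scoring.** Final-layer attention from the [CLS] position
to residue positions, per head. For each annotated pair the budget
highest-attention residues are selected (ties toward the smaller index;
the tie rule is unstated in the original procedure) and merged into
maximal contiguous segments. Overlap score = summed pairwise segment
intersection / total annotated length; false positive rate = fraction of
predicted residues in segments intersecting no annotated segment, with
the indicator applied per predicted segment. The denominator of the
overlap score is read as the annotated total length (the quantity is "the
fraction of annotated residues recovered"), resolving an index
inconsistency in the printed formula. Budgets are supplied per pair in
the annotation file, matching an external reference predictor's output
sizes. A `width1` mode scores each residue as its own segment, making the
false positive rate exactly residue-level. Intervals are 0-based
half-open internally; annotation files are 1-based inclusive.

**Activity prediction.** Rows of (enzyme, substrate, active?) are
featurized as enzyme representation ⊕ Morgan fingerprint (radius 2,
1024 bits). Nested cross-validation with 4 outer folds grouped by enzyme
(the enzyme-discovery scenario: all rows of an enzyme share a fold) and
3 random inner folds; random hyperparameter search (hidden layers 1–2,
width 16–192 step 16, log-uniform learning rate in [1e-4, 2e-2], dropout
in [0, 0.2], log-uniform weight decay in [1e-4, 1e-2]); the top-5
configurations by mean inner validation PR-AUC are retrained on all
inner data and ensembled by averaging predicted probabilities — the
aggregation rule is a package choice, the original text says only
"ensemble". PR-AUC is the area under the precision–recall step curve
pooled over all rows. The classifier trains up to 2000 steps with
validation every 50 steps and keeps the best-validation parameters.

## Problem sizes used in tests and the acceptance script

Desk-scale configurations chosen as the package's own defaults for
CPU execution: reaction/protein hidden size 32, 2 + 2 reaction layers,
2-layer tiny protein encoder; smoke training on a 500-pair corpus
(25 families × 10 sequences × 2 reactions) for 200 steps; the
conditioning ablation on an 8-family corpus with one reaction per family
(96 pairs, 80 train) for 400 steps, comparing masked-token perplexity
with the protein vector live versus zeroed, and comparing family-label
clustering of the adapted versus untrained encoder; nested CV on a
20-enzyme × 6-substrate linearly separable synthetic screen with a
reduced search (3 trials, top-2, 2 inner folds).

## Known limitations

- The shipped protein encoder is small and randomly initialized; absolute
  benchmark numbers obtained with large pretrained encoders on curated
  databases are out of reach by design, and no such numbers are claimed.
- The built-in k-mer clustering is a coarse proxy for alignment-based
  identity clustering; at 5 % family mutation rates, family members can
  fall below the 80 % 5-mer containment bar and split into subclusters
  (families still never merge).
- The fragment-grammar reactions are chemically valid but not
  thermodynamically or mechanistically plausible.
- The hyperparameter search is pure random search behind a pluggable
  interface; Bayesian phases of the original protocol are configuration,
  not correctness.
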