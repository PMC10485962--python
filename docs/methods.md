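# Methods

## Model

### Molecular encoder

A SMILES string is parsed (RDKit) into its heavy-atom graph; hydrogens
are implicit.  Atom features follow the DeepChem/GraphDTA convention —
one-hot atom symbol over a fixed 44-symbol list with an "other" slot,
one-hot degree 0–10, one-hot total hydrogen count 0–10, one-hot implicit
valence 0–10, and an aromaticity flag — 78 binary features per atom, a
layout that is frozen and hashed into every checkpoint so weights are
never restored onto a different featurizer.

Node features are linearly projected to `hidden_dim` and passed through L
GIN layers.  Each layer computes `MLP((1+ε)·x_i + Σ_{j∈N(i)} x_j)` with a
two-stage affine–ReLU–affine MLP of width `hidden_dim`, followed by batch
normalization and ReLU.  ε is fixed at 0 by default with a learnable
option.  The L per-node layer outputs are combined by a learnable kernel
of length L — one scalar per layer, shared across channels, initialized
to 1/L — so shallow (local) and deep (more global) neighbourhood
information both reach the final node matrix.  The raw input features are
not part of this stack: their width differs from `hidden_dim`, so the
kernel spans the L post-projection layer outputs.  The graph embedding is
the column-wise sum over nodes (global add pooling); additivity of this
readout is what makes the soft-partition algebra below exact.

Defaults: L = 4 layers, `hidden_dim` 128.  Batch normalization uses batch
statistics during training (updating running estimates with momentum 0.1)
and frozen running statistics at inference, so single-graph inference is
independent of batch composition.

### Soft subgraph partition

For T rounds, every current soft subgraph is split in two: a learnable
projection W (one per active branch per round) maps the node matrix to
two logits per node, and a row-wise softmax gives branch probabilities;
a child's node mask is the parent mask times its branch column.  With
zero projections the split is the unbiased 0.5/0.5 prior.  After T rounds
there are S = 2^T masks which, by the telescoping of row-stochastic
factors, sum to one per node; consequently the S mask-weighted additive
readouts sum exactly to the full-graph embedding (verified to 1e-5 in the
tests, observed at machine precision).  Masks stay soft so gradients flow
through the partition; a hard 0.5-threshold variant exists for inspection
only.  Default T = 1 (S = 2), configurable; T = 2 is exercised in tests.

### Contrastive objectives

Two levels are scored by separate bilinear discriminators
`T(x, y) = xᵀΩy` (separate because they compare different embedding
kinds) and combined with the Jensen–Shannon mutual-information estimator

    I = mean_pos[−sp(−T(x,y))] − mean_neg[sp(T(x,y′))],  sp(x) = log(1+eˣ).

Positive pairs are drawn from the joint (same-graph) distribution and
negatives from products of marginals within the minibatch.  The published
description of this estimator swaps the P/Q labels relative to the
standard form in one place; this implementation uses the standard
reading — positives get −sp(−t), negatives −sp(t) — which is the only
sign assignment under which maximizing the objective aligns same-graph
pairs.  Each estimate is ≤ 0 and approaches 0 only as positive scores
diverge to +∞ and negative scores to −∞.

* **Subgraph level.**  h(G) with each of its own S subgraph embeddings as
  positives (all S, averaged), and the subgraphs of the other graphs in
  the batch as negatives.
* **Graph level.**  For each graph, every subgraph embedding's maximum
  cosine similarity against the subgraph embeddings of *other* batch
  graphs is found; the ⌈S/2⌉ slots with the highest cross-batch
  similarity are replaced by their best-matching foreign embedding
  (highest-similarity substitution keeps the reconstruction semantically
  close to the original, which the positive-pair construction requires;
  a donor is never the graph itself).  The S slots are aggregated by a
  learnable length-S kernel — distinct from the layer-aggregation
  kernel — into h(Ĝ).  h(G) with its own h(Ĝ) is the positive pair,
  other graphs' reconstructions the negatives.

The training loss is the negated sum of the enabled MI terms (either can
be disabled for ablations), minimized with Adam (lr 1e-3), batch size 32.
Batch-normalization statistics update per batch during pre-training.
Donor selection operates on detached values (it is a discrete choice);
gradients flow through the selected embeddings.

### Protein encoder

Sequences are normalized to a 25-letter alphabet (20 standard residues
plus B, Z, U, O, with X as the unknown symbol — a superset of any
published residue list, so nothing is silently dropped) and tokenized
into overlapping n-grams, stride 1, at n = 2, 3, 4.  Tokens are
positional base-25 codes; the full vocabulary is kept for n = 2 (625) and
n = 3 (15,625), while n = 4 codes are reduced modulo 16,384 hash buckets
(the full 25⁴ ≈ 390k table would give near-singleton word frequencies at
any realistic corpus size; with random sequences the expected bucket
collision rate for a single protein is ≈ L/16384, under 2% at L = 300).
Each scale owns an embedding table (standard-normal initialization) and
one BiLSTM (H = 64 per direction by default, forget-gate bias 1);
per-step forward/backward states are concatenated and max-pooled over
time with padded positions masked out of both the recurrence updates and
the pool, so a sequence's representation is independent of the padding
needed to batch it.  The three pooled vectors are concatenated in order
n = 2, 3, 4 (output 3·2H).  Tokens are truncated at 1,200 per scale.

### Prediction head and training

Drug and protein embeddings are concatenated and passed through
affine(1024) → ReLU → dropout 0.2 → affine(512) → ReLU → dropout 0.2 →
affine(1).  Training minimizes MSE with Adam (lr 5e-4, batch 128 by
default); the output bias is initialized to the training-label mean so
early epochs fit structure rather than scale.  When a pre-trained
encoder checkpoint is given it initializes the molecular branch and all
parameters remain trainable (no freezing).  Within a minibatch each
unique drug and each unique protein is encoded once and shared by every
pair that uses it, which changes nothing mathematically (gradients
accumulate through both uses) and dominates the speedup on dense
drug × protein designs.

### Metrics

* MSE in double precision, index-ascending summation.
* CI over all pairs with strictly ordered true values (Z counts exactly
  those pairs; true-value ties contribute nothing), step function h = 1 /
  0.5 / 0 for positive / tied / negative prediction differences.  The
  published normalization text is ambiguous between "all pairs" and
  "comparable pairs"; comparable pairs is used, matching the summation
  domain.
* r_m² = r²·(1 − √|r² − r₀²|) with the QSAR through-origin convention
  k = Σ(y·ŷ)/Σ(ŷ²), r₀² = 1 − Σ(y − k·ŷ)²/Σ(y − ȳ)²; the absolute value
  guards r₀² > r²; both components are reported so either convention can
  be audited.
* Case-study percentiles: a rank r of N is inside a c% cutoff when
  round(100·r/N) ≤ c, rounding half away from zero — the only convention
  consistent with counting rank 74/1781 (4.15%) inside 4% and rank
  224/1781 (12.58%) inside 13%.

## Numerical core

No deep-learning framework is used.  The package includes a small
reverse-mode autodiff engine over dense float64 NumPy arrays (matmul,
elementwise transcendentals, reductions, indexing with scatter-add
gradients, concatenation/stacking, broadcasting with gradient
un-broadcasting) plus Adam with standard bias correction.  Max reductions
route gradient to the first argmax.  Softplus uses `logaddexp` and
sigmoids clip inputs at ±500 to avoid overflow.  All ops are
deterministic on a single thread, so fixed seeds give bit-identical
histories; gradient correctness is tested against central finite
differences.

## Synthetic study

The fixture generator emulates a dense drug × target affinity panel at
desk scale.  Drugs come from a ~30-piece template grammar (alkane/ether/
amine chains, benzene/pyridine/cyclohexane/piperidine/THF cores with
halogen, hydroxyl, amine and alkyl substituents, and biaryl methanes),
guaranteeing chemical parseability without a chemistry dependency inside
the generator.  Proteins are uniform random sequences over the 20
standard residues, 50–120 residues long, with the 5-mer motif HKLMW
planted in a seeded ~half of them.  The planted affinity is

    y = 5 + 1.0 · (# aromatic rings in the drug) + 1.0 · motif(protein) + N(0, 0.3)

and the generating function is returned with the table so tests can
recompute labels exactly.  Default panel: 200 drugs × 20 proteins (4,000
pairs), split 80/20 by pair.

What this emulates: a learnable structure–activity signal carried by a
graph substructure count and a sequence motif, with measurement noise.
What it does not: real binding physics, activity cliffs, scaffold-level
generalization (duplicated templates mean test drugs resemble training
drugs), realistic affinity distributions, or benchmark-scale protein
diversity.  Passing the synthetic checks demonstrates that the machinery
optimizes, conserves and generalizes in-distribution — not benchmark
performance; published benchmark numbers require full training on the
external Davis/KIBA sets, whose loaders are provided but whose training
runs are out of desk scope.

## Desk-scale study conditions

Chosen once as the package's own conditions for tests and
`scripts/acceptance.py` (full-size defaults above remain the config
defaults): encoder `hidden_dim` 32, L = 4, T = 1; protein embedding 32,
H = 16; head (128, 64); pre-training 20 epochs on 200 fixture molecules,
batch 32; fine-tuning 5 epochs, batch 128, lr 5e-4.  The five-seed
pre-training-versus-scratch ablation uses 10 pre-training epochs, 3
fine-tuning epochs and a 1,600/400 pair subset per seed.  Unit tests of
the optimization loop use 12-wide encoders, 8–16-residue proteins,
dropout 0 and lr 2e-2 so convergence checks run in seconds.

## Known limitations

* Dense adjacency and dense autodiff limit graphs to the small-molecule
  regime (hundreds of atoms) and batches to a few thousand nodes.
* The n = 4 hashing admits token collisions by construction; collision
  effects are measured only indirectly (distinct-index tests at n = 2, 3).
* `rank_candidates` breaks prediction ties by input order; ranks are
  ordinal, not averaged.
* The engine is single-threaded NumPy; wall-clock cost grows quickly with
  sequence length (the BiLSTM loop dominates), which is why desk-scale
  protein panels keep sequences ≤ ~120 residues.
* Stochastic checks (pre-training progress, ablation direction) are
  majority-over-seeds properties, not guarantees for every seed.
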