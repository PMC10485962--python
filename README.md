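# submdta

Drug–target binding-affinity (DTA) regression for small molecules and
protein kinase-style targets, built around two ideas:

1. **Substructure-contrastive pre-training of the molecular encoder.**
   SMILES strings are parsed into heavy-atom graphs and encoded with a
   Graph Isomorphism Network (GIN), whose layer update is
   `x_i' = MLP((1 + ε)·x_i + Σ_{j∈N(i)} x_j)` followed by batch
   normalization and ReLU, with a learnable length-L kernel combining the
   L layer outputs per node and global add pooling producing the graph
   embedding h(G).  Before any labels are seen, the encoder is pre-trained
   on an unlabeled SMILES corpus: each graph is softly split into S = 2^T
   subgraphs through row-stochastic assignment matrices
   `A = softmax(X·W)`, and a *reconstructed* graph h(Ĝ) is assembled by
   replacing the ⌈S/2⌉ most cross-batch-similar subgraph embeddings with
   their best-matching counterparts from other graphs in the batch.  Two
   Jensen–Shannon mutual-information terms are maximized with bilinear
   discriminators — h(G) against its own subgraphs, and h(G) against its
   reconstruction — using
   `I = E_pos[−sp(−T(x,y))] − E_neg[sp(T(x,y′))]`, `sp(x) = log(1+eˣ)`.
2. **Multi-scale n-gram BiLSTM protein encoding.**  Sequences are
   tokenized into overlapping 2-, 3- and 4-grams over a 25-letter amino
   acid alphabet, each scale embedded and run through its own BiLSTM;
   per-step forward/backward states are concatenated, max-pooled over
   time, and the three scales concatenated.

The drug and protein embeddings are concatenated into a two-hidden-layer
ReLU head that regresses the affinity (pK_d = −log₁₀(K_d/10⁹) for
Davis-style data, KIBA score otherwise), trained with MSE.  Evaluation
reports MSE, the concordance index CI (step-function form with half
credit for prediction ties, normalized by the number Z of strictly
ordered true pairs) and r_m² = r²·(1 − √|r² − r₀²|).

Everything runs on plain NumPy: the trainable components are expressed on
a small reverse-mode autodiff engine included in the package, so there is
no deep-learning-framework dependency.

## Worked example

The package ships a seeded synthetic-study generator: template-grammar
SMILES (chains, rings, substituted aromatics) and random protein
sequences with a planted sequence motif, with affinity
`5 + 1.0·(aromatic rings in drug) + 1.0·(motif present) + N(0, 0.3)`.

```python
from submdta import (FixtureSpec, PretrainConfig, DtaConfig,
                     generate_synthetic_dta, generate_fixture_molecules,
                     pretrain, fit, split_records, evaluate_model)

corpus = generate_fixture_molecules(200, seed=0)
encoder, history = pretrain(corpus, PretrainConfig(hidden_dim=32, epochs=20, seed=0))
print(f"pre-training loss: {history[0]:.2f} -> {history[-1]:.2f}")

spec = FixtureSpec(n_molecules=200, n_proteins=20, seed=0, noise_sd=0.3)
records, truth = generate_synthetic_dta(spec)
train, test = split_records(records, test_fraction=0.2, seed=0)
config = DtaConfig(hidden_dim=32, embed_dim=32, protein_hidden=16,
                   head_dims=(128, 64), epochs=5, seed=0)
model, _ = fit(train, config, pretrained=encoder)
report = evaluate_model(model, test)
print(f"test MSE {report.mse:.3f}  CI {report.ci:.3f}  rm2 {report.rm2:.3f}  (n={report.n})")
```

prints

```
pre-training loss: 66.39 -> 2.19
test MSE 0.180  CI 0.849  rm2 0.798  (n=800)
```

The contrastive loss (negated mutual information) falls as the
discriminators learn to tell a graph's own subgraphs from foreign ones,
and the fine-tuned regressor explains most of the held-out affinity
variance (the label noise floor is 0.09 MSE; a mean predictor scores
about 1.0), ordering ~85% of comparable test pairs correctly.

The same workflow is available from the shell:

```bash
submdta gen-fixtures --n-molecules 200 --n-proteins 20 --seed 0 --out-dir fix/
submdta pretrain --smiles fix/drugs.smi --epochs 20 --hidden-dim 32 --seed 0 --out encoder
submdta train --data fix/dta.csv --pretrained encoder --seed 0 --out model
submdta evaluate --model model --data fix/dta.csv --report report.json
submdta predict --model model --sequence MKVLHTRWQACDEFHKLMW --drugs fix/drugs.smi --out ranks.csv
```

Labelled tables use the GraphDTA CSV convention
(`compound_iso_smiles,target_sequence,affinity`); `--raw-kd` applies the
pK_d transform on load for tables holding raw nanomolar dissociation
constants.  Davis/KIBA-style benchmark files in this convention load
unchanged.

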