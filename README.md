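# powerdta

Regression of continuous drug–target binding affinity (DTA) from a drug's
SMILES string and a target protein's amino-acid sequence. Accurate affinity
prediction — pKd for Davis-style kinase panels, KIBA scores for integrated
bioactivity data — is a screening primitive in early drug discovery and drug
repurposing, where it replaces slow and expensive wet-lab binding assays for
candidate ranking.

## Model

**Drug encoder.** A SMILES is parsed (RDKit) into a heavy-atom graph with a
binary adjacency *A* and an *N×C* atom-feature matrix *X* (one-hot element
symbol, degree, total hydrogens, implicit valence, aromaticity; *C* = 78).
To capture multi-hop topology, the encoder works on the *graph powers*
*A*, *A²*, *A³*, where *Aᵏ* joins two atoms iff their shortest-path distance
is ≤ *k*. Each power is normalized as

&nbsp;&nbsp;&nbsp;&nbsp;*Â = D^(−1/2) (Aᵏ + I) D^(−1/2)*

and fed to its own stack of graph-convolution layers

&nbsp;&nbsp;&nbsp;&nbsp;*H⁽ⁱ⁾ = σ(Â H⁽ⁱ⁻¹⁾ W⁽ⁱ⁻¹⁾)*

— three layers on *A*, two on *A²*, one on *A³*, all reading the raw node
features in parallel. Global max pooling over atoms and concatenation give
the drug vector.

**Protein encoder.** The sequence is cut/zero-padded to length 1000 and split
into overlapping 3-grams ("biological words", at most 20³ distinct). Each
word maps to a dense vector from a skip-gram (word2vec) dictionary — trainable
on any corpus, or loadable from word2vec text format — giving a 998×*d*
matrix that a 3-layer 1-D CNN plus global max pooling reduces to a protein
vector. A residue-level one-hot encoder is available as an ablation switch.

**Fusion.** The two vectors are concatenated and passed through three fully
connected layers (dropout 0.2 after the first two) to a single real affinity.
Training minimizes MSE with Adam under five-fold cross-validation
(defaults: 500 epochs, batch 512, learning rate 5e-4). Evaluation uses MSE
and the concordance index CI = (1/Z) Σ_{yᵢ>yⱼ} h(pᵢ − pⱼ) with the step
function h scoring ties 0.5.

The network, including backpropagation, is implemented directly over NumPy
with a small reverse-mode tape (`powerdta._autodiff`).

## Worked example

Train a reduced network on a synthetic planted-signal dataset (500 pairs;
labels are a known descriptor function plus Gaussian noise, so the
mean-predictor baseline equals the label variance):

```python
from powerdta import (SyntheticSpec, generate_dataset, TrainingConfig,
                      make_cv_splits, train_model)

dataset = generate_dataset(SyntheticSpec(seed=0))   # 500 drug-target pairs
config = TrainingConfig(epochs=30, protein_max_len=200, batch_size=64,
                        learning_rate=1e-3, embedding_dim=16,
                        block_dims={1: (16, 32, 64), 2: (32, 64), 3: (64,)},
                        protein_conv_filters=(16, 16, 16),
                        protein_kernel_sizes=(8, 8, 8), fusion_dims=(64, 32),
                        folds_to_run=(0,), seed=0)
split = make_cv_splits(dataset, k=5, seed=0)
model, result = train_model(dataset, config, split)
report = result.fold_results[0].report
print(f"validation MSE {report.mse:.3f}  (label variance {dataset.affinities.var():.3f})")
print(f"validation CI  {report.ci:.3f}")
```

Output:

```
validation MSE 0.463  (label variance 1.099)
validation CI  0.794
```

The held-out MSE is well below the label-variance baseline and the
concordance index is far above the 0.5 of random ranking, approaching the
descriptor oracle's ≈ 0.91 ceiling at this noise level.

A `powerdta` command-line tool wraps the same library: `synth` (generate a
labelled table), `featurize` (SMILES → normalized graph tensors),
`train`, `evaluate` and `predict`. Benchmark tables (flat CSV of
⟨compound SMILES, target sequence, affinity⟩) load via
`load_dataset(path, fmt=...)`; Davis-style raw Kd values (nM) are converted
to pKd = −log₁₀(Kd/10⁹) on load.

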