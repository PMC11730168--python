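# Methods

## Model and assumptions

The regressor maps a (drug, protein) pair to one continuous affinity. It
assumes (i) the drug's binding-relevant information is carried by the 2-D
heavy-atom graph — no conformers, bond orders, or chirality-aware features;
(ii) the protein's information is local sequence context, captured by
overlapping 3-grams and a CNN — no structure, PSSMs or pretrained language
models; (iii) affinity is a smooth function of the two pooled
representations, learnable by an MLP under squared error.

### Drug branch

Atoms become nodes; hydrogens stay implicit (feature values, never nodes);
aromatic bonds count as ordinary edges, so the adjacency is binary and
symmetric with zero diagonal. The five atom descriptors — one-hot element
over a 43-symbol vocabulary plus an "other" bucket, one-hot heavy-atom
degree (0–10), one-hot total hydrogens (0–10), one-hot implicit valence
(0–10), aromatic flag — give a fixed width of 78 columns, identical across
molecules.

Graph powers use the *distance* semantics: `graph_power(A, k)` joins two
distinct vertices iff their shortest-path distance is between 1 and k. It is
computed by boolean products of (A + I) — never raw integer matrix powers,
which count walks, not connectivity. This gives the nesting
supp(A) ⊆ supp(A²) ⊆ supp(A³) that the parallel block design relies on. The
exponent is capped at 3: molecular graphs are small, and chemically
meaningful shortest paths rarely exceed three bonds, so higher powers add
density (and cost) with little information.

Normalization follows symmetric degree scaling D^(−1/2)ÂD^(−1/2). The
encoder always adds self-loops first (Â = Aᵏ + I) so each atom retains its
own features in the update; the raw no-self-loop form is exposed behind a
flag because its closed forms (path graph off-diagonals 1/√2; regular graph
A/d) make exact unit tests possible. Degree-0 rows, possible only with
self-loops off, map to zero rather than dividing by zero.

Block depths are fixed at (3, 2, 1) layers for powers (1, 2, 3): one layer
on A³ already mixes 3-hop neighborhoods, so deeper stacks on higher powers
mostly add oversmoothing risk. The three blocks read the same raw node
features in parallel (a chained variant exists behind
`ModelConfig.chained_blocks`, default off). Pooling is global max over atoms
— together with the symmetric normalization it makes the prediction exactly
invariant under atom relabelling, which a test asserts to float precision.

### Protein branch

Sequences are truncated/right-padded to `protein_max_len` (default 1000)
with a reserved pad character `0` outside the amino-acid alphabet, then
split into overlapping 3-grams, giving exactly max_len − 2 rows. Padding
must not inject vocabulary, so any word containing the pad symbol embeds as
the zero vector; out-of-vocabulary words (e.g. X/U/B codes) also embed to
zero and are logged at debug level. The word2vec dictionary is an
interchangeable input: its dimension defaults to 100 but any trained or
loaded dictionary works. The built-in trainer uses skip-gram with negative
sampling (window 5, minimum count 1, 5 negatives, 5 epochs), single-threaded
with one seeded generator, so identical (corpus, seed) pairs give identical
vectors. The CNN applies three valid (unpadded) 1-D convolutions, 32 filters
of width 8 each by default, then global max pooling.

### Fusion head and training

Concatenated drug and protein vectors pass through fully connected layers
1024 → 512 → 1 with the rectifier everywhere except the linear output.
Dropout 0.2 is applied after the first two fusion layers only — not inside
the graph blocks — the conventional placement in this model family. Weights
initialize uniform in ±1/√fan_in from a recorded seed. The optimizer is
Adam; loss is MSE, matching the evaluation metric. Cross-validation
shuffles indices once with the run seed and deals them round-robin into
five folds (sizes differ by at most one); each fold serves once for
validation and per-fold reports are averaged. No early stopping: the
published operating point trains a fixed 500 epochs, and `epochs` is simply
configurable for desk-scale runs. Reported numbers are CV-averaged
validation metrics; a separate held-out test partition is not used.
Splitting is random over drug–target *pairs* (not cold-drug/cold-target),
the convention of this benchmark family.

## Metrics

pKd = −log₁₀(Kd/10⁹) for Kd in nM. CI sums h(pᵢ − pⱼ) over the Z pairs with
strictly greater true affinity; tied-truth pairs are excluded from both
numerator and Z, and all-tied truth raises rather than silently returning
0. h uses exact floating-point equality for the 0.5 branch — model outputs
essentially never tie except by construction. The vectorized CI is tested
for exact equality against an exhaustive O(n²) double loop.

## Synthetic data generator

The generator emulates the benchmark table shape with no download: valid
SMILES assembled from concatenation-safe fragments (chains, branches,
carbonyls, benzene rings; every product re-parsed), uniform random
sequences over the 20 letters, and labels

    affinity = 8 + β · z(z(heavy atoms) + z(ring count) + z(count of "W")) + N(0, sd)

standardized over the generated pairs. Defaults: 50 drugs × 25 proteins,
500 sampled pairs, sequence lengths 80–200, β = 1, sd = 0.3 — an affinity
band of roughly 5–11, mimicking transformed Davis values so loss magnitudes
are realistic. All descriptors are computable by the package's own
featurizers, so the signal is learnable in principle; the score itself is a
known oracle predictor whose CI (≈ 0.90 at β = 1, sd = 0.3) upper-bounds any
model. The motif descriptor is tryptophan content — chosen because a
single-letter motif has enough count variance in uniform random sequences
for the protein branch to matter, where a rare 3-letter motif would almost
never occur.

What the generator does **not** emulate: real chemical scaffolds and their
correlation structure, homology between proteins, the long-tailed affinity
distributions of real panels, or any binding physics. Passing tests
therefore demonstrate that the pipeline is wired and can extract a planted
signal at desk scale — not that it reproduces published benchmark accuracy,
which requires the external Davis/Kiba datasets and full-length training.

## Numerical choices and problem sizes

Everything runs in float64 on a NumPy reverse-mode tape; analytic gradients
of the full forward pass agree with central finite differences to < 1e-4
relative (tested, typically ~1e-11). Max pooling routes gradient to the
first argmax row on ties. Training aborts with a diagnostic on non-finite
loss. Desk-scale runs in the tests and the acceptance script use a reduced
operating point chosen once: hidden widths ≤ 64, 30 epochs, batch 64,
learning rate 1e-3 (Adam needs the slightly larger step than the published
5e-4 to converge within 30 epochs), protein length 200 (sequences are
generated at 80–200), embedding dimension 16, and a single CV fold for the
headline run; the ablation grid runs all five configurations at 150 pairs,
60 epochs in the acceptance script. These sizes train in about a minute on
one CPU while leaving a clear margin over the mean-predictor baseline.

## Known limitations

- Per-sample forward passes (molecular graphs vary in size) make the NumPy
  implementation ~10–100× slower than a batched GPU implementation;
  full-benchmark 500-epoch training is supported in configuration but is a
  long-running workflow, not a test surface.
- Bond types, stereochemistry and 3-D geometry are not encoded.
- The concordance index is O(n²) in memory; fine up to tens of thousands of
  validation pairs.
- `chained_blocks=True` is provided for architecture exploration but is not
  the documented default reading of the design.
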