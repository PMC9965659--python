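# Methods

## Model

`dtafuse` regresses a real-valued binding affinity from three views of a
drug–protein pair.

**Token dictionaries and embeddings.** Drug SMILES and protein sequences
are encoded character-wise with label dictionaries shipped as package
defaults: 64 SMILES characters (the charset of canonicalised SMILES) and
22 protein characters (20 standard amino acids + X + U), codes assigned in
insertion order from 1; 0 is the padding code and its embedding row is
frozen at zero. User dictionaries are accepted as two-column TSV. Unknown
characters raise by default; a permissive mode maps them to the padding
code with a logged warning. Maximum lengths default to 100 (SMILES) and
1000 (protein) for benchmark presets and 64/64 for the desk-scale
synthetic preset; they only control truncation/padding.

**Sequence channels.** Each embedded sequence passes through stacked
`[1-D convolution (same padding, stride 1) → squeeze-and-excitation]`
blocks, SE applied after every convolution. The SE squeeze is the
per-channel mean over *valid* (non-padding) positions; the excitation is a
bias-free two-layer bottleneck `σ(W₂ relu(W₁ z))` with reduction ratio `r`
(16 in benchmark presets, 4 at desk scale, which must divide the channel
count); reweighting multiplies each channel by its gate. Convolution
kernel sizes (4 drug / 8 protein by default) are free parameters.
Convolution biases leak into padding positions, so the map is re-masked
after every convolution; squeeze statistics, pooling and attention all
exclude padding. Consequence (tested): appending padding to a sequence
changes no output by more than 1e-6.

The encoder returns both the position-resolved feature map and its global
max pool. The attention stage consumes the position-resolved map; global
max pooling is applied only at fusion. This is the single reading that
makes the channel-attention equations and the fusion shapes consistent,
and it is the one implemented.

**Graph channel.** RDKit parses SMILES into heavy-atom graphs; hydrogens
are implicit and bonds are unlabeled (message passing uses adjacency
only). Nodes carry a 62-wide descriptor vector of 10 blocks: atom symbol
(one-hot over 44 symbols + reserved "other" slot), atomic number,
hybridization (one-hot over SP/SP2/SP3/SP3D/SP3D2 + other), heavy-atom
degree, chirality (unspecified/CW/CCW/other), formal charge, aromaticity,
bonded hydrogens, explicit and implicit valence. GIN layers compute
`MLP((1+ε)·h_v + Σ_{u∈N(v)} h_u)` with a two-layer perceptron
(hidden = output = layer width), learnable ε initialised at 0, node-level
batch normalisation (statistics over all nodes in the batch, per channel)
and ReLU. The graph-level vector concatenates per-layer sum readouts and
projects them through linear + ReLU + dropout — the canonical multi-layer
GIN readout, which reconciles the concatenated-readout and final-layer-
projection formulations. Depth defaults to 5 (warning outside the studied
3–7 range; the ablation sweep over 3–7 runs end-to-end in the tests).
Graphs are processed as stacked node matrices with segment ids, so batched
and one-at-a-time encodings agree exactly in evaluation mode.

**Cross-attention interaction.** Queries come from the drug (SMILES
features in one block, GIN node features in the other); keys and values
are the protein sequence features and share one input projection per
block (keys and values are the same projected tensor, as in the
published formulation). Per-head projections split the attention width
across `h` heads; logits are scaled by `√(d_in/h)` where `d_in` is the
query branch's input width (the printed convention; the conventional
`√(d_head)` is available via `scale_mode="head"`). Masked protein
positions receive exactly zero attention mass; every map row sums to 1
over unmasked keys.

The decoupling consumes the head-averaged *pre-value* attention maps —
the only shape-consistent reading, since row/column decoupling does not
type-check against value-weighted head outputs. Those value-weighted
outputs are therefore not consumed by the model (the block still exposes
them for standalone use). Drug weights are per-position row means,
computed separately per branch because the SMILES length and atom count
differ; the protein weight is the column mean of the drug-axis stack of
both maps. Sums are implemented as means: any positive rescaling of the
weights is absorbed by the trained head. Because attention rows are
normalised, the row means are constant across drug positions — the
learned interaction signal flows through the protein weights and the
fused representation, and the drug-side weighting acts as a plain pooling
of each branch.

Fusion global-max-pools the three reweighted maps (SMILES positions,
graph nodes, protein positions) and concatenates them into `I_dp`. The
trailing global *average* pool of the original formulation acts on an
already-pooled vector (window 1) and is implemented as the identity. A
four-affine-layer MLP (ReLU + dropout after each hidden layer) produces
the scalar affinity.

## Metrics

- MSE (the training loss), minimised by Adam.
- Concordance index: over ordered pairs with distinct labels, credit 1
  for correctly ordered predictions, 0.5 for prediction ties; undefined
  (rejected) when all labels are equal. Verified against an O(n²)
  brute-force oracle and invariant under strictly increasing transforms.
- rm² = r²·(1−√(max(r²−r₀², 0))) where r² is the squared Pearson
  correlation and r₀² = 1 − SS_res(through-origin fit)/SS_tot. The
  radicand is clamped at zero, so rm² ≤ r² always, with equality iff
  r₀² = r². A variant without the square root circulates in print but
  goes negative for perfect fits; it is kept behind
  `rm_squared(..., printed_form=True)` for auditability only.
- Pearson correlation (sample covariance over sample standard deviations).

## Training

Adam at the benchmark settings (600 epochs, lr 1e-4, batch 512/1024,
dropout 0.2) for the dataset presets; the desk-scale synthetic preset uses
60 epochs, lr 3e-3, batch 64, dropout 0.1. Every epoch logs train and
validation MSE; the returned checkpoint is the epoch with the best
validation MSE (plain best-checkpoint selection; no early stopping).
All randomness (initialisation, batch order, dropout) derives from
explicit seeds, so identical configurations reproduce identical loss
curves. Splitting is a seeded uniform shuffle with largest-remainder
rounding at 4:1:1 by default (matching the benchmark interaction-count
proportions); k-fold cross-validation over the non-test portion and
cold-drug/cold-target splitting are provided as optional modes.

## Synthetic data: what it emulates and what it does not

The generator emulates the *triplet structure* of affinity benchmarks at
desk scale. Drugs are assembled from a pool of chain-extendable acyclic
SMILES fragments (3–6 fragments per molecule), so every emitted string
parses; proteins are uniform random 48-mers over the 20 standard amino
acids. With probability 0.5 each, independently, a trifluoromethyl cap
(`C(F)(F)F`) is appended to the drug and a fixed 6-mer motif (`HYWHYW`)
is spliced into the protein — a factorial design in which neither feature
alone carries signal. The affinity is
`base (5) + effect (2) · 1[both present] + N(0, 0.3²)`. Fluorine appears
in no pool fragment and the motif has ~20⁻⁶ background probability, so
the planted indicators are exact; the pharmacophore's atom indices are
recorded for attribution ground truth. The CF₃ group is appended
terminally because fluorine is monovalent; its string position is fixed
but its atom indices vary with molecule size.

What passing tests on this generator do **not** show: real affinity data
have correlated drugs and proteins, shared scaffolds, assay noise that is
not Gaussian or homoscedastic, rings and stereochemistry, and graded
dose–response rather than a single binary interaction. Desk-scale results
demonstrate that the architecture, optimisation and attribution are wired
correctly — not that benchmark-level accuracy transfers.

**A structural note on the concordance index under this generator.** The
planted effect is binary. A held-out predictor, however good, can only
order between-class pairs; within-class label order is pure noise, so
those pairs contribute 0.5 in expectation. Expected CI is therefore capped
at `0.5 + P(between-class pair)/2` — about 0.69 at the 0.5×0.5 planting
rates (co-occurrence ≈ 0.25), and at most 0.75 for any planting rate. The
test suite's signal-recovery check reports the trained model's CI next to
the CI of the *oracle* predictor (the noise-free class mean) on the same
labels; the trained model matches the oracle (0.693 vs 0.692 at the
default seeds) while reaching test MSE ≈ 0.09 = σ², i.e. the Bayes floor.
A fixed CI target of 0.8 on this generator is unattainable in principle
and the corresponding assertion is expected to fail; it is kept, with this
analysis, rather than weakened.

## Attribution

Gradients are taken in evaluation mode (dropout off, batch-norm running
statistics) with the autodiff graph enabled. Channel weights average the
gradient over nodes; the raw map is ReLU of the weighted channel sum;
min–max normalisation maps it to [0,1]. A constant raw map (e.g. all
gradients non-positive) is defined as all-zeros with a logged warning.
Top-contributing atoms for the overlap rate are those with normalised
score ≥ 0.5 (configurable); atom-level counting is used — functional-group
level grouping would be an extension. Heatmaps are SVG renderings with a
white-to-red linear colour scale; output bytes are deterministic for
fixed inputs.

## Numerical choices

- float64 throughout; the autodiff op set is finite-difference-verified.
- Max-pool gradients route ties to the first maximal entry.
- Masked attention logits are filled with −1e30 before the softmax
  (−inf would produce NaNs for fully masked rows, which are rejected
  upfront instead).
- Split sizes use largest-remainder rounding (stable argsort, earlier
  parts win ties), making a 30,056-record set partition into
  20,038/5,009/5,009.
- Degenerate inputs are rejected with specific errors: empty graphs,
  all-padding sequences, all-equal labels (CI), zero variance
  (Pearson/rm²), queries with every key masked.

## Problem sizes used by the test suite

Overfit capacity: 64 noise-free records, 200 epochs (~25 s). Signal
recovery: 2000 records at the generator defaults, 60 epochs (~3 min),
followed by attribution on 120 held-out molecules. These sizes were chosen
so the whole suite runs comfortably on one CPU core.

## Known limitations

- No 3-D conformers, protein structures or docking; proteins are
  sequences only.
- Bond types, edge features and self-attention within a single entity are
  out of scope by design.
- The value-path parameters of the attention blocks (`w_v`, `w_o`) are
  not trained by the full model (see the decoupling note above); they
  exist for standalone use of the block.
- The numpy engine is single-threaded apart from BLAS matmuls; benchmark
  presets (600 epochs on 30k–118k records) are configuration-complete but
  impractical without substantial compute.
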