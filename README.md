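# dtafuse

Drug–target binding affinity (DTA) regression that fuses three views of a
drug–protein pair — the drug's SMILES character sequence, the protein's
amino-acid sequence, and the drug's molecular graph — through
cross-multi-head attention, with gradient-based atom attribution for
interpreting what the graph channel learned.

## Who this is for

Computational chemists and ML practitioners who want a desk-scale,
CPU-only, fully tested implementation of a modern three-channel DTA
architecture: to train on their own affinity tables (Davis/KIBA/BindingDB
CSV exports or anything with `smiles,protein,affinity` columns), to rank
candidate ligands against a target sequence, and to inspect per-atom
contribution heatmaps.

## The model

Given a pair (drug `d`, protein `p`) the model predicts a real-valued
affinity (pKd for Davis-style data, where `pKd = −log10(Kd/10⁹)` with Kd in
nM):

- **Sequence channels.** Characters are mapped by fixed label dictionaries
  (64 SMILES tokens, 22 amino-acid tokens; 0 = padding) to integer vectors,
  embedded, and passed through stacked `[1-D convolution → squeeze-and-
  excitation]` blocks. An SE block computes channel statistics
  `z_c = mean_i u_c(i)`, gates them with
  `s = σ(W₂ · relu(W₁ · z))` (reduction ratio `r`), and rescales each
  channel: `x_c = s_c · u_c`.
- **Graph channel.** RDKit parses the SMILES into a heavy-atom graph whose
  nodes carry a 62-dimensional descriptor vector (10 blocks: symbol,
  atomic number, hybridization, degree, chirality, formal charge,
  aromaticity, bonded hydrogens, explicit/implicit valence). Stacked graph
  isomorphism network (GIN) layers update nodes as
  `h_v ← MLP((1+ε)·h_v + Σ_{u∈N(v)} h_u)` with node-level batch
  normalisation and ReLU; per-layer sum readouts are concatenated and
  projected into a graph vector, and the last layer's node features feed
  attention and attribution.
- **Interaction.** Two cross-multi-head attention blocks use the drug's
  sequence features and graph-node features as queries against the protein
  sequence features as keys/values. The head-averaged attention maps are
  decoupled into drug position weights (row means) and a protein position
  weight (column means of the stacked maps); the weighted representations
  are global-max-pooled and concatenated into the interaction vector
  `I_dp`, which a four-layer MLP maps to the affinity.
- **Metrics.** MSE, concordance index (CI; prediction ties credited 0.5),
  the external-validity index `rm² = r²·(1−√(r²−r₀²))`, and Pearson
  correlation.
- **Attribution.** For a prediction `DTA`, channel weights over the last
  GIN feature map `F` are `W_c = (1/|V|) Σ_v ∂DTA/∂F_vc`; the per-atom map
  `relu(Σ_c W_c F_c)` is min–max normalised to `[0,1]` and rendered as a
  molecule heatmap. The overlap rate against reference binding-site atom
  sets is `mean_i |top_i ∩ site_i| / |site_i|`.

All neural components run on a small reverse-mode autodiff engine over
numpy float64 (`dtafuse.autograd`), verified op-by-op against finite
differences in the test suite.

## Worked example

Train the desk-scale preset on synthetic data with a planted
pharmacophore–motif interaction (affinity = 5 + 2·1[CF₃ in drug AND motif
in protein] + N(0, 0.3²)), then attribute a test molecule:

```python
import numpy as np
from dtafuse import (SyntheticSpec, generate_synthetic, split_dataset,
                     prepare_dataset, DTAModel, evaluate_model, train)
from dtafuse.config import model_config, train_config
from dtafuse.attribution import grad_aam

spec = SyntheticSpec(n_records=400, seed=1)
records, meta = generate_synthetic(spec)
cfg = model_config("synthetic", seed=1)
prepared = prepare_dataset(records, cfg)
split = split_dataset(records, seed=1)
model, history = train(DTAModel(cfg), prepared, split.train, split.validation,
                       train_config("synthetic", seed=1, epochs=25))
report = evaluate_model(model, prepared, split.test)
print(f"test MSE {report.mse:.3f}  CI {report.ci:.3f}  "
      f"rm2 {report.rm2:.3f}  Pearson {report.pearson:.3f}")
i = next(i for i in split.test if meta[i]["has_pharmacophore"])
cmap = grad_aam(model, prepared[i])
print(prepared[i].smiles, "-> top atoms", cmap.top_atoms(0.5),
      "planted", meta[i]["pharmacophore_atoms"])
```

Output:

```
test MSE 0.293  CI 0.688  rm2 0.562  Pearson 0.829
CCOCC(O)COC(N)CCOC(F)(F)F -> top atoms [13] planted [13, 14, 15, 16]
```

After 25 epochs on 400 records the model already explains most of the
planted signal (Pearson 0.83 against labels whose irreducible noise is
σ=0.3), and the highest-scoring atom (index 13) is the carbon of the
planted trifluoromethyl group. The CI of ~0.69 is near the ceiling for
this binary-effect generator: pairs within the same planted class are
ordered by pure noise, which caps the expected CI around 0.69 at the
default planting rates (see `docs/methods.md`).

The same workflow is available from the shell:

```bash
dtafuse generate --preset synthetic --seed 1 --n 400 --out runs/gen
dtafuse train    --preset synthetic --seed 1 --out runs/fit
dtafuse predict  --checkpoint runs/fit/checkpoint.npz --data query.csv --out runs/pred
dtafuse explain  --checkpoint runs/fit/checkpoint.npz --data hits.csv --out runs/maps
```

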