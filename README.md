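# deephop

Target-conditioned **scaffold hopping** as molecule-to-molecule translation,
for computational and medicinal chemists who want novel-framework analogues
of an active compound rather than R-group edits.

Given a seed molecule X and a protein target Z, the package

1. **mines training pairs** ((X, Y) | Z) from a bioactivity table under the
   hop criteria — activity gain ΔpChEMBL ≥ 1, Bemis–Murcko scaffold
   Tanimoto(X, Y) ≤ 0.6, 3D shape-and-color score SC(X, Y) ≥ 0.6 — with
   per-target test molecules held out before mining and at most 10 hops per
   source;
2. **trains a multimodal transformer** whose encoder fuses the SMILES token
   sequence with per-atom embeddings from a 3D spatial graph network
   (h_i ← Σ_{j∈N_i} ReLU((Uᵀ(p_j − p_i) + b) ⊙ h_j), GRU readout over the
   canonical atom order) and is conditioned on a k-dimensional protein
   sequence embedding H_p broadcast along the sequence;
3. **generates candidates** by beam search and **scores** them with a
   multi-task QSAR profiler (shared trunk, one pChEMBL regression head per
   target, masked-label MSE) and a metric suite: validity, uniqueness,
   novelty, mean improvement, success rate (valid ∧ structural hop ∧
   Δ ≥ 0) and constraint success rate (Δ ≥ 1).

All neural components run on a small numpy autodiff engine bundled with the
package (`deephop.nn`), so everything trains and evaluates on a single CPU
core with no GPU framework.

## Worked example

```python
import numpy as np
from deephop import fixtures, pairs, protein, qsar, transformer, metrics

spec = fixtures.FixtureSpec(n_molecules=30, n_targets=2, seed=1)
library = fixtures.attach_conformers(fixtures.make_library(spec), n_conf=3)
records = fixtures.make_bioactivity(spec, library)
mols = {m.mol_id: m for m in library}

split = pairs.split_dataset(records, mols, seed=5)
print(len(split.train_pairs), len(split.val_pairs))
# 153 17

proteins = {p.seq_id: protein.embed_protein(p)
            for p in fixtures.make_proteins(spec)}
cfg = transformer.HopTransformerConfig(f=64, n_heads=4, n_encoder_layers=2,
                                       n_decoder_layers=2, ffn_hidden=128,
                                       graph_dim=16, graph_layers=2,
                                       dropout=0.0, max_len=80)
report = transformer.TrainReport()
model = transformer.train(split, proteins, config=cfg, epochs=5,
                          seed=3, report=report)
print([round(l, 3) for l in report.train_loss])
# [2.557, 2.123, 1.979, 1.843, 1.759]   <- per-epoch token cross-entropy
```

The mined pair counts come from a 30-molecule, 2-target synthetic panel
(153 training and 17 validation pairs satisfying all three hop predicates);
the loss trace is the teacher-forced cross-entropy per token, falling from
near ln|vocab| as the model starts to learn the transformations. With ~200
epochs on a 30-pair corpus the same model reconstructs over 80% of training
products exactly; `examples/` walks through generation and evaluation.

A thin CLI mirrors the pipeline: `deephop fixtures`, `deephop mine-pairs`,
`deephop train-qsar`, `deephop train`, `deephop generate`,
`deephop finetune`, `deephop evaluate` (see `deephop --help`).

## Examples

Each script in `examples/` builds a small input, runs one capability and
prints what the numbers mean:

* `01_hop_criteria.py` — scaffolds, fingerprint and SC similarity for a pair
* `02_mine_pairs.py` — mining and capping hop pairs from a synthetic table
* `03_qsar_profiler.py` — multi-task QSAR training, CV gating
* `04_train_and_generate.py` — transformer training and beam-search hops
* `05_evaluate.py` — the metric suite on a generation run

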