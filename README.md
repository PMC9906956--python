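# simscreen

A distance-aware SMILES transformer autoencoder for latent-space molecular
similarity search. The encoder maps each molecule to a single d-dimensional
vector, and the latent space is explicitly shaped during training so that the
Euclidean distance between two embeddings approximates `a · (1 − sim(A, X))`,
where `sim` is a pluggable ground-truth similarity metric (Morgan-fingerprint
Tanimoto by default). Screening a library then reduces to exact L2
nearest-neighbour ranking in latent space, which drastically shrinks the
search space that an exhaustive (expensive) similarity method has to process.

Three training objectives are implemented and compared:

* **vanilla** — reconstruction cross-entropy only;
* **triplet** — reconstruction + margin hinge on (anchor, positive, negative)
  triplets, with positives/negatives defined by a similarity threshold;
* **similarity** — reconstruction + the distance-regression loss
  `| a·(1 − sim(A, X)) − ‖f(A) − f(X)‖ |`, applied between batch anchors and
  all other batch members.

The transformer (4-layer/4-head, d = 256 in the full profile; a toy
d = 64/2-layer profile for CPU tests) is implemented on a minimal NumPy
reverse-mode autodiff engine (`simscreen.autodiff`) — no deep-learning
framework is required. RDKit supplies SMILES parsing, canonicalization and
Morgan fingerprints. A deterministic fixture generator builds clustered
synthetic SMILES datasets (families of structurally related molecules plus a
diverse background) so everything runs offline.

## CLI

A single entry point, `simscreen` (see `--help` on each subcommand):

```bash
# deterministic synthetic dataset (20 families x 10 + 100 background)
simscreen make-fixtures --spec default --seed 7 --out data/

# train a variant: vanilla | triplet | similarity
simscreen train --data data/data.smi --loss similarity --profile toy \
    --seed 1 --epochs 90 --out runs/sim/

# embed a library with the trained encoder
simscreen embed --data data/data.smi --model runs/sim/checkpoint --out runs/sim/lib

# rank the library against a reference (SMILES or a library mol_id)
simscreen search --ref fam00_s --library runs/sim/lib \
    --model runs/sim/checkpoint -n 50 --out hits.csv

# evaluation protocols: auroc | topk | hits | ranking
simscreen evaluate --model runs/sim/checkpoint --data data/data.smi \
    --protocol auroc --seed 1 --out report.json
```

`hits.csv` columns: rank, mol_id, distance, smiles, approx_similarity —
the last via the rescaling `s ≈ 1 − d/d_max`.

## Package layout

| module | contents |
| --- | --- |
| `simscreen.autodiff` | tensor autograd engine (broadcasting ops, matmul, fused softmax/layer-norm, embedding) |
| `simscreen.chem` | molecule records, Morgan fingerprints, Tanimoto, similarity matrices, `.smi` IO |
| `simscreen.tokenizer` | regex SMILES tokenizer, vocabulary, encode/decode, right-shifted pairs |
| `simscreen.model` | encoder–decoder transformer, sinusoidal positions, masked-mean latent, greedy decoding, checkpoints |
| `simscreen.losses` | reconstruction / triplet / similarity losses and batch (anchor) variants |
| `simscreen.training` | similarity-grouped batching, Adam, the training loop |
| `simscreen.search` | library embedding, exact L2 top-N queries, distance→similarity rescaling |
| `simscreen.evaluation` | rank-sum AUROC, threshold-AUROC protocol, top-k reproduction, hit identification, ranking histograms |
| `simscreen.fixtures` | deterministic synthetic SMILES dataset generator |
| `simscreen.benchmark` | the fixed desk-scale comparison protocol used by tests and the acceptance script |
| `simscreen.config` / `simscreen.cli` | layered JSON configuration and the `simscreen` command |

## Notes

* Checkpoints are NumPy `.npz` archives with a JSON sidecar carrying the
  model config, seed and vocabulary; loading refuses on vocabulary mismatch.
* All randomness flows through explicit seeds; training runs are
  bit-reproducible on a single machine.
* The similarity metric is an arbitrary callable into [0, 1]; swapping it
  changes nothing downstream (the model never sees fingerprints, only the
  similarity values).
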