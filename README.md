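# dtidae

Drug–target interaction (DTI) prediction from a binary interaction matrix
and binary drug fingerprints, using a small masked denoising autoencoder.

The pipeline has three stages:

1. **Densification.** The sparse drugs × targets adjacency `Y` is lifted onto
   the fingerprint axis: `W = Z @ Y` (fingerprint bits × targets), min–max
   normalised and binarised. Entry `(k, t)` of the binary `W` says "some drug
   carrying substructure bit `k` hits target `t`", which is a much denser
   signal than `Y` itself.
2. **Denoising autoencoder.** Each target's length-`f` fingerprint profile
   (a column of `W`) is one training sample for a mirrored sigmoid network
   (`f → 15 → 5 → 15 → f` by default). Unknown positions are zeroed at the
   input and contribute no error; a random fraction of the observed positions
   is additionally corrupted, and the squared error is reweighted `alpha` on
   corrupted versus `beta` on intact observed positions, plus an L2 weight
   penalty. Backpropagation is hand-written dense NumPy and is validated
   against finite differences in the test suite.
3. **Back-projection.** The reconstructed matrix is projected through the
   fingerprints: `Y_hat = Z.T @ W_hat`, giving every drug–target pair a score.

Evaluation supports three cross-validation scenarios — random held-out pairs,
whole held-out drug profiles (new-drug cold start) and whole held-out target
profiles — with 5 × 10-fold CV and AUC/AUPR scoring by default. A synthetic
generator with planted latent structure makes the whole pipeline testable
without any data download.

## Data formats

All matrices are tab-delimited text with identifiers in the header row and
first column:

- `Y.tsv` — drugs × targets, entries 0/1 (use `--orientation targets-as-rows`
  if your file has targets as rows);
- `Z.tsv` — fingerprint bits × drugs, entries 0/1 (fingerprints are computed
  externally, e.g. 800-bit substructure fingerprints from SMILES);
- score and affinity matrices — same layout, real-valued.

## Command line

```bash
# synthetic dataset (writes Z.tsv, Y.tsv, affinity.tsv)
dtidae synth --spec spec.yaml --out-dir data/

# individual stages
dtidae preprocess --y data/Y.tsv --z data/Z.tsv --out data/W.tsv
dtidae train --w data/W.tsv --config config.yaml --out model.npz
dtidae predict --w data/W.tsv --z data/Z.tsv --model model.npz \
               --y data/Y.tsv --top-k 20 --out-dir run/

# everything in one go (scores.tsv + ranked novel_pairs.tsv + manifest.json)
dtidae pipeline --y data/Y.tsv --z data/Z.tsv --config config.yaml --out-dir run/

# cross-validated AUC/AUPR
dtidae evaluate --y data/Y.tsv --z data/Z.tsv --scenario pairwise \
                --folds 10 --repeats 5 --seed 1 --out-dir eval/
```

`config.yaml` is a flat key/value file mirroring `TrainingConfig`; absent
keys take the defaults (`alpha: 0.4`, `beta: 0.6`, `hidden_sizes: [15, 5]`,
`batch_size: 100`, `lambda_reg: 10.0`; use `lambda_reg: 1.0` for very small
datasets). Every run writes a `manifest.json` (config snapshot, input
digests, seed, wall times) sufficient to reproduce it bit-identically.

### A note on "observed" entries

By default only the ones of the binary training matrix are treated as known;
zeros are missing (they are zeroed at the input and excluded from the loss).
Set `zeros_are_observed: true` to treat every entry as known — on binary
data this gives the model real negatives and is what the recovery tests use.

## Python API

```python
from dtidae import TrainingConfig, run_pipeline, read_interaction_matrix, read_fingerprint_matrix

Y = read_interaction_matrix("Y.tsv")
Z = read_fingerprint_matrix("Z.tsv")
scores = run_pipeline(Z, Y, TrainingConfig(lambda_reg=1.0, seed=0))
```

See `dtidae.evaluation` (`make_cv_plan`, `run_cv`, `auc_score`, `aupr_score`)
and `dtidae.synthetic` (`SyntheticSpec`, `generate`) for the evaluation and
simulation surfaces.

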