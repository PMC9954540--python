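# p300lab

Tools for studying P300 classification pipelines end to end without any
external data:

- **`p300lab.synth`** — synthetic oddball ("Brain Invaders"-style) EEG
  sessions: 16 channels at 128 Hz, 8 target symbols × 8 repetitions × 12
  flashes (2 TARGET + 10 NON-TARGET each), a Gaussian P300 bump on TARGET
  epochs peaking 240–600 ms post-stimulus, pink-noise background, fully
  seeded. Serializes sessions/epochs to a zip-of-raw-arrays archive with a
  JSON sidecar.
- **`p300lab.preprocess`** — zero-phase Hamming FIR band-pass (1–24 Hz
  default) and epoch extraction (100–700 ms window, half-open sample
  convention: 77 samples at 128 Hz).
- **`p300lab.xdawn`** — per-class spatial filters maximizing the
  evoked-to-signal variance ratio (generalized eigenproblem); with one
  filter per class the filtered epochs have 2 virtual channels.
- **`p300lab.spd`** — super-trial construction (filtered TARGET prototype
  stacked on the filtered epoch), shrunk correlation matrices (4×4), Karcher
  mean, tangent-space projection (length-10 vectors with √2 off-diagonal
  weighting so vector norms equal Riemannian distances), and the reduced
  off-diagonal flattening with the prototype block removed.
- **`p300lab.riemann`** — affine-invariant distance and the
  minimum-distance-to-mean (MDM) baseline classifier.
- **`p300lab.hcbr`** — hypergraph case-based reasoning: feature vectors are
  rounded (4 decimal digits by default) into token-set cases, tokens are
  partitioned by case-membership signature, and a signed per-cell strength
  vector `mu` with case-overlap weights `W` (‖w_j‖₁ = ‖μ‖₁ = 1) yields a
  signed support; queries sharing no token abstain to the majority class.
- **`p300lab.quantum`** — exact state-vector simulation of a second-order
  Pauli-Z feature map (2 repetitions, linear entanglement by default), the
  fidelity kernel + precomputed-kernel SVM (QSVC), a two-local ry/rz + cz
  variational circuit read out by bitstring parity with a learned bias
  (VQC), and an SPSA optimizer (c0 = 4, maxiter = 40 defaults). Optional
  seeded shot sampling (R = 1024 convention) everywhere.
- **`p300lab.evaluate`** — balanced accuracy, stratified k-fold CV (k = 5),
  the permutation significance threshold (0.975 quantile of permuted CV
  accuracies), an end-to-end experiment runner, and the digits × filter-count
  sweep for the case-based classifier.

## CLI

```bash
p300lab simulate --seed 1 --out session.archive            # synthetic session
p300lab preprocess --in session.archive --out epochs.archive
p300lab features --in epochs.archive --mode tangent --out features.csv
p300lab evaluate --config cfg.json --out report.json
p300lab permtest --in epochs.archive --n-perm 200 --seed 7
```

`evaluate` reads a flat JSON config; the main keys (see
`p300lab.evaluate.DEFAULT_CONFIG` for all of them):

```json
{
  "seed": 1,
  "design": {"n_targets": 8, "n_repetitions_per_target": 8},
  "amplitude": 5.0,
  "noise_scale": 1.0,
  "classifiers": ["mdm", "svm", "hcbr", "vqc", "qsvc"],
  "nfilter": 1,
  "k": 5,
  "classifier_options": {"vqc": {"maxiter": 40}},
  "sweep": false,
  "permutation": false,
  "n_perm": 200
}
```

The classifier registry knows `mdm`, `svm`, `hcbr`, `vqc`, `qsvc`. Feature
mode defaults to SPD matrices for MDM and tangent vectors for everything
else; `"feature_mode"` accepts `tangent`, `reduced`, `epochvec` (the three
case-based input variants) or `matrix`.

## Notes

- Everything is seeded; the same seed reproduces sessions, folds,
  permutations, shot samples, and SPSA trajectories bit-for-bit.
- An optional adapter (`p300lab.zenodo.load_zenodo_bi`) can point the same
  pipeline at a locally downloaded real recording; nothing in the tests
  depends on it.
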