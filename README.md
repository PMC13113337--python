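# mirfnet

Multimodal intrapartum fetal-risk assessment: a tested library + CLI that
classifies 30-minute cardiotocography (CTG) segments as normal/abnormal by
fusing three modalities:

* **CTG time series** (FHR + UC, 4 Hz) — per-channel instance normalization,
  overlapping patch embedding, and a channel-independent Transformer encoder
  with shared weights;
* **Gramian-angular-difference-field (GADF) images** of the FHR — min-max
  rescale → arccos polar mapping → pairwise angular Gramian → bilinear resize
  to 224×224, encoded by a residual network (depths 50/101/152, plus reduced
  depths for desk-scale runs);
* **structured maternal metadata** (age, gravidity, parity, gestational
  diabetes) — training-split standardization with mean imputation, compressed
  by a small autoencoder whose latent vector feeds fusion and whose
  reconstruction regularizes training.

Modality embeddings are projected to a common width, stacked as a 3-token
sequence with a learnable modality embedding, fused by post-norm Transformer
blocks (concat/add/MLP baselines available), and classified by a 2-logit
softmax head. Training minimizes label-smoothing cross-entropy (ε = 0.1) plus
λ = 0.5 × metadata-reconstruction MSE, with Adam (lr 1e−3, weight decay 1e−4,
batch 64, ≤100 epochs) and best-validation-QI checkpoint selection over seeds
0/42/3407, each seed driving an independent stratified 6:2:2 split.

All neural components run on a small numpy reverse-mode autodiff engine in
`mirfnet.nn` (the target environment ships no deep-learning framework); it is
validated by finite-difference gradient checks in the test suite.

## Layout

| module | role |
|---|---|
| `mirfnet.fixtures` | seeded synthetic CTG generator (label-coupled decelerations, contractions, metadata priors, injected artifacts with ground-truth masks) |
| `mirfnet.preprocess` | FHR range/jump and UC 3σ invalid-point detection, linear interpolation, moving-average smoothing, signal-loss eligibility |
| `mirfnet.gadf` | rescale / polar / Gramian / bilinear-resize pipeline, fast piecewise-aggregate path |
| `mirfnet.encoders` | CTG patch Transformer, residual-network image encoder, metadata standardization + autoencoder |
| `mirfnet.fusion_model` | token projection, fusion Transformer + baselines, classifier head, composite loss |
| `mirfnet.metrics` | ACC/SEN/SPE/QI/F1/MCC, dual-route ROC AUC (trapezoid ≡ rank statistic), Brier score, mean±sd aggregation |
| `mirfnet.harness` | stratified splitting, training loop, multi-seed experiments, ablation sweeps, checkpoints |
| `mirfnet.io_wfdb` | minimal WFDB reader (formats 16/212), last-30-min segment selection, CSV+JSON fixture format |
| `mirfnet.nn` | numpy autodiff engine, layers, Adam |

## CLI

```bash
mirfnet simulate --n 40 --seed 0 --segment-length 7200 --out data/
mirfnet prep     --in data/manifest.json --out clean/        # QC report + cleaned fixtures
mirfnet gadf     --in clean/syn0000.csv --out img.png --size 224 --fast
mirfnet train    --in clean/manifest.json --config model.yaml --run-dir runs/r0
mirfnet evaluate --in clean/manifest.json --seeds 0,42,3407 --out report.json
mirfnet sweep    --in clean/manifest.json --axis strategy=transformer,concat,add,mlp --out sweep.csv
```

Configuration is YAML mirroring `mirfnet.config.ModelConfig`
(`ModelConfig().to_yaml("model.yaml")` writes the defaults).

## Notes

* Pretrained image-encoder weights are not downloadable in the target
  environment; `pretrained=true` falls back to random initialization with a
  warning (`weights_path` accepts a local `.npz` checkpoint).
* Everything the tests need is generated programmatically; no data files ship
  with the repository and nothing touches the network.
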