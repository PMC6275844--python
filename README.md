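# octaline

A-line-based coronary plaque classification for polar-domain intravascular
OCT pullbacks. Each radial depth profile (A-line) is classified as
**fibrocalcific** (fibrous layer over calcium: signal-poor pocket with sharp
borders), **fibrolipidic** (fibrous layer over lipid: fast diffuse signal
drop-off), or **other**, then the per-A-line calls are cleaned spatially in
the en-face (θ, z) view.

Because no clinical pullback data is publicly available, the package ships a
first-class synthetic pullback simulator with exact ground truth, and every
pipeline stage is developed and tested against it.

## Pipeline

1. **sim** — synthetic polar pullbacks: eccentric lumen, drifting guidewire
   shadow, jittered rectangular lesions in (θ, z), class-conditional radial
   profiles, unit-mean multiplicative gamma speckle. Deterministic per seed.
2. **preproc** — lumen boundary by exact dynamic programming over radial edge
   strength (circular in θ), guidewire zeroing, pixel shifting so depth 0 is
   the first sample past the lumen, 200-sample crop, log(1+x), 7×7 σ=1
   Gaussian smoothing.
3. **nets** — 1-D CNN (replicate-pad 5 → conv 32×11 → pool 2 → conv 64×9 →
   pool 2 → dense 100 → softmax 3) and a 200→100→50→3 ANN baseline,
   implemented in NumPy with explicit forward/backward passes; Adam
   (lr 1e-4), inverse-proportion class weights, early stopping on relative
   validation-loss improvement (<0.01% for 5 epochs, cap 100).
4. **crf** — smoothness-only dense CRF (appearance kernel weight w1 = 0) with
   mean-field inference realized as Gaussian filtering of the class
   marginals (circular in θ), followed by three serial area-opening passes
   (threshold 10 px, 8-connected, θ-wrap-aware).
5. **saliency** — guided backpropagation from the pre-softmax class
   activation, per A-line and column-stacked per frame.
6. **evaluation** — pullback-held-out 10-fold cross-validation (48 ids →
   nine 38/5/5 folds plus one 40/5/3), confusion matrices and class-wise
   metrics before/after cleaning, paired two-tailed t-test across folds.

## CLI

```sh
octaline simulate --seed 7 --frames 40 --alines 448 --depth 968 --out run/
octaline preprocess --pullback run/sim.tif --meta run/sim.json \
    --labels run/sim_labels.csv --use-true-geometry --out run/
octaline train --processed run/processed.bin --index run/processed_index.csv \
    --arch cnn --out run/model.npz
octaline predict --model run/model.npz --processed run/processed.bin \
    --index run/processed_index.csv --out run/pred.csv
octaline clean --predictions run/pred.csv --alines 448 \
    --out run/cleaned.csv --png run/cleaned.png
octaline evaluate --truth run/sim_labels.csv --cleaned run/cleaned.csv \
    --out run/report.json
octaline saliency --model run/model.npz --processed run/processed.bin \
    --index run/processed_index.csv --frame 0 --class-index 0 \
    --out run/sal.csv --png run/sal.png
octaline crossval --pullbacks 10 --frames 20 --folds 2 --out run/cv/
```

Formats: pullbacks are multi-page 16-bit TIFF plus a JSON sidecar; labels,
en-face maps, and metrics are CSV; label maps and saliency overlays export
as PNG. Every artifact records the config and seed that produced it.

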