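# echoscope

Classifying bat species from their echolocation calls, end to end: from raw
ultrasonic audio to a compact convolutional classifier small enough for a
Raspberry-Pi-class field node, plus the surrounding machinery a deployed
acoustic monitoring system needs.

Bats emit species-typical ultrasonic pulses (roughly 9–200 kHz) whose sweep
shape, frequency band, duration and repetition rate differ between species.
A passive acoustic monitor records these calls, converts fixed-length audio
segments into time–frequency images, and classifies them. `echoscope`
implements that pipeline for researchers in bioacoustics and ecological
monitoring:

- **`synthetic_calls`** — a parametric generator of labeled ultrasonic pulse
  trains (FM sweeps, constant-frequency calls, FM–CF calls) at a native
  384 kHz rate with Gaussian noise at configurable SNR and configurable
  class imbalance. Field recordings of bats are rarely redistributable, so
  all tests and examples run on this generator.
- **`features`** — the exact preprocessing chain: rate relabeling (time
  expansion) to a nominal 44.1 kHz, 3-s segmentation, power STFT (25 ms
  Hann window, 10 ms hop, hence a 15 ms overlap), a 128-band log mel filter
  bank (MSFB), optional 20-coefficient MFCC, and rendering to the model's
  112×170×3 image.
- **`dataset_prep`** — per-class stratified train/validation/test splitting
  and SMOTE oversampling (k = 5 neighbors) that raises every training class
  to the majority count by convex interpolation between same-class samples.
- **`classifier`** — the compact CNN: four conv–batchnorm–ReLU–pool blocks
  and a 48-unit dense block ending in an 8-way softmax, **204,256
  parameters** (203,648 trainable) at the 112×170×3 input; declarative
  layer specs with closed-form parameter counting, Adam training (batch 8,
  learning rate 3·10⁻³), and serialized export with optional int8 weight
  quantization. The network runs on a small built-in NumPy layer engine.
- **`sgan`** — the semi-supervised GAN variant: a generator mapping
  100-dimensional standard-normal latents to 112×168×3 images (15.7M
  parameters), and a dual-head discriminator sharing all weights with the
  classifier — `C_out = softmax(logits)` for the 8 species and
  `D_out = Z/(Z+1)`, `Z = Σₖ exp(logitₖ)` for real/fake. Per step the
  discriminator trains twice (real, fake) and the generator once.
- **`evaluation`** — per-class precision/recall/F1 (`F1 = 2PR/(P+R)`),
  macro F1, confusion matrices, and one-vs-one pairwise ROC/AUC with
  renormalized class-pair probabilities.
- **`edge_utils`** — streaming detection over 3-s segments, the
  `"code,lat,lon"` serial payload codec with ISO 8601 timestamps, and
  battery-life arithmetic for field deployments.

## Worked example

`examples/03_train_and_evaluate.py` generates an imbalanced 4-species
synthetic dataset (60/40/30/20 three-second segments), SMOTE-balances the
training partition, trains the compact CNN and prints:

```
dataset: 150 images, class counts [60, 40, 30, 20]
after SMOTE the training partition has class counts [43, 43, 43, 43]
model: 204,060 parameters (203,452 trainable)
epoch 1: train_loss=1.3257 val_loss=1.2755 val_acc=0.556
epoch 2: train_loss=0.7435 val_loss=1.1842 val_acc=0.259
epoch 3: train_loss=0.2310 val_loss=0.2799 val_acc=1.000
...
epoch 15: train_loss=0.0125 val_loss=0.0011 val_acc=1.000

test accuracy 1.000, macro F1 1.000
normalized confusion matrix (rows = true class):
[[1. 0. 0. 0.]
 [0. 1. 0. 0.]
 [0. 0. 1. 0.]
 [0. 0. 0. 1.]]
int8 export: 819,793 -> 221,567 bytes (73.0% smaller)
```

The parameter count differs slightly from the 8-class reference (204,256)
because the final dense layer here has 4 outputs. Perfect test accuracy
means the model recovered the four synthetic species' frequency bands; the
int8 artifact is what a field device would load. The other examples cover
call synthesis, the feature pipeline stage by stage, and the detection
payload/power arithmetic.

A thin CLI mirrors the library: `echoscope simulate|featurize|split|train|
evaluate|detect|battery` (see `--help`).

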