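# Methods

## The classification problem

Bat species differ in the structure of their echolocation pulses: the
frequency band (roughly 20–150 kHz for the species groups modeled here),
the sweep shape (downward frequency-modulated chirps, constant-frequency
tones, or an FM sweep with a CF tail), pulse duration (1–10 ms) and pulse
repetition rate (tens of milliseconds). A passive monitor converts each
fixed-length audio segment into a time–frequency image and assigns it to
one of 8 species with a convolutional network small enough for single-board
edge hardware.

## Synthetic data: what it emulates and what it does not

Real field recordings of bats are typically restricted, so the package
ships a parametric generator used by every test. Each species template is a
pulse train: a linear-FM, CF, or FM–CF pulse with a Hann (or rectangular)
amplitude envelope, optional harmonics at 1/h amplitude, repeated every
inter-pulse interval, synthesized natively at 384 kHz. Harmonic content
that would exceed the Nyquist frequency is masked rather than aliased.
White Gaussian noise is added so that `10·log10(P_signal/P_noise)` over the
pulse regions equals the requested SNR (default 20 dB — a clearly audible
but non-trivial noise floor). The eight default templates span 20–150 kHz
with partially overlapping bands; they are fixture constants, not claims
about real species.

The generator reproduces the statistical structure the classifier relies on
(species-specific spectral placement and timing, class imbalance up to the
~60:1 skew of real monitoring archives, deterministic seeding) but not the
acoustics of real recordings: no atmospheric attenuation, Doppler, echoes,
within-species call variation, or non-stationary noise. Passing tests
therefore demonstrate that the pipeline and models are implemented
correctly and can recover separable spectral classes — not field-level
accuracy on real bats.

## Feature pipeline

Order is fixed: STFT first, then mel filters, then (optionally) a DCT.

1. **Rate relabeling, not resampling.** A 384 kHz recording is reinterpreted
   at a nominal 44.1 kHz with the samples untouched (time expansion): a
   160 kHz component reads as 160·(44100/384000) ≈ 18.4 kHz. The call
   pattern shifts into the audible band without its shape changing.
   Anti-aliased resampling would instead delete all ultrasonic content.
2. **Segmentation** into 3-s windows on the relabeled time axis:
   `round(3 · 44100) = 132300` samples per model input.
3. **STFT**: periodic Hann window of 25 ms (1102 samples), hop 10 ms
   (441 samples) — a 661-sample ≈ 15 ms overlap — zero-padded to a
   2048-point FFT; power spectrum. Framing is "valid" (no padding), so a
   segment yields exactly `1 + floor((132300 − 1102)/441) = 298` frames.
   Centered framing is available behind `FeatureConfig.center`.
4. **MSFB**: 128 triangular filters on the Slaney mel scale spanning
   0–22.05 kHz, area-normalized, followed by `log(energy + 1e-10)`; the
   floor keeps silent frames finite.
5. **MFCC** (optional): orthonormal type-II DCT along the mel axis, first
   20 coefficients kept.
6. **Image rendering**: per-image min–max normalization to [0, 1], viridis
   colormap lookup to 3 channels, vertical flip (low frequencies at the
   bottom), bilinear resize to 112×170. A constant matrix maps to the
   colormap midpoint. The published input shape fixes 112×170×3 but not
   the resize/colormap convention; this choice is isolated behind
   `render_input_image`.

## Dataset preparation

The stratified split takes `round(test_frac · n_c)` test samples per class
and `round(val_frac · remainder)` validation samples (nearest integer,
half up). Defaults are `test_frac = 0.10`, `val_frac = 0.20`: these
reproduce the reference per-species table exactly (its test column is ~10%
of the totals, even though the accompanying text says 20% — the table
arithmetic wins here and both fractions are configurable). Classes too
small for three partitions allocate to test first, with a warning.

SMOTE raises each training class to the majority count. Synthetic vectors
are `x_i + u·(x_nn − x_i)` with `u ~ U[0, 1)` and `x_nn` one of the k = 5
nearest same-class neighbors (k reduced to `class_size − 1` for tiny
classes; singletons duplicate with a warning). Interpolation happens on
flattened image vectors: [0, 1]^d is convex, so every synthetic sample is a
valid image. Only the training partition is ever oversampled.

## The compact CNN

Blocks: conv(56, 7×7, stride 2) → BN → ReLU → maxpool(2) → spatial dropout;
conv(72, 5×5, stride 2) → … → avgpool(2); conv(56, 3×3) → … → avgpool(2);
conv(72, 3×3) → … → avgpool(2); flatten(432) → dense(48) → BN → ReLU →
dropout → dense(8) → softmax. All convolutions use `same` padding; pooling
is ceil-mode `same` (this is what maps an 85-wide map to 43). Kernel sizes
and strides are uniquely determined by the published output shapes and
parameter cells (e.g. 8288 = 7·7·3·56 + 56). Totals: 204,256 parameters,
203,648 trainable; the 608 non-trainable are the batchnorm running moments,
2·(56+72+56+72+48).

Dropout rates: 0.05 spatial after each conv block, 0.2 after the dense
block (configurable). Training: Adam, batch 8, learning rate 3·10⁻³,
sparse categorical cross-entropy, early stopping on validation loss
(default patience 10, max 100 epochs) with best-epoch weight restoration.
Batchnorm uses momentum 0.9 and eps 10⁻³; momentum 0.9 keeps inference
statistics usable after the few hundred steps typical of the small study
datasets here.

Export serializes the spec plus weights to an NPZ archive; optional
quantization stores ≥2-D weight tensors as symmetric per-tensor int8
(`scale = max|w|/127`), biases and batchnorm vectors in float32. The
unquantized round trip is bit-exact.

### The NumPy layer engine

The network runs on a purpose-built NumPy engine (`echoscope.nn`):
convolution, transposed convolution, batchnorm, ceil-mode pooling,
dropout variants, dense layers, Adam, and the two training losses. Layer
semantics follow the common TensorFlow conventions so the published shape
tables propagate exactly. Convolutions pick between three equivalent
evaluation strategies by problem size (one im2col GEMM when the patch
matrix is small, row-grouped GEMMs for dense stride-1 maps, a per-offset
loop otherwise); all paths are finite-difference tested against each
other and against numeric gradients.

## Semi-supervised GAN

The discriminator is the classifier backbone at a 112×168×3 input (real
images are center-cropped two columns so generator outputs can be fed back
directly; the 168-wide variant has the same 432-unit flatten and the same
parameter total). Its two heads share every weight including the final
dense layer: `C_out = softmax(logits)` over the 8 classes, and
`D_out = Z/(Z+1)` with `Z = Σ exp(logits)` — a sigmoid of the logsumexp,
the standard shared-logit real/fake squashing; it is strictly increasing
in every logit and bounded in (0, 1). `D_out` trains with binary
cross-entropy, `C_out` with sparse cross-entropy on the labeled subset.

The generator maps a 100-dimensional standard-normal latent through a
dense layer to 28·42·128 = 150,528 units, two 4×4 stride-2 transposed
convolutions (128 filters each), and a 7×7 convolution to 3 channels
(kernel sizes recovered from the published parameter cells: 262,272 =
4·4·128·128 + 128 and 18,819 = 7·7·128·3 + 3). A final sigmoid bounds
outputs to the [0, 1] image range; LeakyReLU slope is 0.2 (GAN
convention).

Per training step: (1) discriminator update on a real batch — `D_out`
target 1 plus the supervised loss on labeled members; (2) discriminator
update on a generated batch — `D_out` target 0; (3) generator update
through the frozen discriminator — `D_out` target 1. The same fake batch
serves steps (2) and (3). The full real set feeds `D_out` while only the
stratified `labeled_fraction` subset feeds `C_out`; setting
`unlabeled_reals=False` restricts training to the labeled subset entirely.
SMOTE is not applied in the semi-supervised setting, which models label
scarcity, not class imbalance.

Because both heads share the final dense layer, the `D_out` binary
cross-entropy gradient is proportional to the softmax — it acts mostly on
the currently-largest class logit and can thrash the class ranking when
the adversarial game is unbalanced (the 15.7M-parameter generator adapts
much faster than the 204k-parameter discriminator; left unchecked it
saturates `D_out` on fakes and the resulting full-magnitude gradients
collapse the supervised head to chance). Three standard stabilizations
keep the supervised task primary: Adam β₁ = 0.5 for both players (GAN
convention), a slow generator (learning rate 5·10⁻⁵ vs the
discriminator's 10⁻³), and a weight of 0.2 on the two `D_out` losses
relative to the supervised loss (the method fixes the loss types but not
their relative weights). The supervised loss is averaged over the labeled
members of each real batch at full strength, so a lower labeled fraction
reduces the diversity of the supervised signal, not its magnitude — label
scarcity then shows up as overfitting, which is the phenomenon the
labeled-fraction experiment measures.

## Evaluation

Precision, recall and F1 are per class, with the 0/0 convention → 0;
the headline F1 is the unweighted (macro) mean, the conservative choice
under class imbalance. "Pairwise ROC" is one-vs-one: for a pair (a, b)
only samples of those classes enter, scored by `p_a/(p_a + p_b)`
(defined as 0.5 where both vanish), and AUC is the Mann–Whitney rank
statistic with midrank tie handling — verified in tests against O(n²)
pair enumeration.

## Edge utilities

Detection runs the feature pipeline over consecutive 3-s segments and
emits an event whenever the top class probability exceeds a threshold
(default 0.5; threshold 0 emits every segment). The wire payload is the
minimal `"code,lat,lon"` string; the ISO 8601 timestamp is attached at
decode time, mirroring a transport that carries no clock. Battery life is
`floor(capacity·voltage / power)` hours with an additional derating factor
(default 0.5) for CPU-usage variability: 528 mA at 5 V on a 50 Ah bank
gives 250 Wh / 2.64 W → 94 h, derated 47 h.

## Study problem sizes

The training checks run on deliberately small studies chosen for a single
CPU: the supervised study uses 4 species with well-separated bands, 100
three-second segments per class at 20 dB SNR, a 10%/20% stratified split,
and at most 30 epochs (early stopping, patience 4); the semi-supervised
study uses a pool of 24 segments per class of which a stratified 20% forms
a shared validation set, real batch 8 / fake batch 4, and 6 epochs per
labeled fraction (1.0, 0.5, 0.25) with a shared seed and split,
restoring each run's best-validation-epoch discriminator. The acceptance
script reruns both studies from scratch at these sizes.

## Known limitations

- The synthetic generator's realism limits (above) mean accuracy numbers
  here say nothing quantitative about real field data.
- Rate relabeling assumes the native rate is known and ≥ the target rate.
- The SGAN study at desk scale shows the qualitative labeled-fraction
  trend for the fixed study seed; across seeds, run-to-run variance at
  this problem size is comparable to the fraction effect itself, so
  individual reruns with other seeds can show a flat or noisy picture.
  GAN sample quality is out of scope and unmeasured.
- The engine is single-threaded NumPy: adequate for the study sizes, not
  for large-scale training.
- Hyperparameter search is out of scope; the architecture and training
  constants are fixed.
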