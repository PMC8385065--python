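# Methods

This note records the models implemented, the choices made where the design
was genuinely open, the numerical conventions, and what the synthetic data
does and does not establish.

## Pipeline and conventions

**Standardization.** Clips are mixed down to mono (channel mean), resampled
with a polyphase resampler, and truncated to the first `target_len` seconds
(default 7 s at 32 kHz). Shorter clips are rejected with an error carrying
the clip id, mirroring the curation rule that recordings shorter than the
standard length are ignored.

**Sliding windows.** With window `Ws` and hop `Hs` (defaults 500/250 ms) a
clip of `T` ms yields `n = ⌊(T − Ws)/Hs⌋` slides; slide `k` covers
`[k·Hs, k·Hs + Ws)` (0-based). The convention drops the final
partially-usable start offset: it is the unique simple rule that yields the
pipeline's canonical 26 slides for 7 s at (500, 250) — the naive
`⌊(T − Ws)/Hs⌋ + 1` would yield 27. The same `k·Hs` map aligns memory-trace
columns with spectrogram time in the rendered figures.

**Mel spectrograms.** Hand-rolled (no audio DSP package in the dependency
set): centred STFT framing with Hann windows and reflect padding, so a
window of `L` samples gives `1 + ⌊L/hop⌋` frames (500 ms at 32 kHz with
hop 512 → 32 frames); triangular filters on the HTK mel scale
(`m = 2595·log10(1 + f/700)`); power spectra. Whether magnitudes are
log-scaled before entering the CNN is an open choice; the default converts
power to dB relative to the per-slice maximum, floored at −80 dB, which is
standard practice and gives the models a bounded input range. Models
internally rescale dB inputs to `[−1, 1]`.

**Whole-clip images.** For the stand-alone baselines the whole-clip mel
spectrogram is bilinearly resized to 224×224 and replicated into three
identical channels; replication (rather than a colormap) is testable
channel-by-channel and adds no arbitrary palette.

## Models

Architectures are declarative token lists loaded from a config mapping, so
any alternative reading of the printed tables can be swapped in without code
changes. The three-column source table for the representation CNNs is
flattened in print and admits more than one column assignment; the
reconstruction used here (CNN1 ending `…128,128,128, AAvgPool`; CNN2 ending
`…256,256,256, AAvgPool`; CNN3 ending `…512,512,512, AAvgPool`) reproduces
the published trainable-parameter counts for the small hybrids exactly
(e.g. CNN1+LSTM-S-1 = 1.2 M), which is the strongest available consistency
check. Every conv is 3×3 with bias, followed by batch-norm and ReLU; max
pools halve both axes; the final adaptive (2,1) average pool makes the
feature length input-size independent (CNN1→256, CNN2→512, CNN3→1024).

Temporal CNNs consume the concatenated per-slide features as a one-channel
2-D map (feature dimension × slide index) and end with an adaptive (1,1)
average pool so the head input is architecture-independent; whether the
original pipeline pooled or flattened here is unstated, and pooling is the
choice that keeps the head size fixed.

Recurrent cells follow their printed update equations literally. Two
consequences worth flagging:

- the LSTM candidate `c̃_t` passes through the logistic σ in the default
  `"paper"` mode (the conventional tanh candidate is available as
  `mode="standard"`), since which variant produced the published results is
  unknowable;
- the LMU drive `u_t` uses the *incoming* memory `m_{t−1}`, the memory is
  updated first, and the hidden state reads the fresh memory — the original
  delay-network construction's ordering.

The GRU+LMU combination stacks GRU layers below a single LMU top layer
(GRU as feature smoother feeding the memory) and requires ≥ 2 layers.
Initialization is Xavier-uniform for kernels, zeros for biases; LMU encoders
start with `e_x` uniform-scaled and `e_h = e_m = 0`. All initialization is
seeded and bit-reproducible.

The classification head is one 512-unit ReLU layer, dropout 0.5 (train mode
only), and an `n_classes` softmax output; training uses logits with
cross-entropy for numerical stability. RNN outputs are summed over all
time-steps before the head.

Stand-alone baselines (VGG16, ResNet18, ResNet50) are built internally from
their standard published layer configurations with the final layer resized
to the class count, and are treated as opaque baselines. The VGG16
construction counts 138,357,544 trainable parameters with a 1000-class head,
matching the published architecture exactly. The published complexity table
is embedded as reference data and `report_table2` prints recomputed counts
beside it with deltas; it is diagnostic, not asserted, because of the table
ambiguity above and because the published ResNet18 count (14 M) exceeds any
standard 100-class ResNet18 (~11.2 M), suggesting an undocumented head
modification.

All layers (conv via im2col + BLAS matmul, batch-norm, pooling, linear,
dropout, BPTT for all three cells) carry hand-written analytic backward
passes, each verified against central differences in the test suite.
Checkpoints capture trainable parameters *and* batch-norm running
statistics; restoring the best-validation checkpoint reproduces its
validation accuracy exactly.

## Legendre memory: projection vs recursion

The continuous delay system is
`A[i,j] = (2i+1)/θ · (−1 if i<j else (−1)^{i−j+1})`,
`B[i] = (2i+1)(−1)^i/θ`. Discretization is zero-order hold by default
(exact for piecewise-constant drive, computed via one augmented matrix
exponential, so no explicit inverse of `A` is formed; the spectral radius of
`Ā` stays ≤ 1 for all tested `d ≤ 64`, `dt ≤ θ`); forward Euler is retained
for hand-checkable examples. The window length θ is not published for the
trained models; the default sets θ to the full sequence duration (26 steps,
`dt` = 1 step), the smallest window consistent with memory traces that
persist across the whole clip.

The *direct oracle* `project_history` maps the history window onto the
polynomial domain [−1, 1] with the **most recent sample at −1** (absolute
time `s ↦ 2(t−s)/θ − 1`) and integrates the staircase signal against each
polynomial by Gauss–Legendre quadrature, returning least-squares
coefficients (the `(2m+1)/θ` normalization included). That orientation is
forced by the delay-system construction itself — the input enters through
`B ∝ P_m(−1)` — and is the one under which the recursion reproduces the
oracle; the mirrored map would flip the sign of every odd channel. The
projection as literally printed (`∫₀ᵗ f(x)P_m(x)dx` with the raw time axis
as polynomial argument) is available behind `literal=True`, defined only
while `t ≤ 1`.

The recursion and the true windowed projection are *not* identical at finite
d: the delay system replaces the (zero) signal value leaving the window with
its truncated-basis reconstruction, so the gap is a Gibbs-type edge term
that shrinks with probe smoothness and with d. With the default Hann-shaped
probes (onset n/8, width n/3 — the geometry of the simulated-pulse figures)
at d = 64 the global disagreement is below 1%, and each channel agrees
within 5% of its own range, with a 1%-of-trace-scale absolute floor for
channels the probe barely excites (whose coefficients are numerically ~0, so
a pure ratio there is ill-posed). Sharp rectangular probes degrade this
agreement markedly; that is a property of the delay approximation, not of
the implementation. Both traces are *exactly* zero before pulse onset: no
history, no projection.

## Synthetic data

Each class calls at a deterministic centre frequency `f0 + i·Δf`
(f0 = 2 kHz, Δf = 1.2 kHz, bandwidth 400 Hz) with `1 + (i mod 3)` pulses per
clip; onsets, durations and amplitudes jitter per clip from a substream
keyed by (class, clip index), so enlarging a dataset never changes existing
clips. Pulses are Tukey-windowed tone bursts (raised-cosine edges keep the
energy inside the declared band, making the spectral-locality property
assertable) with slow sinusoidal FM inside the band, over a white Gaussian
floor clipped to [−1, 1]. The noise RMS default is 0.01 (≈30 dB SNR at
default pulse amplitudes) — the real corpus's SNR regime is unpublished, so
this is a free parameter chosen to resemble a reasonable field recording.

What the generator emulates: band-limited tonal pulses of variable onset,
count and rhythm over a noise floor, with class identity carried by the
spectro-temporal pattern. What it does not emulate: harmonic stacks,
syllable grammars, overlapping vocalizers, reverberation, or non-stationary
background. Tests passing on this data therefore establish that the
pipeline is mechanically correct and can learn spectro-temporal class
structure; they say nothing about accuracy on real field recordings, and
the published corpus-scale accuracy table is out of reach at desk scale by
design.

## Training and evaluation

Stratified 80/10/10 split; 5 stratified folds rotate the validation part
within the 90% non-test pool while the 10% test part stays fixed (the
fold–split interaction is under-specified in the source protocol; this
reading keeps test data untouched across folds). Adam at learning rate 1e−4
for up to 50 epochs, batch size 32 (unpublished; 32 fits desk memory), the
max-validation-accuracy checkpoint selected with ties to the earliest epoch.
Argmax ties break to the lowest class index. An optional `target_val_acc`
stops training once a validation-accuracy target is reached.

The learnability demonstration uses the package's own desk-scale problem
size: 150 clips (3 classes × 50) of 2 s at 16 kHz, 64 mel bands, FFT 1024 —
6 slides of 64×16 per clip — with CNN1+GRU (hidden 128, 1 layer), batch 16,
learning rate 1e−4, at most 20 epochs. Across seeds this reaches ≥ 93%
validation accuracy within 4 epochs (~1–2 minutes on one CPU core). The
paper-geometry facts (26 slides, 128×32 slices) are asserted separately at
full scale.

## Known limitations

- Single-label classification only; no multi-species detection.
- No data augmentation (rotation/flip-style augmentation is not meaningful
  for spectrograms) and no denoising or bird-activity detection.
- The numpy engine is single-threaded BLAS-bound; it is built for
  correctness and desk-scale experiments, not corpus-scale training.
- t-SNE perplexity defaults to 30 (capped at (n−1)/3 for small sets), seeded;
  embeddings are reproducible but, as always with t-SNE, distances between
  far clusters are not quantitatively meaningful.
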