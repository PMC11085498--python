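# Methods

## Problem and model

`emgfuse` classifies hand gestures from two synchronized sensing
modalities: 12 channels of surface EMG (sEMG) and 36 channels of
accelerometry (a tri-axial accelerometer on each of the 12 electrodes),
recorded in the NinaPro DB2 layout at 2 kHz.  Classification operates on
short sliding windows — 200 ms by default, advanced by 50 ms — so a
deployed decoder stays within the ~300 ms latency budget of myoelectric
control.

The classifier is a two-stream convolutional network.  Each modality's
window enters its own branch as a single-plane image of shape
(signal channels × time samples), so 3×3 convolutions integrate both
along time (signal morphology) and across electrode channels (spatial
muscle-activation structure).  Branches are stacks of residual blocks

    y = ReLU(F(x) + x),    F = Conv-BN-ReLU-Conv-BN,

with a strided 1×1 projection on the shortcut whenever the shape
changes.  Because ∂y/∂x = ∂F/∂x + I, gradients reach shallow layers even
when the residual path saturates; the suite verifies this numerically
(the backward pass of a zero-residual block is exactly the identity).

Each branch ends in global average pooling (GAP), producing one value
per feature channel.  The pooled length-C vector is re-weighted by
efficient channel attention (ECA): a single 1-D convolution of odd
length k shared across channels, followed by a sigmoid,

    ω = σ(C1D_k(g(χ))),    attended_c = ω_c · g(χ)_c,

with k the nearest odd integer to log2(C)/γ + λ/γ (γ=2, λ=1; ties
between equidistant odd integers resolve downward, so C=512 → k=5 and
C=64 → k=3).  The two attended vectors are concatenated, passed through
one fully connected hidden layer with ReLU, dropout 0.5, and a softmax
over the gesture classes.

Two branch presets exist.  `full` follows the ResNet-18 layout — four
stages of two residual blocks with widths 64/128/256/512 — and
reproduces the canonical stage output sizes 56/28/14/7 on a 224×224
probe.  Because a 12×400 EMG window would be collapsed by the
image-style 7×7-stride-2 stem, signal-shaped inputs use a stem that
strides and max-pools along the time axis only; inputs at least 64 rows
high are treated in image mode.  `small` is a two-stage desk-scale
variant (widths 16/32, 3×3 stem, no stem pooling) used for CPU
experiments and the test suite.

## Preprocessing

Order is fixed: filter → normalize → segment.

1. **Bandpass filter.**  Fourth-order Butterworth, 10–500 Hz, applied
   identically to EMG and ACC.  Application is forward–backward
   (zero-phase) by default so the two streams suffer no relative phase
   skew; a causal mode exists for real-time emulation.  For sessions
   sampled below 1 kHz the high edge drops to 0.45·fs (the 500 Hz edge
   would otherwise sit above Nyquist).
2. **Z-scoring.**  Per-channel mean and standard deviation are fitted on
   *training-split samples only* and applied to both splits — no test
   leakage.  The population convention (divide by n) is used; at the
   sample counts involved the difference from n−1 is negligible.  A
   constant channel is an error naming the channel.
3. **Segmentation.**  Windows of L = T·F/1000 samples advance by
   Ld = S·F/1000; both must be exact integers, so the 200 ms/50 ms
   setting adapts automatically to down-sampled synthetic sessions
   (L=400/Ld=100 at 2 kHz, 100/25 at 500 Hz).  A signal of n samples
   yields floor((n−L)/Ld)+1 windows.  A window's label is the majority
   of its per-sample labels (ties toward the lower label); windows
   mixing rest (label 0) with movement are dropped, and a `strict`
   policy drops any mixed window.  EMG and ACC are windowed with
   identical offsets so the streams stay paired window-for-window.

Train/test partitioning is by movement repetition — repetitions
{1, 3, 4, 6} train, {2, 5} test — and windowing is applied per
contiguous run of each split mask, so no window straddles a split
boundary.  When a file carries both raw and movement-onset-corrected
annotations, the corrected ones (`restimulus`/`rerepetition`) are used,
which is the prevailing convention for DB2 classification; the choice is
recorded in the session metadata.  Rest is excluded by default (the
49-class task); it can be included, in which case the rest repetition
index 0 must be added to one of the split sets.

## Training protocol

Cross-entropy on one-hot labels (an ε = 1e-12 floor inside the logarithm
keeps saturated predictions finite), minimized by Adam with *decoupled*
weight decay 0.0005 ("weight decay factor" admits both readings; the
decoupled form is implemented and stated).  Decay applies to convolution
and dense kernels, not to biases or batch-norm parameters.  30 epochs,
batch size 256; gradients within a batch are accumulated over
micro-batches (default 32) purely to bound the im2col working set — one
optimizer step still covers 256 windows.  One tenth of the training
windows, stratified by label, form the validation set.  After any epoch
whose validation loss fails to improve (patience 1) the learning rate is
multiplied by 0.1, from 0.001 down to a floor of 1e-6, so the recorded
rate is always 0.001·0.1^d after d plateau events.  The monitored
quantity is validation loss (accuracy is configurable).  No early
stopping: all epochs run and the checkpoint with the best validation
accuracy is restored, ties resolved toward lower validation loss (an
early epoch can reach 100% validation accuracy on a small validation
set while still underfitting the training data).  Training is fully
seeded and single-threaded-deterministic; checkpoints restore
predictions bit-exactly.

The network is implemented directly in numpy (`emgfuse.nn`): im2col
convolutions, batch normalization with running statistics, max pooling,
dense layers, inverted dropout, the ECA 1-D convolution, and AdamW, all
with hand-written backward passes.  Every forward operation is checked
against explicit-loop oracles in the test suite, and gradients were
verified against finite differences during development.  Weights use
single precision; the functional oracle-facing APIs
(`eca_attend`, `residual_block_forward`, `global_average_pool`) compute
in double precision.

## Evaluation

Per-subject accuracy Acc is the fraction of correctly classified test
windows for that subject (window-level, not trial-level).  The overall
accuracy OA is the *unweighted mean of per-subject accuracies* —
subjects, not windows, are the unit of aggregation.  Confusion matrices
are indexed (true, predicted).  Subjects are modeled individually
(train/test per subject, then averaged); pooled cross-subject training
is out of scope.

The ablation harness sweeps conditions × window lengths × seeds:
`emg-only` and `acc-only` (one branch + ECA + head), `fused` (the full
two-stream model; `fused+eca` is an alias), and `fused-attention`
(fusion with ECA removed, isolating the attention contribution).  It
exports one row per (condition, T, seed) so significance testing can be
done externally; ANOVA/post-hoc machinery is deliberately not included.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not muscle physiology.  Per gesture class g:

- **EMG** is amplitude-modulated band-limited Gaussian noise — the
  standard phenomenological picture of an interference EMG — with a
  class-specific gain per channel (`emg_pattern[g]`, uniform in
  [0.5, 2]).  The carrier band is 20–450 Hz at 2 kHz, scaled
  proportionally at lower rates.  Rest is low-amplitude noise
  (σ = 0.05).
- **ACC** is a class-specific sum of two tones with per-channel
  amplitudes (`acc_pattern[g]`), placed at 12–40 Hz — deliberately above
  the filter's 10 Hz low edge, because the pipeline applies the same
  bandpass to both streams and the class information must survive it —
  plus Gaussian noise at 10 dB SNR during movement.

The schedule copies the acquisition protocol: each class repeated six
times, movement followed by rest, with per-sample stimulus/repetition
annotation.  The protocol-default config is 8 classes × 6 × (5 s + 3 s)
at 2 kHz (768 000 samples); the *desk preset* keeps the class and
repetition structure but shrinks to 500 Hz and 1 s/0.5 s blocks so a
full train/evaluate cycle runs on one CPU in minutes.  Sessions are
deterministic given (seed, subject id) and serialize to the same `.mat`
dialect as real recordings.

A *split-information* mode makes half the classes separable only
through EMG (they share one ACC signature) and the other half only
through ACC.  A single-stream model is then structurally capped near
(h + (n−h)/2)/n accuracy (75% for n=4) while the fused model can reach
100% — a designed, qualitative counterpart of the single-stream versus
two-stream comparison on real data.

**What passing these tests does not show:** the synthetic classes are
linearly separable in channel-energy space by construction (a
nearest-centroid baseline already beats 3× chance), so success here
demonstrates that the pipeline, model and training loop are correct and
that fusion integrates complementary modalities — not that the
architecture reaches any particular accuracy on real sEMG, which has
inter-subject variability, electrode shift, fatigue and far subtler
class structure.

## Problem sizes and numerical choices

- Desk-scale end-to-end run: 8 classes, 544 train / 272 test windows of
  100 samples, `small` preset (~34k parameters), 30 epochs — the
  configuration used by `scripts/acceptance.py` and the end-to-end test.
- Fusion ablation: 4 classes split-information, 15 epochs per condition,
  seeds 1–3.  Fifteen epochs suffice for convergence at this size and
  keep the 9-run sweep tractable.
- Batch-norm: batch statistics in training, running averages (momentum
  0.9) at inference.  ε = 1e-5.
- 'Same' convolution padding is asymmetric (extra sample on the
  bottom/right) exactly as in common DL frameworks; the loop oracles in
  the tests replicate it independently.
- Majority-label ties break toward the lower label index; empty signals
  shorter than one window yield an empty window set with a warning
  rather than an error, so short rest fragments are tolerated.
- The ECA kernel formula is the original adaptive rule
  |log2(C)/γ + λ/γ| rounded to the nearest odd integer with downward
  tie-break and a floor of 1.
- The fusion head's hidden width defaults to max(64, fused/4); it is not
  pinned by the reference architecture description and is configurable.
- Branches share no parameters.

## Known limitations

- No physiological motor-unit simulation, no inter-subject domain shift,
  no electrode-shift or fatigue modeling in the generator.
- The 10–500 Hz bandpass applied to real DB2 accelerometry would remove
  most gross-movement (sub-10 Hz) content; the generator sidesteps this
  by construction, and whether the choice is optimal on real data is an
  open question the package does not answer.
- Pooled cross-subject training, SE-Net comparison baselines and
  significance testing are out of scope.
- Training is CPU-bound numpy; the full ResNet-18-scale preset trains
  only at toy sizes on one core (it is exercised for architecture
  audits and forward passes, not full protocol runs).
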