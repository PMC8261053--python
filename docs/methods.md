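# Methods

## Harmonization

Every recording is mapped to a 20 × T matrix at 256 Hz.

**Scaling scope.**  The per-sequence rescale to ±1 uses one weight and
offset across *all* channels of the sequence, not per channel.  This
preserves inter-channel amplitude ratios (which carry spatial information,
e.g., lateralized band power) and keeps the amplitude channel — the ratio
of the sequence's range to the dataset's global range — meaningful.  A flat
(constant) sequence scales to all zeros and is flagged degenerate; zero is
already the missing-channel sentinel.  Amplitude values above 1 (possible
when dataset statistics were estimated on a subset) clamp to 1 with a
warning.

**Canonical montage.**  The 19 electrodes of the reduced 10/20 set, in a
fixed order using modern temporal-chain names (T7/T8/P7/P8), with
case-insensitive matching, legacy aliases (T3→T7 …), and bipolar names
mapped by their first electrode (FPz-Cz→FPz).  Fpz and Oz have no dedicated
row; they land on the nearest canonical electrode (Fp1, O1 respectively) so
two-electrode sleep montages still populate two rows.  Row 19 is the
amplitude constant.

**Resampling.**  Integer step first: enumerate whole multiples (rate below
target) or divisors (above) of the source rate and take the one nearest
256 Hz, ties toward the higher rate; the integer step is sample repetition
or decimation.  Nearest-neighbor interpolation then maps output index j to
input index round(j·f_in/f_out), half-up.  Duration is preserved within one
output sample for every rate in the supported pool.  When source content
exceeds the target Nyquist, a zero-phase FIR low-pass below 120 Hz
(transition band 10% of cutoff, applied forward-backward) runs first.
Indexing is 0-based, windows half-open, second→sample conversion floors.

**Windows and trials.**  Pre-training uses non-overlapping 60 s windows
(15,360 samples at 256 Hz; shorter windows are a config choice at desk
scale).  Labeled trials are cropped at event onset + offset with a fixed
length; trials that would leave the recording are dropped and counted.
Scaling for downstream trials is applied per extracted trial (the natural
reading of "per sequence"); this choice is isolated in one code path if a
sensitivity analysis is wanted.

## Encoder

Kernel size equals stride in every block, so receptive fields tile the
input without overlap and the output length is the composed floor division
of T by (3, 2, 2, 2, 2, 2); trailing samples are dropped.  Convolutions are
implemented as patch-reshape + dense projection (exactly equivalent), with
biases enabled, Kaiming fan-in initialization, GroupNorm (16 groups of 32
at full width; any divisor of the filter count is valid and the desk-scale
configs use 8 groups), and exact (erf-based) GELU.

## Contextualizer

BENDR dimension (512) and transformer model dimension (1536) are bridged by
learned linear projections at input and output, untied, so the contrastive
similarity is computed in BENDR space and classification heads consume the
512-d start-token output.  "Internal normalization removed" is implemented
as: no LayerNorm anywhere in the stack; trainability is restored by T-Fixup
scaling — Xavier baseline init, then value-projection, attention-output and
feed-forward weights multiplied by 0.67·N^(−1/4) (N = layer count; the
constant is exposed in the config since the exact prescription for a
conv-position hybrid is not fully determined).  Position is an additive
grouped convolution branch (receptive field 25, 16 groups, same-length zero
padding, GELU on the branch, no normalization), which keeps the whole
architecture sequence-length independent.  LayerDrop (p = 0.01) and dropout
(p = 0.15) act only when a training RNG is supplied; evaluation and
fine-tuning always run every layer with no rescaling.  The −5 start token
is prepended after masking and can never be masked.

## Pre-training

Span masking: every BENDR position independently starts a span of 10 with
probability 0.065; spans may overlap and truncate at the end.  The interior
masked fraction is therefore 1 − (1 − 0.065)¹⁰ ≈ 0.489.  A batch whose
plans mask nothing is resampled once, then skipped (negligible probability
at realistic lengths).  Negatives: 20 indices uniform *with replacement*
over the same sequence excluding the target index; the candidate set is
those vectors plus b_t.  The loss is −log softmax over the 21 candidates of
cossim/κ at the target, averaged per masked position across the batch; the
activation penalty is the mean squared entry of the full unmasked BENDR
(weight 1).  Ties in the accuracy argmax count as errors, so the measure
cannot be inflated by representation collapse.

Optimization: Adam with *decoupled* weight decay 0.01 (the reading of
"Adam with weight decay" consistent with the speech-model lineage this
follows), linear warm-up over 5% of steps (10% for fine-tuning) then
half-cosine decay to zero.  Peak learning rates are task-level
configuration: 1e-4 is the full-scale pre-training default; the desk-scale
experiments use 1e-3 (pre-training) and 2e-3 (fine-tuning), appropriate for
the much smaller widths.  Optimizer moments are checkpointed with the
weights, so runs resume; all randomness flows from one seeded generator.

## Evaluation and fine-tuning

The generalization protocol masks half the training budget with evenly
spaced spans: N_m = max(1, ⌊0.5·L·p_mask⌋) spans of 10 starting at 0,
spaced ⌊L/N_m⌋.  The formula is applied in BENDR steps, not raw samples —
spans "of 10" are BENDR spans, and the samples reading would demand ~499
spans on a 160-token sequence, which is impossible.

The six transfer variants are encoded declaratively (which stage loads
pre-trained weights, which is frozen, which head).  Freezing excludes a
sub-tree from the optimizer entirely, so frozen weights are bitwise stable.
Downstream regularization masks time spans of round(0.10·L) (start
probability 0.01 per position) with the *frozen* pre-trained mask vector
and zeroes contiguous feature spans of ⌊0.10·512⌋ = 51 (start probability
0.005 per feature), training mode only.  Class imbalance is handled by
re-drawing, every epoch, n_min points per class (uniform with replacement
for the larger classes).  Metrics: balanced accuracy (mean per-class
recall), plain accuracy, binary AUROC; chance levels 1/n_classes and 0.5
respectively; normalized metric (value − chance)/(1 − chance).  Confidence
intervals are percentile bootstrap over per-subject values, 1000 resamples,
0.95.  Subjects are assigned to folds atomically.

## Synthetic data

The generator emulates exactly the heterogeneity the pipeline must absorb:
per-subject sampling rates drawn from {100, 160, 250, 256, 2048} Hz,
montages cycling through the full 19-electrode set, a two-electrode
bipolar sleep pair, and a superset with auxiliary channels, and per-subject
amplitude scales in [0.5, 2].  Signals are sums of narrow-band oscillations
(band-pass-filtered noise at ~4, ~10, ~20 Hz) amplitude-modulated by smooth
random envelopes with 1–5 s timescales — slow enough that the ≈2.67 Hz
BENDR sequence carries predictive temporal structure for the contrastive
task — on top of 1/f noise synthesized with random spectral phases
(exponent 1).  Labeled trials embed a lateralized band-power effect (the
favored electrode's 10 Hz gain is `effect_size` times the suppressed one's);
effect size 1 is an exact null.  An independent band-power-ratio classifier
bounds detectability: at effect size 3 it exceeds 0.9 accuracy, at 1 it
sits in the binomial chance band — the latter guards the whole pipeline
against label leakage.

What this does *not* emulate: volume-conduction topographies, artifacts
(EOG/EMG), non-stationarity across sessions, or realistic inter-subject
variability.  Passing tests therefore demonstrate that the machinery
learns the structure it is pointed at, not clinical-grade performance on
real EEG.

## Desk-scale experiment sizes

The test suite exercises the full procedures at reduced width: encoder
filters 64 (GroupNorm groups 8), contextualizer 2 layers × 4 heads,
d_model 64, d_ff 128, 20 s windows, batch 2, 2000 pre-training steps.
Under these conditions contrastive accuracy on the structured corpus
reaches ~0.4 versus 1/21 chance, and fine-tuning variant 2 recovers the
effect-size-3 lateralized classes at BAC ≈ 0.89 within 20 epochs (32
trials per class, 4 s trials, 2 subject folds).  The null-effect check
pools predictions over three independently generated datasets and applies
a Bonferroni-corrected (family-wise 95%) binomial band across the six
variants, since six independent 95% tests would fail spuriously a quarter
of the time.

**Evaluation-length dependence.**  At full scale, contrastive accuracy is
reported to rise with evaluation length, attributed to nearby BENDR being
redundant (hard local distractors) while distant ones are distinct.  At
desk scale this trend *reverses* on the synthetic corpora (e.g.,
0.42/0.23/0.16 at 20/40/60 s on the fast-envelope corpus;
0.14/0.09/0.09 on the long-context corpus): the tiny encoder does not
over-resolve the synthetic signal, so local distractors are not especially
hard, and the evaluation protocol's masked budget — N_m grows linearly
with L — dominates, making longer sequences harder.  `length_sweep`
reports the full table either way; the directional claim should only be
expected where local representation redundancy actually holds.

## Numerical choices and limitations

* The autodiff engine is float64 throughout; gradients of every primitive
  and of the full contrastive loss are checked against central finite
  differences (1e-4 relative or better).
* Cosine similarities add 1e-12 inside the norm square root for gradient
  stability; exact zero vectors in candidate sets are rejected instead of
  silently regularized.
* The equation as printed in some descriptions of this loss places κ
  outside the exponential; the implemented form exp(cossim/κ) is the one
  consistent with the stated worked values and with standard InfoNCE.
* Checkpoints are a flat name→array container (.npz) with a schema version;
  loads with a different schema are rejected with a message.
* No quantization of BENDR, no codebook losses, no distributed training,
  no 2D spatio-temporal convolution variants: out of scope by design.
* The full-width architecture (512 filters, d_model 1536, 8 layers) is
  constructible but slow to train without accelerator support; the package
  is a desk-scale laboratory for the training scheme, not a production
  trainer for terabyte corpora.
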