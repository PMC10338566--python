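# Methods

## Task and data model

The unit of annotation is a half-open time interval `[start_s, end_s)`
carrying one of five frame classes; a video's intervals tile
`[0, duration_s)` with no gaps or overlaps, and frame `i` (0-based) at
`fps` frames/second lives at timestamp `i / fps`.  Half-open semantics
make per-frame counting exact: every frame belongs to exactly one
interval, and the per-class frame tally always sums to the frame count.
The five classes collapse onto inside/outside by a fixed total mapping
(`ABDOMINAL_CAVITY`, `TROCAR` → inside; `OUTSIDE`, `CLEANING`,
`TRANSLUCENT_TROCAR` → outside).  Unknown class tokens in annotation
files are hard errors: an anonymization pipeline must fail closed, not
coerce.

Annotation files are plain CSV (`video_id,start_s,end_s,label`) with a
JSON sidecar for video metadata.  Adjacent equal-label intervals are
merged on load rather than rejected, because annotation tools that work
in fixed-length sections split intervals at arbitrary boundaries;
normalization is idempotent.

## Classifier

Architecture: frozen convolutional feature extractor → dropout +
linear layer (the FC6 replacement) → single-layer unidirectional
stateless LSTM → dropout 0.5 → linear head with 2 or 5 outputs,
softmax per frame.  Inputs are 32-frame sequences of 224×224 frames,
bilinearly resized and normalized per channel with μ = [0.485, 0.456,
0.456], σ = [0.229, 0.224, 0.225] (configurable; note the third mean
component follows the printed source convention rather than the common
0.406).

Two backbones are registered.  `tiny_conv` is three frozen
He-initialized conv blocks (stride 4/4/2, global average pool, 64
features) with weights fixed by an internal seed — it is the desk-scale
feature extractor used by the test suite and the reference study, *not*
a stand-in for a trained network's representational power; random
convolutional projections preserve the color and coarse-texture
statistics that separate the synthetic classes.  `alexnet_pretrained`
runs the classic AlexNet feature stack (9,216 features) from a
user-supplied `.npz`; no download is attempted.  Backbone parameters
are excluded from training by construction, and the trainable set
(`fc`, `recurrent`, `head` by default; `head` alone as a strict mode)
is enforced by dropping gradients for everything else — a contract
tested bit-for-bit.

The head widths default to 4096/512 (fc/LSTM) for the AlexNet-scale
configuration and 256/64 for `tiny_conv`; with 64 input features a
4096-wide head would be pure overhead.

## Loss and training

Focal loss, mean over frames: `−α_y (1−p_y)^γ log p_y` with γ = 2 and
α = inverse class frequency normalized to mean 1 (a class absent from
training gets α = 0 and a warning).  γ = 0 with unit α reduces exactly
to cross-entropy, which is tested to 1e−9, and the analytic gradient is
verified against finite differences.  True-class probabilities are
clamped at 1e−12 so the loss is always finite.

Training is Adam (β = 0.9/0.999, ε = 1e−8), batch size 8 sequences,
exactly `epochs` (default 5) full passes, no early stopping or
schedule.  The default learning rate is 1e−3, Adam's canonical setting
for from-scratch training: although the backbone is pretrained/frozen,
the fc/LSTM/head stack is freshly initialized, and at desk scale a fold
sees only tens of optimizer steps — a fine-tuning rate of 1e−4 visibly
undertrains there.  The rate is a constructor parameter for users who
train larger heads longer.

One integer seed drives everything: fold assignment, weight
initialization, shuffling and dropout masks all derive from it, so two
identical runs produce bit-identical weights (a test asserts this).
The network is implemented in NumPy; convolution exists forward-only
(backbones are frozen), while linear, dropout and LSTM layers carry
full backward passes.  `mixed_precision` is accepted for API
compatibility and is a no-op on CPU.

## Sampling, sequences, folds

Frames are sampled at 1 frame/second for both training and evaluation
(timestamps `k / rate` for `k = 0 … ⌊duration·rate⌋−1`); evaluating at
native 25 fps would multiply compute ~25× for near-duplicate frames.
Sequences are non-overlapping 32-frame chunks; training drops a short
trailing remainder, inference pads it by repeating the last frame and
records the pad count so padded rows are excluded from metrics.  Labels
are taken at the sampled timestamp (point sampling), the simplest rule
consistent with per-frame annotation.

Cross-validation folds are built per video, never per frame.  Within
each operation type, videos sorted by descending duration are assigned
greedily to the fold with the smallest running total duration (ties to
the lowest fold index); the seed permutes only type order and exact
duration ties.  This is a reproducible stand-in for manual
stratification on operation type and total length; on 100-video rosters
the fold-duration max/min ratio stays below 1.25.  A leakage guard
asserts train/test video-id disjointness before any gradient step.

## Evaluation and the privacy report

Confusion matrices are counted over a fixed vocabulary (rows =
annotated, columns = predicted); the five-class matrix collapses onto
the binary one by summing under the class mapping on both axes, which
commutes exactly with collapsing the label streams first.  Per-class
metrics are one-vs-rest sensitivity, specificity, precision and F1;
zero-denominator ratios are reported as NaN, never 0.  Percentages and
F1 are displayed at two decimals; fold summaries use the sample (n−1)
standard deviation.

The privacy report scales the binary error rates to a video of given
length and outside share:

```
at_risk_s = duration × outside_fraction × (1 − sensitivity_outside)
lost_s    = duration × (1 − outside_fraction) × (1 − specificity_outside)
```

rounded to whole seconds for display.  `at_risk_s` is the breach
quantity — outside footage the classifier lets through; `lost_s` is
merely discarded data.  This asymmetry drives every fail-closed choice
in the package: exact score ties resolve toward the outside-mapped
class with the lowest index, and redaction aborts rather than guess
when labels and frames disagree.

## Redaction

Smoothing (`symmetric`): any maximal run strictly shorter than
`min_island_s` (default 2 s) whose two neighbors agree is reassigned to
the neighbors' label; edge runs are never touched; the rule iterates to
a fixpoint.  `privacy_safe` (default) applies the same rule but never
reassigns an outside run to inside — removing a spurious inside island
costs only footage, while flipping a genuine one-second outside glimpse
would be a breach.  Each 1 fps decision then governs all native frames
of its second (trailing frames inherit the last label), and outside
frames are censored as all-black (default) or by block-averaging with
blocks ≥ ⅛ frame width — pixelation rather than a convolutional blur so
that re-redacting an already-redacted video is exactly idempotent.
Black is stronger anonymization; blur retains temporal context for
reviewers and is documented as weaker.

## Synthetic data

The generator emulates the *structure* of out-of-body detection, not
surgical imagery: segment scripts are drawn as a renewal process whose
class probabilities are `fraction / mean_length`, so long-run time
shares match the requested class fractions (defaults 81.39 / 1.39 /
16.07 / 1.08 / 0.07%); mean segment lengths are 40 s (cavity), 15 s
(outside), 5 s (cleaning), 4 s (trocar) and 2 s (translucent trocar,
matching its characteristically brief episodes), each drawn uniformly
in [0.5, 1.5]×mean.  Appearance is a per-class mean color plus smooth
drifting texture: warm red cavity, dark circular vignette for the
trocar classes, cool drape/skin tones for the outside classes,
horizontal motion blur for cleaning, seeded per-frame noise, and a
linear cross-fade (default 0.3 s) at segment boundaries — transitions
being the empirically hard case, the generator must produce them; the
ground-truth label stays with the segment that owns the timestamp.

Defaults render at 160×90 / 5 fps for test-suite runtime, configurable
up to 960×540 / 25 fps.  An enforced separability floor (cavity and
outside mean colors differ ≥ 0.2 in some channel) guarantees a
mean-channel threshold classifier already reaches ≥ 95% — passing tests
therefore demonstrate that the *pipeline* (sampling, sequences,
training, evaluation, redaction) is correct and that the model can
exploit a learnable signal, **not** that the architecture reaches any
particular accuracy on clinical video, where class appearance overlaps
far more and annotation itself is ambiguous near transitions.

Videos are written as lossless multi-page TIFF stacks by default, so
decode–re-encode drift is pure uint8 quantization (< 1/255 per pixel);
MP4/AVI paths require an ffmpeg-capable imageio backend and otherwise
raise a codec error naming the container.

## Reference study sizes

The shipped end-to-end study uses 20 synthetic videos of 120–300 s at
160×90 / 5 fps, five folds, five epochs, binary task — small enough to
complete in minutes on one CPU while leaving every pipeline stage
non-trivial (multiple sequences per video, imbalanced classes, padded
final chunks, heterogeneous durations for stratification).  The
redaction audit decodes every anonymized held-out video and requires
zero uncensored frames among those predicted outside.

## Known limitations

- The synthetic appearance model is deliberately simple; results on it
  bound nothing about clinical performance.
- No data augmentation, no validation-based model selection, no
  learning-rate schedule: the training loop reproduces a fixed-epoch
  transfer-learning protocol.
- Bidirectional recurrence, attention variants, face detection and
  real-time capture integration are out of scope.
- Annotation ingestion is the plain interval CSV; annotation-tool
  project files are not parsed.
- The privacy report is an expectation under the given error rates and
  outside fraction, not a guarantee about any single video.
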