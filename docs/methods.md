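# Methods

## Problem

Resting-state EEG recorded from the three frontopolar electrodes (Fp1,
Fpz, Fp2) carries features that discriminate depressed from healthy
subjects, but EEG is strongly subject-specific: gain, baseline, noise
level and the individual alpha peak all vary between people, so a
classifier trained on known subjects faces a shifted distribution on a
new one.  The package treats this as unsupervised domain adaptation:
labelled windows from *source* subjects, unlabelled windows from a
*target* subject, one shared task (healthy vs depressed), different
marginal distributions.

## Pipeline

**Preprocessing.**  Each 3×T recording (250 Hz) is min–max normalized per
channel to [0, 1], trimmed to its 30–70% core segment (floor arithmetic,
0-based, half-open), filtered by a three-stage zero-phase Butterworth
cascade — 4th-order high-pass at 1 Hz, 2nd-order band-stop over
[48, 52] Hz, 4th-order band-pass over [0.5, 35] Hz — and cut into
contiguous non-overlapping 250-sample (1 s) windows.  Stage orders are a
package choice (the cascade's composed response is exposed and tested
against measured sinusoid gains).  Two ordering questions were genuinely
open and both orders are supported:

* *normalize before vs after trimming* — default normalizes first
  (`normalize_first=True`);
* *filter the whole core segment vs each 1-s window* — default filters
  the segment once, because filtering 250-sample snippets creates edge
  transients comparable to the window length; `filter_per_window=True`
  restores the per-window order for fidelity experiments.

Because the high-pass removes the mean, the filtered core segment is
re-normalized per channel (one affine map per recording, preserving
relative amplitudes across a subject's windows) before windowing, so
every window is in [0, 1] and ready to rasterize.  A constant channel is
a hard error, never silently mapped to 0.5.

**Image encoding.**  Windows become images by an integer Bresenham
polyline (1-pixel line, no antialiasing): value 1 → top row, 0 → bottom
row, sample index → column.  Two encodings:

* *merged chart* — all three traces over-drawn at intensity 0 on a 255
  background in one grayscale plane (no per-channel colours, so the
  classifier cannot key on colour);
* *RGB synthesis* — each channel's binary plane stacked as one of the R,
  G, B components (default Fp1→R, Fpz→G, Fp2→B; any permutation is
  configurable and simply permutes the planes).  Axes are never drawn in
  this encoding.

Every plane is exactly two-valued and byte-reproducible; `decode_rgb`
inverts the stacking bit-exactly.  The default canvas is 224×224 (the
conventional CNN input); the desk-scale benchmark uses 48×48.

**Backbone.**  A compact numpy network core (im2col convolutions, ReLU,
2×2 max-pool, fully connected head; explicit forward/backward passes,
float32, SGD with momentum 0.9, lr 0.01 decayed ×0.1 at 60% and 80% of
epochs, global gradient-norm clip at 50 that only binds on runaway
steps).  Backbones are partitioned into the three transfer stages:

* `smallcnn` (default): conv1–3 frozen, conv4–5 fine-tuned, fc6–8
  adapted;
* `resnet`: a small residual variant — stem + stages 1–2 frozen, stages
  3–4 fine-tuned, fully connected head adapted.  How a residual network
  maps onto the three-part scheme is this package's choice.

Frozen parameters are never updated (asserted bit-exactly after every
training run), which also allows their features to be computed once and
cached.  The frozen features are random projections, not pretrained
filters; with 32 KiB-scale datasets this is the honest desk-scale
analogue of "generic early layers".

**Adaptation losses.**  Per minibatch pair (equal-size source and target
batches, the smaller domain cycled):

* **DAN** — one biased-estimator MK-MMD term per adapted head layer
  (post-ReLU fc6, fc7 and the logits), Gaussian family with m = 5
  kernels, bandwidth ladder σ·{1/4, 1/2, 1, 2, 4} around the median
  pairwise distance, β fixed uniform (Σβ = 1, β ≥ 0; learning β is an
  extension point, not a default).  Bandwidths are recomputed from each
  batch by default (`kernel_per_batch=False` freezes them at
  initialization instead).
* **DANN** — a 2-layer domain discriminator on fc7 features behind a
  gradient-reversal layer (forward identity, backward ×−λ).
* **DeepCoral** — one covariance-alignment term
  (1/4d²)‖C_s − C_t‖²_F (sample covariances, n−1) per adapted layer.
* **source_only** — cross-entropy only; with λ = 0 every method's
  trajectory coincides with it exactly under the same seed.

Gradients of both losses are closed-form and verified against finite
differences to ~1e-8.

**λ defaults.**  The adaptation weight is unstated in the underlying
methods and matters greatly at this scale: λ = 1 on the *sum of three*
MK-MMD terms collapses the source fit entirely (features are pulled
together faster than the classifier can separate them).  The standard
benchmark therefore uses λ = 0.05 for DAN and λ = 1.0 for DANN and
DeepCoral (single or weaker terms), each ramped in as
λ·(2/(1+e^{−10p}) − 1) over training progress p.  `TrainConfig`'s
generic default stays λ = 1.0.

## Synthetic cohort

The generator emulates the statistical structure of a few-electrode
resting-state depression cohort, not its waveforms:

* per subject: band-limited alpha (±1 Hz around an individual peak in
  [8, 13] Hz), band-limited theta (4–7 Hz), a 1/f pink floor (sd 1 µV),
  50 Hz mains (0.5–3 µV), white sensor noise; the oscillatory sources are
  shared across channels through a fixed mixing matrix (neighbouring
  prefrontal electrodes are strongly correlated), white noise is
  per-channel;
* class effect: log-normal band powers (log-sd 0.3) whose means shift by
  `class_effect` standardized units — alpha down, theta up for the
  depressed class.  This is a configurable stand-in (reduced alpha /
  raised theta–alpha ratio is a commonly reported frontal signature),
  not a clinical claim; `class_effect=0` makes the classes identical by
  construction;
* subject shift: gain ~ logN(0, 0.25·s), baseline ~ N(0, 10·s) µV,
  noise sd ~ 2·logN(0, 0.5·s) µV, alpha peak ~ 10 + N(0, 1.5·s) Hz
  clipped to [8, 13], with s = `shift_sd`;
* one PCG64 stream per subject seeded by (cohort seed, subject index),
  so enlarging a cohort never perturbs existing subjects.

What passing tests on this cohort do *not* show: robustness to ocular or
muscle artifacts, non-stationarity within a recording, electrode
placement variation, or any real clinical effect size — none of these
are modelled.

## Evaluation protocol

Each group samples 8 healthy + 8 depressed subjects and splits them
7:1 (7+7 source / 1+1 target) or 4:4; source and target subject sets are
disjoint, so no target window can appear as labelled training data (an
audit test also asserts it).  Accuracy is per window (each 1-s image is
one prediction); a majority-vote per-subject accuracy is secondary.
Groups are drawn independently (subjects may recur across groups) and
summarized as mean ± sample sd (n−1) over groups.

## Desk-scale study conditions

Fixed in `eegtransfer.benchmark` and used by tests, examples and
`scripts/acceptance.py`:

| quantity | value | note |
| --- | --- | --- |
| recording length | 40 s | → 16 one-second windows per subject |
| canvas | 48×48 | backbone minimum is 32 |
| shift benchmark | class_effect 1.5, shift_sd 0.5, 7:1, 5 seeds | fresh 8+8 cohort per seed |
| benchmark epochs | 100 | convergence at this scale; the full-scale prescription (500) is scaled ~5× |
| null calibration | class_effect 0, 10 seeds, 50 epochs | 9+9 cohort, 8+8 source / 1+1 target |
| protocol | 29+26 cohort, 11 groups, 3 methods, 30 epochs | Table-shaped grid + mean ± sd |

With 1+1 balanced target subjects, even a degenerate one-class predictor
scores exactly 0.5, so the null calibration checks the *mean* over seeds
against a 95% band around 0.5 (binomial over all target predictions,
widened to the empirical between-seed standard error because windows
cluster within subjects).

## Numerical choices and edge cases

* biased MK-MMD clamps float round-off at 0 (the V-statistic is
  mathematically nonnegative); identical inputs give exactly 0;
* degenerate pooled features (median distance 0) fall back to bandwidth
  1.0 with a warning;
* prediction ties break toward the lower class index (healthy);
* windows shorter than 250 samples are discarded (a too-short segment
  yields an empty window set, not an error);
* rasterization clips trace values into [0, 1] and rejects NaN;
* `images_to_array` scales pixels by 1/255; training is float32
  throughout with a float64 accumulator for the clip norm.

## Known limitations

* Random frozen features stand in for pretrained early layers; absolute
  accuracies are far below what a pretrained full-scale backbone reaches
  on real data, and only method *orderings* at matched conditions are
  meaningful.
* Two-subject targets make per-group accuracy extremely high-variance
  (one atypical subject swings a group by ±0.5); conclusions rest on
  seed/group averages.
* β of the multi-kernel combination is not learned.
* The adversarial method can take occasional large steps; the global
  clip prevents divergence but a collapsed discriminator is still
  possible on unlucky groups.
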