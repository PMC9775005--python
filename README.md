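# eegtransfer

Cross-subject depression detection from few-electrode prefrontal EEG
(Fp1, Fpz, Fp2 at 250 Hz) using deep domain adaptation over
signal-to-image encodings.

EEG is strongly subject-specific — gain, baseline, noise level and the
individual alpha peak all differ between people — so a classifier trained
on known subjects faces a shifted distribution on every new one.  The
package treats a new subject as an unlabelled *target domain* and aligns
its deep features with the labelled *source* subjects during training.
It is aimed at researchers studying cross-subject transfer in
EEG-based computational psychiatry who need a fully synthetic, seeded,
CPU-scale testbed for the whole pipeline.

## What's inside

* **`cohort`** — a seeded generator of labelled 3-channel resting-state
  EEG with a configurable class effect (reduced alpha power, raised
  theta/alpha ratio in the depressed class), per-subject random effects
  producing real between-subject shift, 50 Hz mains and a 1/f floor;
  plain-text recording I/O and cohort manifests.
* **`preprocess`** — per-channel [0, 1] normalization, 30–70%
  core-segment selection, a zero-phase Butterworth cascade (1 Hz
  high-pass, [48, 52] Hz notch, [0.5, 35] Hz band-pass) and 1-second /
  250-sample windowing.
* **`encode`** — two binary image encodings of each window: the merged
  grayscale chart (three traces over-drawn, intensity 0 on 255) and the
  RGB synthesis (one channel per colour plane); deterministic integer
  rasterization, lossless PNG I/O, exact decoding.
* **`adapt`** — the multi-kernel maximum mean discrepancy

  d²ₖ(p, q) = ‖E_p[φ(xˢ)] − E_q[φ(xᵗ)]‖²_{H_k},  k = Σᵤ βᵤkᵤ, Σβᵤ = 1, βᵤ ≥ 0,

  with biased/unbiased estimators and closed-form gradients; CORAL
  covariance alignment; a gradient-reversal layer with domain
  discriminator; and a three-stage network (frozen early convolutions,
  fine-tuned middle convolutions, adaptation-regularized fully connected
  head) trained by minibatch SGD on a compact numpy network core.
* **`evaluate` / `benchmark`** — subject-level 7:1 and 4:4
  source/target splits, per-group window accuracy, multi-group
  mean ± sd summaries, and the frozen desk-scale benchmark conditions.
* **CLI** — `eegtransfer simulate | preprocess | encode | train |
  evaluate | report`, a thin wrapper over the library.

## Worked example

`examples/04_train_adaptation.py` trains one 7:1 group — 14 labelled
source subjects, one healthy + one depressed unlabelled target subject —
with and without MK-MMD alignment:

```
source subjects: ['H07', 'H02', 'H06', 'H05', 'H03', 'H04', 'H01', 'D02', ...]
target subjects: ['H00', 'D06']

 source_only: final target accuracy 0.500 (last-10-epoch mean 0.500, majority-vote subject accuracy 0.5)
         dan: final target accuracy 0.688 (last-10-epoch mean 0.688, majority-vote subject accuracy 1.0)
```

Source-only training collapses to one class on this target pair (0.5 is
exactly chance on a balanced target); the MK-MMD-adapted network
recovers above-chance window accuracy and classifies both held-out
subjects correctly by majority vote.  Target labels are used only for
scoring, never for gradients.  Single groups are intentionally
high-variance (two target subjects); method comparisons should use the
seeded benchmark (`examples/05_protocol_summary.py`), where MK-MMD
adaptation beats source-only training on average.

The other examples demonstrate the cohort generator and its spectral
class signature (`01`), the preprocessing + encoding chain (`02`), and
MK-MMD as a two-sample statistic, zero under equality and monotone in
the shift (`03`).

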