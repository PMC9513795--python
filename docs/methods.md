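# Methods

## Problem and model

Resistive-pulse sensors (solid-state nanopores here) report analyte
translocations as transient blockades of the open-pore ionic current.
`pulsedet` treats finding those pulses in a noisy trace as *direct set
prediction*: a temporal window of the trace is mapped, in one forward
pass, to a fixed-size set of N candidate detections, each a normalised
bounding segment (center c, width w, both in window units) plus a
pulse/no-pulse probability.  The mapping is a 1D adaptation of the
detection-transformer family:

1. **Backbone** — a residual 1D CNN with the ResNet-18 layout (7-wide
   stride-2 stem, max-pool, four stages of basic blocks, channel widths
   1x/2x/4x/8x the base width).  Cumulative temporal stride is 32, so a
   0.5 s window at 10 kHz becomes a sequence of 157 feature vectors.
   Normalisation is channel-group normalisation (batch-independent, so
   training and inference behave identically and runs are reproducible at
   batch size 6).
2. **Transformer** — a kernel-size-1 convolution projects the features to
   `hidden_dim`; a fixed sinusoidal positional encoding is added once;
   `Nenc` encoder layers (multi-head self-attention + feed-forward,
   post-norm residuals) produce the memory.  The decoder runs `Mdec`
   layers of self-attention over N learned query embeddings followed by
   cross-attention into the memory.
3. **Heads** — a single linear layer classifies each output embedding as
   pulse / no-pulse; a 3-layer feed-forward stack with a sigmoid output
   regresses (c, w).  Reported segments are (c - w/2, c + w/2), clipped to
   the window.  The width output's bias is initialised low (sigmoid ~ 0.02)
   because translocation pulses occupy a small fraction of a window;
   this removes an early training phase in which all proposals are
   window-sized.
4. **Pulse counter** — an independent residual CNN regressor (global
   average pooling + two linear layers) predicts the number of pulses in a
   window.  It gates inference only: windows counted as zero skip the
   detector entirely.  It never participates in detector training or
   validation.

All N candidates are produced in parallel; there is no autoregressive
loop, so runtime per window does not depend on how many pulses it holds.

## Training objective

Predictions and ground-truth pulses are matched one-to-one by the
Hungarian algorithm (scipy's linear-sum-assignment) on the pairwise cost

    cost = 1 * (-p_pulse) + 5 * L1((c, w)) + 2 * (1 - gIoU),

with gIoU the 1D generalised intersection-over-union (the hull-gap
penalty makes it informative for disjoint segments).  The loss is
cross-entropy over all N candidates (unmatched candidates are "no-pulse"
targets, down-weighted by 0.1) plus the L1 and (1 - gIoU) terms over
matched pairs, divided by the number of ground truths.  The matching is
computed on detached values; only the loss is differentiated.  The
coefficients are the detection-transformer convention; the minimum over
assignments and the gradient-flow contract are property-tested.

Optimisation is Adam (decoupled weight decay 1e-4), batch size 6, with a
step learning-rate schedule dividing the rate by 10 every decay period.
Validation runs on a schedule (first at epoch 50, again at 100, then every
5 by default; configurable for short runs, and always after the final
epoch) using the standard 1D-IoU mAP, and the checkpoint with the highest
validation mAP is kept — ties go to the later epoch, because in short runs
the strict IoU metric can sit at zero while localisation is still
improving.  The adapted mAP (below) is reserved for testing.

Two backbone regimes are exposed. With a *pretrained* backbone (the
`pretrain_backbone` pretext task regresses per-window pulse count and mean
width from pooled backbone features, mirroring how a two-branch
counting/feature network is pre-trained before reuse), fine-tuning uses
0.1x the main learning rate.  Training *from scratch* — the mode used in
the scaled-down runs — sets the backbone multiplier to 1.0: a starved
random backbone lets the transformer memorise training windows while
held-out performance collapses.

## Evaluation

- **Adapted mAP** — average precision where a score-ranked prediction is a
  true positive iff the distance between its midpoint and the matched
  ground-truth midpoint, as a percentage of the ground-truth duration, is
  strictly below a threshold; matching is greedy one-to-one in score
  order.  AP uses all-point interpolation of the precision-recall curve
  and excludes scenes without ground truths (AP is undefined there).  The
  adapted mAP averages over thresholds 100%..400% in 10% steps (31
  thresholds).
- **Coverage** — true positives / ground truths at a single threshold
  (default 100%).
- **Errors** — over matched pairs only: |duration error| relative to the
  true duration, and absolute start/end errors in ms (mean and sd).
- **Standard 1D mAP** — the COCO-style sweep (IoU 0.50:0.05:0.95) with a
  1D interval IoU, kept for comparison and used for validation.

## Synthetic data generator

A trace is baseline + noise - pulse train, all in pA at a configurable
sampling rate (default 10 kHz):

- **Amplitude physics** — volume exclusion: dG = G_pore d^3 / (D^2 L_eff)
  with L_eff = thickness + 0.8 D and open-pore conductance
  G_pore = sigma [4 L_eff / (pi D^2) + 1/D]^-1 (channel plus access
  resistance); sigma scales linearly with KCl concentration (1.28 S/m at
  100 mM).  Defaults: 20 nm pore diameter and thickness, 300 mV bias,
  100 mM KCl, -0.02 C/m^2 surface charge (the surface-charge field is
  carried in the configuration but does not enter the bulk-conductance
  formula).  dI = V dG; for a 10 nm sphere this gives ~162 pA against a
  ~2.3 nA open-pore current.
- **Events** — a homogeneous Poisson capture process with rate k c
  (k = 10 events/s per nM at 300 mV, scaled linearly with bias), each
  event exactly `event_duration` long; overlapping draws are rejected and
  redrawn so ground truth is uniquely matchable.
- **Pulse shape** — rectangular blockades low-pass filtered by a 4-pole
  Butterworth at the configured analog bandwidth (default 2 kHz),
  emulating the amplifier; ground truth keeps the unfiltered boundaries.
- **Noise** — Gaussian noise shaped in the frequency domain to
  S(f) = white + pink (f_ref/f) + dielectric (f/f_ref) (f_ref = 1 kHz),
  normalised to exactly zero mean and the requested rms.  SNR follows the
  nanopore convention amplitude / peak-to-peak noise; peak-to-peak of
  unbounded Gaussian noise is ill-defined, so it is operationalised as
  6x rms (the +-3 sigma span), making `calibrate_snr` deterministic and
  testable.
- **Baseline** — slow drift (white noise through a 2-pole low-pass at the
  corner frequency, rms-normalised) plus Poisson step jumps.  When no
  baseline model is given, defaults scale with the pulse amplitude: drift
  rms at half the amplitude below 1 Hz, jumps at 0.05 /s with rms equal to
  the amplitude.  Nothing in the source quantifies these; the defaults
  exercise both fluctuation kinds without drowning the pulses.
- **Grid** — the default dataset is the full factorial of 15 analyte
  diameters (3..17 nm) x 20 concentrations (log-spaced 0.01..1 nM) x 5
  durations (0.5, 1, 1.5, 3, 5 ms) = 1500 traces per SNR.

What the generator does *not* emulate: electrode/amplifier transfer
functions beyond a single low-pass, correlated event clusters, analyte
polydispersity within a trace, or the exact spectra of any published
dataset.  Tests passing on this generator show the method works when its
modelling assumptions hold; they do not certify performance on any
particular experimental record.

## Windowing and standardisation

Traces are cut into consecutive non-overlapping windows (default 0.5 s);
pulses straddling a boundary are attached truncated to both windows
(truncation keeps partial pulses detectable and windows independent;
whether the original pipeline dropped or truncated them is unknowable from
the text, and truncated edge slivers are among the hardest targets).
Each window is standardised to zero median and unit robust scale
(1.4826 x MAD), which makes the detector insensitive to the absolute
baseline level and to amplitude scale; a constant window gets a floored
scale and a flag.  Times are 0-based ms, windows half-open.

## Short-pulse compensation

A 0.5 ms pulse at 10 kHz spans 5 samples — too few for the convolutional
kernels and attention to latch onto.  `interpolate_linear` inserts 9
linearly interpolated points per gap ((p+1)(n-1)+1 samples, 10x effective
sampling rate), making the apparent duration 10x longer while leaving
ms-domain ground truth unchanged.  Because interpolation smooths the
noise, `add_compensation_noise` injects freshly synthesised noise with the
training spectral shape at half the amplitude measured on the first
pulse-free 50 ms stretch (ground-truth-masked when labels exist, otherwise
threshold-pre-screened), raising total noise power by 1 + 0.25 = 1.25x and
costing a factor 1/sqrt(1.25) in SNR (4 -> 3.58).  The compensated trace
is then processed with the detector trained at the matched original SNR,
using 5000-sample windows (now 50 ms of real time) so the pulse statistics
the model sees match its training regime.

The classical comparison detector thresholds the deviation below a
moving-median baseline at k x (MAD-estimated noise rms) for a minimum run
length; its score is the peak excursion ratio squashed monotonically into
[0, 1).  Its sensitivity to k is demonstrated in tests — the
user-dependence the learned detector exists to remove.

## Scaled-down study conditions

The source-scale experiment (hidden dim 512, 6+6 transformer layers, 25
queries, 60,000 training windows per SNR) is far beyond a CPU test
budget.  The repository's end-to-end runs (test fixtures and
`scripts/acceptance.py`) instead train a reduced detector — hidden dim 64,
1 encoder + 2 decoder layers, 4 heads, 10 queries, backbone base width 8
with one block per stage and stage strides (1, 2, 2, 1) — on an easy slice
of the grid: SNR 4, durations {3, 5} ms, eight diameters between 5 and
16 nm, concentrations {0.15, 0.2, 0.3} nM, 48 traces of 10 s cut into
0.25 s windows (500 train / 40 validation non-empty windows; held-out
evaluation on the non-empty windows of 48 fresh traces).  Optimisation:
lr 5e-4, decay /10 at epoch 90, 150 epochs, batch 6, from-scratch
backbone at the full rate.  These sizes are the package's own choice of a
study a laptop CPU can reproduce in minutes; the expectation they probe
is the qualitative one: near-perfect detection of long pulses at high
SNR, and a strict improvement from compensation on 0.5 ms pulses.

Two reduced-study choices deserve their rationale.  0.25 s windows halve
the per-step cost and double a pulse's relative width, which matters at
this model size; the full-scale default remains 0.5 s.  The backbone's
stage strides are relaxed to a cumulative stride of 16 because at stride
32 one feature vector spans 3.2 ms — as long as the shortest pulse in the
study — and the dominant residual error was localisation at exactly that
granularity; the full-size default keeps the classical stride-32 layout.

Known limitations of the reduced runs: adjacent pulses closer than a few
pulse durations are sometimes merged (query collapse in a small decoder),
boundary-truncated slivers are often missed, and occasional confident
false positives appear near baseline jumps.  All three shrink with model
and data scale.

## Numerical substrate

No deep-learning framework is assumed: `pulsedet.nn` is a compact
reverse-mode automatic-differentiation engine over numpy (broadcast
arithmetic, batched matmul, conv1d/maxpool1d, group/layer norm, attention,
Adam with decoupled weight decay).  Default dtype is float32; every
primitive's gradient is checked against central finite differences in
float64 in the test suite.  Determinism: all randomness flows through
seeded numpy generators; identical seeds reproduce identical traces
bit-for-bit and identical CPU loss curves to float tolerance.

Degenerate inputs: zero-weight noise models, zero-length segments,
windows longer than the trace, truths exceeding the query budget, and
scenes without ground truths all raise explicit errors rather than
returning silent defaults; constant windows standardise to zero with a
flag.
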