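# Methods

## Problem and approach

During multisensory stimulation therapy, a subject in a baseline behavioral
state (active AC, agitated AG, apathetic AP, relaxed RE) is stimulated with
the aim of inducing a behavioral-state change — typically from agitation to
relaxation. Autonomically regulated physiological signals (heart rate HR,
heart-rate variability HRV, respiration rate RR, blood pressure BP, skin
conductance GSR, plus an activity channel ACT) are not under voluntary
control and shift ahead of, or together with, the overt behavioral change,
so the change-prediction problem is posed as *one-class novelty detection on
multivariate 1 Hz time series*: fit a model of "normal" on the
pre-stimulation baseline phase only, then score the stimulation phase for
departure from it. No post-change data ever enters training, normalization
or thresholding — the detector must be usable causally, while the
stimulation is running.

Three detectors share this contract:

1. **Handcrafted features + one-class SVM.** Sliding windows are summarized
   by the 22 canonical time-series characteristics per channel, and a
   ν-parameterized one-class SVM is fitted on the baseline feature rows.
   The signed kernel margin is the change score (negated, so larger =
   more changed).
2. **BLSTM autoencoder.** A sequence autoencoder whose encoder and decoder
   are bidirectional peephole-LSTM blocks is trained to reconstruct
   baseline windows; the per-window reconstruction error
   RE = ½‖z − ẑ‖² is the change score. An autoencoder trained only on
   baseline patterns cannot reconstruct never-seen patterns, so RE rises
   after a genuine state change.
3. **Joint TCN + BLSTM autoencoder.** A residual temporal convolutional
   network is first pretrained with 4-class state supervision on a
   *separate* labeled cohort (in the original protocol: healthy volunteers
   simulating the four states), then briefly refined on the test session's
   baseline; its time-pooled last-block activations are the learned
   features. The autoencoder is trained on baseline activations and scores
   stimulation activations by RE. Supervision never touches the scored
   subject's stimulation data, so scoring remains unsupervised.

## Windowing and normalization

Sessions are standardized to `dS` seconds per phase (default 420 s = 7 min)
and cut into windows of duration `cW` ∈ {10, 15, 20, 30, 40, 50, 60, 70} s
at a 1 s step, giving `nW = dS − cW + 1` windows per phase (the inclusive
count; coordinates are 0-based half-open `[i, i+cW)`). Each window is
flattened channel-major. GSR acquired natively at 5 Hz is down-sampled to
1 Hz by 5-sample block means (mean rather than decimation, for noise
suppression).

Raw windows are z-scored per channel using the mean/sd of the *baseline
phase only*; stimulation windows are transformed with the same baseline
statistics. A channel with (near-)zero baseline variance has its sd floored
at 1e-8 with a logged warning. The same rule is applied one level up in the
joint detector: TCN activations are z-scored per dimension with
baseline-activation statistics (sd floored at 1e-6) before the autoencoder.
This second application is load-bearing: without it, baseline-only
refinement can collapse the activations of unseen inputs toward zero, which
a scale-free RE would read as "well reconstructed" and invert the score
ordering.

## The feature catalogue

`bscdetect.features` implements the 22-feature canonical catalogue in
numpy/scipy: histogram modes of the z-scored distribution (5 and 10 bins,
ties averaged), interpolated first 1/e crossing and first minimum of the
autocorrelation, even-binned automutual information (lag 2, 5 bins), the
time-reversibility statistic ⟨(Δx)³⟩, the proportion of successive
differences exceeding 0.04 (on the z-scored series), longest runs above the
mean and of successive decreases, the 3-letter transition-matrix covariance
trace (down-sampled at the first autocorrelation zero-crossing), a
spline-detrended autocorrelation periodicity measure (threshold 0.01),
the exponential-fit discrepancy of successive 2-d embedding distances,
the first minimum of the Gaussian automutual information (lags 1–40),
the forecast-residual autocorrelation ratio and rolling-3-mean forecast
error, positive/negative extreme-event median-timing drifts,
rectangular-window spectral area (lowest fifth) and centroid, the pair
entropy of a 3-letter equiprobable symbolization, and the two-regime
scaling-split proportions of rescaled-range and detrended fluctuation
analysis (lag-2 cumulative sums, ~50 log-spaced timescales).

All features operate on the z-scored window, so they are invariant to
affine rescaling of the raw signal. Conformance is established by
per-feature brute-force oracles in the test suite (explicit double loops,
direct DFTs, analytic cases such as the lag-10 autocorrelation minimum of a
period-20 sine), not by comparison to any external binary. Two deliberate
adaptations to short windows: the fluctuation-analysis split margin shrinks
from 6 timescales toward 2 when fewer than 18 distinct timescales exist,
and features that remain undefined (the two fluctuation proportions below
~40 samples, occasionally the transition matrix on heavily down-sampled
windows) return NaN and are imputed by the *baseline-set* median of the
same feature, with a logged warning. Windows shorter than 15 s are refused
outright — a hard precondition rather than a guess about which features
survive — so the handcrafted detector's sweep starts at `cW = 15`.

## One-class SVM

`fit_ocsvm` solves the ν-parameterized one-class maximum-margin problem
(separate the baseline mass from the origin in kernel space with maximal
offset ρ, slack-penalized by 1/(νM)). The implementation wraps the libsvm
solver with a tight stopping tolerance (1e-7); a standard-scaler is fitted
on the baseline rows. Kernel: RBF with the median-heuristic bandwidth
γ = 1/(2·median²) of pairwise training distances — a standard default for
novelty detection — both kernel and ν (default 0.1) are configurable. The
ν-property (at most ~ν of training rows scored negative, within 2/√M)
is verified across seeds, and decision values are checked against an
independent dual-QP solve (SLSQP + exact KKT polish) to 1e-5.

One honest caveat, documented because it shapes expectations on real data:
1-s-step windows overlap by `cW − 1` samples, so the baseline feature cloud
underestimates the process variability, and the training-row ν bound does
*not* transfer to a fresh same-state segment (measured continuation
false-positive rates of ~0.3–0.4 at a 420 s baseline). This matches the
known behavior of window-level one-class scoring on short baselines and is
the main reason the handcrafted detector trails the learned detectors at
short windows.

## Neural building blocks

The LSTM cell includes the three peephole connections: input and forget
gates peek at the previous cell state, the output gate at the current one;
cell input and output use tanh, gates the logistic function. Bidirectional
layers run independent forward and backward passes and concatenate per-step
outputs. The dilated causal convolution is y_i = Σ_j g_j·x_{i−d·j} with
left zero-padding (causality is probe-tested: perturbing time t never
changes outputs before t), and a K-layer doubling-dilation stack with
kernel S has receptive field D = (S−1)(2^K − 1) + 1 — verified against the
impulse-response support. For heterogeneous per-block kernels the formula
is ill-defined and the receptive field is reported numerically. Residual
blocks contain two equal-dilation convolutions with ReLU and dropout and an
identity skip (1×1 projection when the channel count changes). The
classification head for pretraining — global average pooling over time plus
a 4-way softmax — is a package design choice.

The training loss is the standard reconstruction error ½Σ‖z_i − ẑ_i‖².
A literal difference-of-norms variant ½Σ(‖z_i‖−‖ẑ_i‖)² exists behind a
flag for auditability only; it is rotation-blind and never used to train.

Everything runs on a small reverse-mode autodiff core (float64 numpy),
gradient-checked against central finite differences. Weights are
Glorot-uniform, biases and peepholes start at zero, dropout is disabled at
inference, and all randomness (init, batching, dropout masks) flows from a
single integer seed, so training is bit-reproducible. Optimization is Adam
with gradient decay factor (β₁) 0.9 and initial learning rate 0.001.

## Frozen architectures and desk-scale defaults

Three architecture configurations ship as frozen defaults: the standalone
autoencoder (BLSTM hidden sizes [16, 256, 16], fully-connected sizes
[500, 50, 500], middle-block ReLU + dropout 0.7810), the five-block TCN
(256 filters per block, kernel sizes [8, 6, 19, 8, 7], dropouts [0.6116,
0.6391, 0.0438, 0.6323, 0.5121], dilations 1–16) and the joint-use
autoencoder (hidden [256, 128, 256], fully-connected [200, 100, 200],
dropouts [0.0083, 0.2875, 0.0095]). They are treated as fixed
configurations; the architecture search that produced them is out of scope.
Default epoch budgets are 1000 (standalone AE), 500 (TCN) and 2000 (joint).

Because those sizes are impractical for routine single-CPU runs, every
config has a `scaled()` variant (hidden sizes ÷ 8) and `TrainSpec.desk()`
(epochs ÷ 10); the test suite and the acceptance script go further and use
explicit tiny configurations (TCN 2×8 filters, AE hidden 4–8, 8–20 epochs)
with sessions of 120–420 s. The detectors' qualitative behavior — near-1
AUC on well-separated transitions, the learned detector's smaller
degradation at short windows — is already stable at these sizes.

## The six-step joint workflow

(1) supervised 4-class pretraining of the TCN on a labeled cohort disjoint
from the test subjects; (2) refinement on the test session's baseline
windows — interpreted here as continued supervised training with the
session's known baseline state as the label, at 10× reduced learning rate
and a tenth of the epochs, on a per-session copy of the TCN; (3) activation
extraction on baseline windows (time-pooled last residual block, the block
index configurable); (4) autoencoder training on the z-scored baseline
activations; (5) activation extraction on stimulation windows; (6) RE
scoring. Steps 2–6 are per-session, so sessions never contaminate each
other. The refinement reading and the activation tap are interpretations of
an under-specified protocol and are flagged as such.

## Scoring and evaluation

The positive class is "changed". Stimulation windows of a session whose
stimulated state differs from its baseline are positives; baseline windows
are the negatives (the only unchanged windows observable under this
protocol — note they are also the training windows, which flatters the
false-positive rate; ROC/AUC, which sweeps all thresholds, is the primary
metric for that reason). The default hard threshold for RE detectors is the
95th percentile of the baseline score distribution; the one-class SVM uses
its native margin sign. An optional session-level call declares a change at
the first run of k consecutive flagged windows.

ACC = 100·(TP+TN)/(TP+TN+FP+FN); ROC curves sweep all distinct scores and
AUC is trapezoidal (tie-averaged, equal to the rank statistic — verified
against concordant-pair counting). Cross-validation folds are
session-atomic: splitting one session's overlapping windows across folds
would leak near-duplicate rows, so the fold unit is the session even though
that reduces the effective fold count. The window-duration sweep emits a
detector × duration grid with the handcrafted column empty below 15 s, and
bootstrap CIs (1000 resamples) on fold means.

## The synthetic cohort generator

No clinical recordings are distributed, so every experiment runs on
synthetic sessions. Each channel is state mean + slow sinusoidal drift
(random phase per phase and channel) + white Gaussian noise; after the
boundary the mean relaxes exponentially toward the new state's mean with a
30 s time constant. Default state profiles encode
sympathetic/parasympathetic directionality — agitation: HR 95±6 bpm,
GSR 9.0±1.2 µS, HRV 22±6 ms; relaxation: HR 66±5, GSR 3.0±0.8, HRV 58±10;
the active/apathetic pair (HR 80±6 vs 72±6, ACT 0.35 vs 0.12) is
deliberately the closest, making AC↔AP the hardest transitions. AG↔RE
differ by >2 pooled sd on HR and GSR.

States also differ in *dynamics*, not just level: the drift defaults are
0.9 sd at a 40 s period under agitation, 0.7 sd @ 60 s active, 0.45 sd @
80 s apathetic, and 0.35 sd @ 100 s relaxed (faster, larger slow-wave
activity under sympathetic arousal). This matters because the 22-feature
catalogue z-scores every window: states differing only in mean and sd
would be invisible to it by construction, and handcrafted detection would
rest on transition transients alone. The per-state dynamics give window
features a legitimate shape signal, which is what real autonomic states
provide. These numbers are package defaults
chosen as plausible resting physiology, fully overridable, and a
`scale_separation` helper shrinks all between-state mean differences for
difficulty ladders. Per-session seeds derive from the cohort seed plus a
CRC32 of (subject, transition), so cohorts are reproducible and two
sessions sharing a seed share an identical baseline phase — the property
the no-leakage guard tests exploit.

What the generator does *not* emulate: beat-level cardiac dynamics and
morphological HRV structure, respiratory–cardiac coupling, motion
artifacts, sensor dropouts, or any nonstationarity beyond the single
sinusoidal drift. Passing tests therefore demonstrate the machinery —
causal training, feature computation, score orientation, ranking behavior —
under controlled shifts, not clinical-grade accuracy; the printed
accuracies of the original study are expressly not reproduction targets.

## Numerical choices and degenerate inputs

Histogram-mode ties average the tied bin centers. The first
autocorrelation zero-crossing uses ≤ 0; the 1/e crossing is linearly
interpolated. Quantile symbolization uses (k−½)/n plotting positions.
Constant windows yield NaN features (imputed as above); constant channels
are variance-floored; an all-identical feature matrix is refused with
advice rather than fitted. Non-finite training losses abort with
diagnostics. Dropout uses inverted scaling. The acceptance script reduces
its seed modulo 2²⁰ before deriving per-component seeds.

## Known limitations

The catalogue implementation is validated against internal oracles, not the
reference C binary, so individual feature values may differ from that
implementation in edge-case conventions (histogram tie-breaks at bin edges,
first-minimum boundary handling) even though each feature's definition is
honored. The OCSVM continuation false-positive issue above is inherent to
short overlapping-window baselines. The full-size architectures are
shipped but not routinely trained here; desk-scale results should be read
as qualitative. Session-atomic cross-validation with small synthetic
cohorts yields wide CIs.
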