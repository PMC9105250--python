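# bscdetect

Behavioral-state-change prediction from multivariate physiological time
series.

During multisensory stimulation therapy (for example with dementia
patients), a therapist wants early warning that the subject's behavioral
state — active (AC), agitated (AG), apathetic (AP) or relaxed (RE) — is
changing, read off autonomically regulated signals that cannot be
voluntarily controlled: heart rate (HR), heart-rate variability (HRV),
respiration rate (RR), blood pressure (BP), skin conductance (GSR) and an
activity channel (ACT), sampled at 1 Hz. `bscdetect` frames this as
one-class novelty detection: every model is fitted on the *pre-stimulation
baseline phase only* and scores the stimulation phase for departure from
it, so it is usable causally while the session is running.

Three detectors share that contract:

| Detector | Features | Change score |
|---|---|---|
| `ocsvm` | 22 canonical time-series characteristics per channel per sliding window | negated one-class-SVM margin |
| `blstm_ae` | raw windows, baseline-normalized | reconstruction error of a bidirectional-LSTM autoencoder |
| `joint` | activations of a supervised-pretrained temporal convolutional network (TCN) | reconstruction error of a BLSTM autoencoder over those activations |

The core quantities: a phase of duration `dS` seconds yields
`nW = dS − cW + 1` windows of duration `cW` ∈ {10, …, 70} s at a 1 s step;
the handcrafted map sends the window tensor `tsV ∈ R^{4nW × nC·cW}` to the
feature matrix `tsF ∈ R^{4nW × 22·nC}`; the one-class SVM solves the
ν-parameterized maximum-margin problem (ν bounds the training outlier
fraction); the autoencoder is scored by `RE = ½ Σᵢ ‖zᵢ − ẑᵢ‖²`; the TCN
stacks residual blocks of dilated causal convolutions
`y_i = Σ_j g_j · x_{i−d·j}` with doubling dilations, receptive field
`D = (S−1)(2^K − 1) + 1`. Detectors are evaluated window-level with
`ACC = 100·(TP+TN)/(TP+TN+FP+FN)` and ROC/AUC per state-transition pair.

No clinical recordings are distributed; a synthetic session simulator with
state-dependent channel statistics and dynamics (elevated HR/GSR and
faster slow-wave activity under agitation, the reverse under relaxation)
generates labeled cohorts for every experiment and test. See
`docs/methods.md` for the model, its parameters and its limitations.

## Worked example

```python
from bscdetect import (SessionSpec, simulate_session, run_ocsvm_pipeline,
                       CHANNELS_4)
from bscdetect.evaluate import report_from_series

spec = SessionSpec(subject="S01", channels=CHANNELS_4,
                   baseline_state="AG", stimulated_state="RE",
                   baseline_s=420, stimulation_s=420, seed=7)
session = simulate_session(spec)                 # 840 rows, 1 Hz, 4 channels
series = run_ocsvm_pipeline(session, cW=30, nu=0.1)
report = report_from_series([series], transition="AG-RE")
print(f"windows scored : {report.n_windows}")
print(f"TP/TN/FP/FN    : {report.tp}/{report.tn}/{report.fp}/{report.fn}")
print(f"ACC            : {report.acc:.2f} %")
print(f"AUC            : {report.auc:.4f}")
```

prints

```
windows scored : 782
TP/TN/FP/FN    : 320/350/41/71
ACC            : 85.68 %
AUC            : 0.9383
```

782 windows = 2 × (420 − 30 + 1): each 7-minute phase yields 391 windows.
The 391 baseline windows are the negatives (the session truly is AG there),
the 391 stimulation windows the positives (the state has changed to RE).
ACC 85.7 % is the hard-decision accuracy at the margin-sign threshold; the
AUC of 0.94 says the margin ranks changed above unchanged windows almost
everywhere. The false negatives concentrate in the first minute of
stimulation, where the simulated physiology is still relaxing toward the
new state — exactly the transient a causal early-warning system has to live
with.

The same session through the shell:

```sh
bscdetect simulate --subjects 1 --transitions AG:RE --seed 7 --out sessions/
bscdetect train --detector ocsvm --cw 30 --session sessions/S01_AG-RE.csv --out model.joblib
bscdetect score --model model.joblib --session sessions/S01_AG-RE.csv --out scores.csv
bscdetect evaluate --scores scores.csv --out report.json
```

`train --detector joint --manifest sessions/manifest.yaml` pretrains the
TCN on a labeled cohort; `bscdetect sweep` runs the session-atomic
cross-validated window-duration grid.

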