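"""End-to-end change detectors and the six-step joint workflow.

Three detectors share one contract — fit on the baseline phase, score the
stimulation phase:

* OCSVM: windows -> 22-feature catalogue per channel -> one-class SVM on
  baseline features; change score = negated decision margin.
* BLSTM-AE: normalized raw windows -> BLSTM autoencoder trained on baseline
  windows; change score = per-window reconstruction error.
* Joint TCN + BLSTM-AE: a residual TCN is pretrained with 4-class state
  supervision on a *separate* labeled cohort, refined on the test session's
  baseline, and its time-pooled activations feed a BLSTM autoencoder trained
  on baseline activations; change score = reconstruction error of the
  stimulation activations.

The default hard threshold for the reconstruction-error detectors is the
95th percentile of the baseline score distribution; the one-class SVM uses
its native margin sign.  All training uses Adam with gradient decay factor
0.9 and initial learning rate 0.001.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, replace

import numpy as np

from .autodiff import Adam, Tensor, softmax_cross_entropy
from .features import featurize
from .nets import BLSTMAEConfig, TCNConfig, build_blstm_ae, build_tcn
from .ocsvm import DEFAULT_NU, fit_ocsvm, score_windows
from .preprocess import (ValidationError, WindowingConfig, WindowTensor,
                         baseline_stats, extract_windows, normalize)
from .synthdata import STATES, PhysioSession

logger = logging.getLogger(__name__)

#: Default epoch budgets per network kind.
DEFAULT_EPOCHS = {"blstm_ae": 1000, "tcn": 500, "joint": 2000}

#: Desk-scale divisor for epochs (hidden sizes are divided via cfg.scaled()).
DESK_EPOCH_DIV = 10

#: Default hard-decision threshold: baseline-score percentile.
BASELINE_PERCENTILE = 95.0


@dataclass(frozen=True)
class TrainSpec:
    """Optimizer settings: Adam, gradient decay factor 0.9, lr 0.001."""

    epochs: int
    batch_size: int = 64
    learning_rate: float = 1e-3
    grad_decay: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be > 0")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")

    @classmethod
    def paper(cls, kind: str, seed: int = 0) -> "TrainSpec":
        return cls(epochs=DEFAULT_EPOCHS[kind], seed=seed)

    @classmethod
    def desk(cls, kind: str, seed: int = 0) -> "TrainSpec":
        """Scaled-down epochs for single-CPU desk runs."""
        return cls(epochs=max(1, DEFAULT_EPOCHS[kind] // DESK_EPOCH_DIV),
                   seed=seed)


@dataclass
class ChangeScoreSeries:
    """Time-ordered per-window change scores with ground truth.

    ``scores`` are oriented so larger = more changed (negated margin for the
    one-class SVM, reconstruction error for the autoencoders);
    ``truth`` is 1 for windows drawn from a genuinely changed state.
    """

    start_s: np.ndarray
    scores: np.ndarray
    truth: np.ndarray
    threshold: float
    detector: str
    transition: tuple[str, str]
    subject: str = ""
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.start_s) == len(self.scores) == len(self.truth)):
            raise ValidationError("misaligned score series")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("non-finite change scores")

    @property
    def decisions(self) -> np.ndarray:
        """Hard labels: 1 = changed (score above threshold)."""
        return (self.scores > self.threshold).astype(int)


def _session_windows(session: PhysioSession, cW: int):
    """(baseline tensor, stimulation tensor), normalized with baseline stats."""
    dS = session.boundary
    if session.n_samples - session.boundary != dS:
        raise ValidationError("session phases must be standardized to equal "
                              "duration (run standardize_duration)")
    cfg = WindowingConfig(cW=cW, dS=dS)
    stats = baseline_stats(session)
    base = normalize(extract_windows(session, cfg, "baseline"), stats)
    stim = normalize(extract_windows(session, cfg, "stimulation"), stats)
    return base, stim


def _truth_for(session: PhysioSession, n_base: int, n_stim: int) -> np.ndarray:
    changed = session.states[0] != session.states[-1]
    return np.r_[np.zeros(n_base, dtype=int),
                 np.full(n_stim, int(changed), dtype=int)]


# ---------------------------------------------------------------------------
# OCSVM detector

class OCSVMDetector:
    """Handcrafted-feature one-class detector (fits per session baseline)."""

    name = "ocsvm"

    def __init__(self, cW: int, nu: float = DEFAULT_NU, seed: int = 0):
        self.cW, self.nu, self.seed = cW, nu, seed

    def score_session(self, session: PhysioSession) -> ChangeScoreSeries:
        base, stim = self._featurized(session)
        model = fit_ocsvm(base, nu=self.nu)
        s_base = -score_windows(model, base)
        s_stim = -score_windows(model, stim)
        return ChangeScoreSeries(
            start_s=np.r_[base.labels["start_s"], stim.labels["start_s"]],
            scores=np.r_[s_base, s_stim],
            truth=_truth_for(session, len(s_base), len(s_stim)),
            threshold=0.0, detector=self.name,
            transition=(str(session.states[0]), str(session.states[-1])),
            subject=session.subject,
            phase=np.r_[base.labels["phase"], stim.labels["phase"]])

    def _featurized(self, session):
        base_t, stim_t = _session_windows(session, self.cW)
        base = featurize(base_t)
        stim = featurize(stim_t, impute_medians=base.medians)
        return base, stim


def run_ocsvm_pipeline(session: PhysioSession, cW: int,
                       nu: float = DEFAULT_NU) -> ChangeScoreSeries:
    """Windows -> catalogue features -> baseline one-class fit -> scores."""
    return OCSVMDetector(cW=cW, nu=nu).score_session(session)


# ---------------------------------------------------------------------------
# training loops

def _train_autoencoder(model, windows: np.ndarray, spec: TrainSpec,
                       loss_log: list | None = None):
    """Minimize mean 1/2||z - zhat||^2 over mini-batches; deterministic in
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    drop_rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(model.parameters(), lr=spec.learning_rate,
               beta1=spec.grad_decay)
    n = len(windows)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for s in range(0, n, spec.batch_size):
            idx = order[s:s + spec.batch_size]
            x = Tensor(windows[idx])
            recon = model.forward(x, drop_rng, train=True)
            loss = ((x - recon) ** 2).sum() * (0.5 / len(idx))
            if not np.isfinite(loss.data):
                raise ValidationError(
                    f"non-finite autoencoder loss at epoch {epoch}; "
                    "inspect input scaling / learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
        if loss_log is not None:
            loss_log.append(ep_loss / n)
    return model


def _train_classifier(model, windows: np.ndarray, labels: np.ndarray,
                      spec: TrainSpec, loss_log: list | None = None):
    """Supervised softmax cross-entropy training of the TCN head."""
    rng = np.random.default_rng(spec.seed)
    drop_rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(model.parameters(), lr=spec.learning_rate,
               beta1=spec.grad_decay)
    n = len(windows)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for s in range(0, n, spec.batch_size):
            idx = order[s:s + spec.batch_size]
            logits = model.forward(Tensor(windows[idx]), drop_rng, train=True)
            loss = softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise ValidationError(
                    f"non-finite classifier loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
        if loss_log is not None:
            loss_log.append(ep_loss / n)
    return model


def train_blstm_ae_detector(baseline_windows: WindowTensor,
                            config: BLSTMAEConfig,
                            trainspec: TrainSpec,
                            loss_log: list | None = None):
    """Train the autoencoder on normalized baseline windows only.

    Returns ``(model, baseline_re)`` where ``baseline_re`` is the per-window
    reconstruction-error distribution used for thresholding.
    """
    nC, cW = baseline_windows.n_channels, baseline_windows.cW
    wins = baseline_windows.values.reshape(-1, nC, cW)
    model = build_blstm_ae(config, n_in=nC, seq_len=cW, seed=trainspec.seed)
    _train_autoencoder(model, wins, trainspec, loss_log)
    return model, model.window_re(wins)


# ---------------------------------------------------------------------------
# BLSTM-AE detector

class BLSTMAEDetector:
    """Reconstruction-error detector on normalized raw windows."""

    name = "blstm_ae"

    def __init__(self, cW: int, config: BLSTMAEConfig | None = None,
                 trainspec: TrainSpec | None = None, seed: int = 0,
                 percentile: float = BASELINE_PERCENTILE):
        self.cW = cW
        self.config = config or BLSTMAEConfig.standalone().scaled()
        self.trainspec = trainspec or TrainSpec.desk("blstm_ae", seed=seed)
        self.percentile = percentile

    def score_session(self, session: PhysioSession) -> ChangeScoreSeries:
        base, stim = _session_windows(session, self.cW)
        model, base_re = train_blstm_ae_detector(
            base, self.config, self.trainspec)
        nC, cW = base.n_channels, base.cW
        stim_re = model.window_re(stim.values.reshape(-1, nC, cW))
        thresh = float(np.percentile(base_re, self.percentile))
        return ChangeScoreSeries(
            start_s=np.r_[base.labels["start_s"], stim.labels["start_s"]],
            scores=np.r_[base_re, stim_re],
            truth=_truth_for(session, len(base_re), len(stim_re)),
            threshold=thresh, detector=self.name,
            transition=(str(session.states[0]), str(session.states[-1])),
            subject=session.subject,
            phase=np.r_[base.labels["phase"], stim.labels["phase"]])


# ---------------------------------------------------------------------------
# joint TCN + BLSTM-AE detector

def _labeled_phase_windows(sessions, cW: int):
    """Stack normalized windows + integer state labels from both phases of
    a labeled cohort (for supervised pretraining)."""
    xs, ys = [], []
    state_to_idx = {s: i for i, s in enumerate(STATES)}
    for sess in sessions:
        base, stim = _session_windows(sess, cW)
        for tensor in (base, stim):
            nC = tensor.n_channels
            xs.append(tensor.values.reshape(-1, nC, tensor.cW))
            state = tensor.labels["state"].iloc[0]
            ys.append(np.full(len(tensor.values), state_to_idx[state]))
    return np.concatenate(xs), np.concatenate(ys)


class JointDetector:
    """Six-step joint workflow: supervised TCN pretraining on a labeled
    cohort, per-session baseline refinement, activation extraction, and a
    BLSTM autoencoder over activations as the change scorer.

    The pretraining cohort and the scored sessions must be disjoint.
    """

    name = "joint"

    def __init__(self, cW: int,
                 tcn_config: TCNConfig | None = None,
                 ae_config: BLSTMAEConfig | None = None,
                 trainspec: TrainSpec | None = None, seed: int = 0,
                 percentile: float = BASELINE_PERCENTILE,
                 refine: bool = True,
                 max_windows_per_class: int | None = 150):
        self.cW = cW
        self.tcn_config = tcn_config or TCNConfig().scaled()
        self.ae_config = ae_config or BLSTMAEConfig.joint().scaled()
        self.trainspec = trainspec or TrainSpec.desk("joint", seed=seed)
        self.percentile = percentile
        self.refine = refine
        self.max_windows_per_class = max_windows_per_class
        self.tcn = None

    # step 1: supervised 4-class pretraining
    def pretrain(self, cohort, loss_log: list | None = None) -> "JointDetector":
        X, y = _labeled_phase_windows(cohort, self.cW)
        present = {STATES[i] for i in np.unique(y)}
        if present != set(STATES):
            raise ValidationError(
                f"pretraining cohort must cover all four states "
                f"{set(STATES)}, found {present}")
        if self.max_windows_per_class is not None:
            rng = np.random.default_rng(self.trainspec.seed)
            keep = []
            for cls in np.unique(y):
                idx = np.nonzero(y == cls)[0]
                if len(idx) > self.max_windows_per_class:
                    idx = rng.choice(idx, self.max_windows_per_class,
                                     replace=False)
                keep.append(idx)
            keep = np.concatenate(keep)
            X, y = X[keep], y[keep]
        self.tcn = build_tcn(self.tcn_config, n_in=X.shape[1],
                             seed=self.trainspec.seed)
        _train_classifier(self.tcn, X, y, self.trainspec, loss_log)
        return self

    def classify(self, windows: np.ndarray) -> np.ndarray:
        """Predicted state indices (into STATES) for (B, C, T) windows."""
        if self.tcn is None:
            raise ValidationError("detector not pretrained")
        logits = self.tcn.forward(Tensor(windows)).data
        return logits.argmax(axis=1)

    def score_session(self, session: PhysioSession) -> ChangeScoreSeries:
        """Steps 2-6 for one test session."""
        if self.tcn is None:
            raise ValidationError("detector not pretrained; call pretrain()")
        base, stim = _session_windows(session, self.cW)
        nC, cW = base.n_channels, base.cW
        base_w = base.values.reshape(-1, nC, cW)
        stim_w = stim.values.reshape(-1, nC, cW)

        # step 2: refine the TCN on baseline windows (session's baseline
        # state as label, 10x reduced learning rate, short schedule);
        # a per-session copy keeps sessions independent.
        tcn = copy.deepcopy(self.tcn)
        if self.refine:
            lab = np.full(len(base_w),
                          STATES.index(str(session.states[0])))
            refine_spec = replace(
                self.trainspec,
                epochs=max(1, self.trainspec.epochs // 10),
                learning_rate=self.trainspec.learning_rate / 10)
            _train_classifier(tcn, base_w, lab, refine_spec)

        # step 3: activation extraction on baseline; activations are
        # z-scored with baseline statistics (the same causal-normalization
        # rule applied to raw windows), so that stimulation activations are
        # measured in units of baseline variability
        act_base = tcn.activations(base_w)
        mu = act_base.mean(axis=0)
        sd = np.maximum(act_base.std(axis=0), 1e-6)
        zb = ((act_base - mu) / sd)[:, :, None]
        # step 4: autoencoder on baseline activations (length-1 sequences)
        ae = build_blstm_ae(self.ae_config, n_in=act_base.shape[1],
                            seq_len=1, seed=self.trainspec.seed)
        _train_autoencoder(ae, zb, self.trainspec)
        base_re = ae.window_re(zb)

        # steps 5-6: activations on stimulation windows, RE scoring
        act_stim = tcn.activations(stim_w)
        stim_re = ae.window_re(((act_stim - mu) / sd)[:, :, None])

        thresh = float(np.percentile(base_re, self.percentile))
        return ChangeScoreSeries(
            start_s=np.r_[base.labels["start_s"], stim.labels["start_s"]],
            scores=np.r_[base_re, stim_re],
            truth=_truth_for(session, len(base_re), len(stim_re)),
            threshold=thresh, detector=self.name,
            transition=(str(session.states[0]), str(session.states[-1])),
            subject=session.subject,
            phase=np.r_[base.labels["phase"], stim.labels["phase"]])


def joint_workflow(pretrain_cohort, test_sessions,
                   tcn_config: TCNConfig | None = None,
                   ae_config: BLSTMAEConfig | None = None,
                   trainspec: TrainSpec | None = None,
                   cW: int = 10, seed: int = 0):
    """Run the full six-step workflow; returns the fitted detector and the
    per-session score series of ``test_sessions``."""
    det = JointDetector(cW=cW, tcn_config=tcn_config, ae_config=ae_config,
                        trainspec=trainspec, seed=seed)
    det.pretrain(pretrain_cohort)
    series = [det.score_session(s) for s in test_sessions]
    return det, series


def score_session(detector, session: PhysioSession,
                  cW: int | None = None) -> ChangeScoreSeries:
    """Score a session with a fitted/configured detector."""
    if cW is not None and detector.cW != cW:
        raise ValidationError(
            f"detector was configured for cW={detector.cW}, requested {cW}")
    return detector.score_session(session)


def make_detector(name: str, cW: int, seed: int = 0, **kwargs):
    """Detector factory by name ('ocsvm', 'blstm_ae', 'joint')."""
    if name == "ocsvm":
        return OCSVMDetector(cW=cW, seed=seed, **kwargs)
    if name == "blstm_ae":
        return BLSTMAEDetector(cW=cW, seed=seed, **kwargs)
    if name == "joint":
        return JointDetector(cW=cW, seed=seed, **kwargs)
    raise ValidationError(f"unknown detector {name!r}")


def crossval_factory(name: str, **kwargs):
    """Adapt detectors to the cross-validation harness: the joint detector
    pretrains on the train-fold sessions; the per-session detectors ignore
    them (their fit is the session's own baseline)."""

    def factory(train_sessions, cW, seed):
        det = make_detector(name, cW=cW, seed=seed, **kwargs)
        if isinstance(det, JointDetector):
            det.pretrain(train_sessions)
        return det
    return factory
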