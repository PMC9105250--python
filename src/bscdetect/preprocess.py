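"""Windowing and normalization: building the stacked window matrix.

A session phase of standardized duration ``dS`` seconds sampled at 1 Hz is
cut into sliding windows of duration ``cW`` seconds at a 1 s step, giving

    nW = dS - cW + 1

windows per phase (0-based, half-open ``[i, i + cW)`` starts).  Each window
is flattened channel-major (all of channel 1's samples, then channel 2's, ...)
into one row of the window tensor.  Normalization is z-scoring per channel
using statistics computed from the *baseline phase only*, so that no
information from the post-change segment leaks into the transform applied to
it — a requirement for a causal change detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import PhysioSession

logger = logging.getLogger(__name__)

#: Window durations (s) supported by the sweep.
WINDOW_DURATIONS = (10, 15, 20, 30, 40, 50, 60, 70)

#: Variance floor applied when a channel is constant in the baseline.
SD_EPSILON = 1e-8


class ValidationError(ValueError):
    """Raised when inputs violate a preprocessing precondition."""


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window parameters.

    cW: window duration in seconds (one of WINDOW_DURATIONS);
    dS: standardized per-phase duration in seconds; step is fixed at 1 s.
    """

    cW: int
    dS: int = 420
    step: int = 1

    def __post_init__(self) -> None:
        if self.cW not in WINDOW_DURATIONS:
            raise ValidationError(
                f"cW must be one of {WINDOW_DURATIONS}, got {self.cW}")
        if self.cW > self.dS:
            raise ValidationError("cW must not exceed dS")
        if self.step != 1:
            raise ValidationError("step is fixed at 1 s")

    @property
    def n_windows(self) -> int:
        """Windows per phase: dS - cW + 1 (inclusive count)."""
        return self.dS - self.cW + 1


@dataclass
class WindowTensor:
    """Stacked flattened windows plus per-row labels.

    ``values`` has shape (n_rows, nC * cW) with channel-major flattening;
    ``labels`` carries state, phase, window start time and subject per row.
    """

    values: np.ndarray
    labels: pd.DataFrame
    channels: tuple[str, ...]
    cW: int

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.channels) * self.cW:
            raise ValidationError("column count must equal nC * cW")
        if len(self.labels) != len(self.values):
            raise ValidationError("labels must align with rows")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def unflatten(self, row: int) -> np.ndarray:
        """Return window ``row`` as an (nC, cW) array."""
        return self.values[row].reshape(self.n_channels, self.cW)

    def stack(self, other: "WindowTensor") -> "WindowTensor":
        if self.channels != other.channels or self.cW != other.cW:
            raise ValidationError("incompatible tensors")
        return WindowTensor(
            values=np.vstack([self.values, other.values]),
            labels=pd.concat([self.labels, other.labels], ignore_index=True),
            channels=self.channels, cW=self.cW)


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean/sd, computed from baseline samples only."""

    channels: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    floored: tuple[str, ...] = field(default=())


def downsample_gsr(series: np.ndarray, native_hz: int = 5) -> np.ndarray:
    """Down-sample a native-rate skin-conductance trace to 1 Hz by block mean.

    Output length is ``len(series) // native_hz``; trailing samples that do
    not fill a block are dropped.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValidationError("empty GSR series")
    n = x.size // native_hz
    if n == 0:
        raise ValidationError("GSR series shorter than one block")
    return x[: n * native_hz].reshape(n, native_hz).mean(axis=1)


def standardize_duration(session: PhysioSession, dS: int = 420) -> PhysioSession:
    """Truncate both phases to their first ``dS`` seconds."""
    n_base = session.boundary
    n_stim = session.n_samples - session.boundary
    if n_base < dS:
        raise ValidationError(
            f"baseline phase has {n_base} s, shorter than dS={dS}")
    if n_stim < dS:
        raise ValidationError(
            f"stimulation phase has {n_stim} s, shorter than dS={dS}")
    idx = np.r_[0:dS, session.boundary:session.boundary + dS]
    data = session.data.iloc[idx].reset_index(drop=True)
    data.index.name = "time_s"
    return PhysioSession(
        data=data, states=session.states[idx], boundary=dS,
        subject=session.subject, seed=session.seed)


def extract_windows(session: PhysioSession, config: WindowingConfig,
                    phase: str) -> WindowTensor:
    """Extract the sliding-window tensor for one phase of a session.

    Row ``i`` covers samples ``[i, i + cW)`` of the phase; flattening is
    channel-major.  The phase must last exactly ``dS`` seconds.
    """
    frame = session.phase_slice(phase)
    if len(frame) != config.dS:
        raise ValidationError(
            f"{phase} phase lasts {len(frame)} s, expected dS={config.dS}; "
            "run standardize_duration first")
    offset = 0 if phase == "baseline" else session.boundary
    state = session.states[offset]
    arr = frame.to_numpy(dtype=float)          # (dS, nC)
    nW, cW = config.n_windows, config.cW
    # (nW, cW, nC) sliding view -> channel-major flatten (nW, nC*cW)
    win = np.lib.stride_tricks.sliding_window_view(arr, cW, axis=0)  # (nW, nC, cW)
    values = win.reshape(nW, -1).copy()
    labels = pd.DataFrame({
        "state": state,
        "phase": phase,
        "start_s": np.arange(nW) + offset,
        "subject": session.subject,
    })
    return WindowTensor(values=values, labels=labels,
                        channels=tuple(frame.columns), cW=cW)


def baseline_stats(session: PhysioSession) -> ChannelStats:
    """Per-channel mean/sd over the baseline-phase samples (ddof=0)."""
    base = session.phase_slice("baseline").to_numpy(dtype=float)
    mean = base.mean(axis=0)
    sd = base.std(axis=0)
    floored = []
    for j, ch in enumerate(session.channels):
        if sd[j] < SD_EPSILON:
            logger.warning("channel %s has (near-)zero baseline variance; "
                           "sd floored at %g", ch, SD_EPSILON)
            sd[j] = SD_EPSILON
            floored.append(ch)
    return ChannelStats(channels=session.channels, mean=mean, sd=sd,
                        floored=tuple(floored))


def normalize(tensor: WindowTensor, stats: ChannelStats) -> WindowTensor:
    """Z-score a window tensor per channel using baseline statistics.

    Stimulation-phase tensors must be normalized with the *baseline* phase's
    statistics — never their own — so the transform is available causally at
    stimulation time.
    """
    if stats.channels != tensor.channels:
        raise ValidationError("stats channels do not match tensor channels")
    vals = tensor.values.reshape(len(tensor.values), tensor.n_channels, tensor.cW)
    out = (vals - stats.mean[None, :, None]) / stats.sd[None, :, None]
    return WindowTensor(values=out.reshape(len(tensor.values), -1),
                        labels=tensor.labels.copy(),
                        channels=tensor.channels, cW=tensor.cW)
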