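"""Synthetic physiological session simulator.

Generates labeled multichannel 1 Hz sessions that emulate the structure of
short multisensory-stimulation recordings: a baseline phase in one behavioral
state followed by a stimulation phase in another (or the same) state, over a
channel set drawn from {HR, RR, HRV, BP, GSR, ACT}.

The generative model per channel is deliberately simple and controllable:

    x(t) = m(t) + a * sin(2*pi*(t + phi)/T) + sigma * eps(t)

where ``m(t)`` is the state mean, relaxing exponentially toward the new
state's mean after the phase boundary with a per-state lag constant, ``a``/
``T`` parameterize a slow sinusoidal drift with a random phase ``phi``, and
``eps`` is white Gaussian noise.  The default state profiles encode the
sympathetic/parasympathetic directionality of the four behavioral states
(agitation: elevated heart rate and skin conductance, depressed heart-rate
variability; relaxation: the reverse), with the active/apathetic pair placed
deliberately closer together, which makes their transitions the hardest to
detect.  The numbers are package defaults, fully overridable — they are
plausible resting-physiology values, not measurements.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The four behavioral states: active, agitated, apathetic, relaxed.
STATES = ("AC", "AG", "AP", "RE")

#: Chest-strap-only channel set (4 channels).
CHANNELS_4 = ("HR", "RR", "HRV", "ACT")
#: Full channel set including blood pressure and skin conductance (6 channels).
CHANNELS_6 = ("HR", "RR", "HRV", "BP", "GSR", "ACT")

#: Native GSR sample rate before down-sampling (Hz).
GSR_NATIVE_HZ = 5

SAMPLE_RATE_HZ = 1


class ConfigurationError(ValueError):
    """Raised for invalid simulator/session configuration."""


@dataclass(frozen=True)
class StateProfile:
    """Per-state channel statistics driving the generative model.

    Parameters
    ----------
    state
        One of ``AC``, ``AG``, ``AP``, ``RE``.
    means
        Channel -> mean level (HR bpm, HRV ms, RR breaths/min, ACT a.u.,
        GSR uS, BP mmHg).
    sds
        Channel -> Gaussian noise standard deviation (same units).
    drift_amp
        Channel -> amplitude of the slow sinusoidal drift.
    drift_period_s
        Period of the slow drift, seconds.
    lag_s
        Exponential time constant (seconds) of the relaxation toward this
        state's mean after a state change; 0 means an instantaneous switch.
    """

    state: str
    means: dict[str, float]
    sds: dict[str, float]
    drift_amp: dict[str, float] = field(default_factory=dict)
    drift_period_s: float = 90.0
    lag_s: float = 30.0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ConfigurationError(f"unknown state {self.state!r}")
        if set(self.means) != set(self.sds):
            raise ConfigurationError("means and sds must cover the same channels")
        for ch, sd in self.sds.items():
            if sd < 0:
                raise ConfigurationError(f"negative sd for channel {ch}")
        for ch, m in self.means.items():
            if not np.isfinite(m):
                raise ConfigurationError(f"non-finite mean for channel {ch}")
        if self.lag_s < 0:
            raise ConfigurationError("lag_s must be >= 0")


# Default per-state channel statistics.  AG and RE are separated by well over
# two pooled standard deviations on HR and GSR; AC and AP are much closer
# (their separation is the difficulty knob for the hardest transitions).
_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    #         (mean, sd)
    "AG": {"HR": (95.0, 6.0), "RR": (20.0, 2.0), "HRV": (22.0, 6.0),
           "BP": (145.0, 8.0), "GSR": (9.0, 1.2), "ACT": (0.55, 0.15)},
    "RE": {"HR": (66.0, 5.0), "RR": (12.0, 1.5), "HRV": (58.0, 10.0),
           "BP": (118.0, 6.0), "GSR": (3.0, 0.8), "ACT": (0.08, 0.05)},
    "AC": {"HR": (80.0, 6.0), "RR": (16.0, 2.0), "HRV": (40.0, 8.0),
           "BP": (130.0, 7.0), "GSR": (6.0, 1.0), "ACT": (0.35, 0.12)},
    "AP": {"HR": (72.0, 6.0), "RR": (14.0, 2.0), "HRV": (45.0, 9.0),
           "BP": (124.0, 7.0), "GSR": (5.0, 1.0), "ACT": (0.12, 0.07)},
}


# Per-state slow-drift dynamics: sympathetic arousal shows faster, larger
# slow-wave fluctuations; vagal dominance slower, smaller ones.  These shape
# differences are what window-level features can see after z-scoring.
_DRIFT_DEFAULTS: dict[str, tuple[float, float]] = {
    #      (amplitude as a fraction of the noise sd, period s)
    "AG": (0.9, 40.0),
    "AC": (0.7, 60.0),
    "AP": (0.45, 80.0),
    "RE": (0.35, 100.0),
}


def default_profiles(channels: tuple[str, ...] = CHANNELS_6,
                     drift_frac: float | None = None,
                     drift_period_s: float | None = None,
                     lag_s: float = 30.0) -> dict[str, StateProfile]:
    """Return the four default state profiles restricted to ``channels``.

    By default each state carries its own slow-drift amplitude fraction and
    period (:data:`_DRIFT_DEFAULTS`); passing ``drift_frac`` and/or
    ``drift_period_s`` overrides them uniformly across states (``0`` for a
    drift-free generator).
    """
    unknown = set(channels) - set(CHANNELS_6)
    if unknown:
        raise ConfigurationError(f"unknown channels {sorted(unknown)}")
    out = {}
    for state in STATES:
        spec = _DEFAULTS[state]
        frac, period = _DRIFT_DEFAULTS[state]
        if drift_frac is not None:
            frac = drift_frac
        if drift_period_s is not None:
            period = drift_period_s
        out[state] = StateProfile(
            state=state,
            means={ch: spec[ch][0] for ch in channels},
            sds={ch: spec[ch][1] for ch in channels},
            drift_amp={ch: frac * spec[ch][1] for ch in channels},
            drift_period_s=period,
            lag_s=lag_s,
        )
    return out


@dataclass(frozen=True)
class SessionSpec:
    """Specification of one simulated session."""

    subject: str
    channels: tuple[str, ...]
    baseline_state: str
    stimulated_state: str
    baseline_s: int = 420
    stimulation_s: int = 420
    sample_rate_hz: int = SAMPLE_RATE_HZ
    seed: int = 0
    gsr_native_5hz: bool = False

    def __post_init__(self) -> None:
        for st in (self.baseline_state, self.stimulated_state):
            if st not in STATES:
                raise ConfigurationError(f"unknown state {st!r}")
        if self.baseline_s < 1 or self.stimulation_s < 1:
            raise ConfigurationError("phase durations must be positive")
        if self.sample_rate_hz != SAMPLE_RATE_HZ:
            raise ConfigurationError("only 1 Hz sessions are supported")
        if self.gsr_native_5hz and "GSR" not in self.channels:
            raise ConfigurationError("gsr_native_5hz requires a GSR channel")


@dataclass
class PhysioSession:
    """A simulated (or loaded) multichannel 1 Hz session.

    ``data`` holds one row per second and one column per channel; ``states``
    is the per-sample behavioral state; ``boundary`` is the index of the
    first stimulation-phase sample.  ``gsr_5hz``, when present, is the native
    5 Hz skin-conductance trace whose block means equal the GSR column.
    """

    data: pd.DataFrame
    states: np.ndarray
    boundary: int
    subject: str = ""
    seed: int | None = None
    gsr_5hz: np.ndarray | None = None

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def phase(self) -> np.ndarray:
        """Per-sample phase labels ('baseline' / 'stimulation')."""
        out = np.where(np.arange(self.n_samples) < self.boundary,
                       "baseline", "stimulation")
        return out

    def phase_slice(self, phase: str) -> pd.DataFrame:
        if phase == "baseline":
            return self.data.iloc[: self.boundary]
        if phase == "stimulation":
            return self.data.iloc[self.boundary:]
        raise ValueError(f"unknown phase {phase!r}")

    def validate(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("session contains missing values")
        changes = np.nonzero(self.states[1:] != self.states[:-1])[0] + 1
        if self.states[0] != self.states[self.boundary - 1]:
            raise ValueError("state label changes before the phase boundary")
        if len(changes) > 1 or (len(changes) == 1 and changes[0] != self.boundary):
            raise ValueError("state label must change exactly once, at the boundary")


def _mean_trajectory(n: int, boundary: int, m0: float, m1: float,
                     lag_s: float) -> np.ndarray:
    """Piecewise mean with exponential relaxation after the boundary."""
    t = np.arange(n, dtype=float)
    m = np.full(n, m0)
    post = t >= boundary
    if lag_s <= 0:
        m[post] = m1
    else:
        dt = t[post] - boundary
        m[post] = m1 + (m0 - m1) * np.exp(-dt / lag_s)
    return m


def simulate_session(spec: SessionSpec,
                     profiles: dict[str, StateProfile] | None = None) -> PhysioSession:
    """Simulate one session according to ``spec``.

    Deterministic in ``spec.seed``: identical specs yield bit-identical
    sessions.
    """
    if profiles is None:
        profiles = default_profiles(spec.channels)
    for st in (spec.baseline_state, spec.stimulated_state):
        if st not in profiles:
            raise ConfigurationError(f"no profile for state {st!r}")
    p0 = profiles[spec.baseline_state]
    p1 = profiles[spec.stimulated_state]
    for p in (p0, p1):
        missing = set(spec.channels) - set(p.means)
        if missing:
            raise ConfigurationError(
                f"profile {p.state} lacks channels {sorted(missing)}")

    n = spec.baseline_s + spec.stimulation_s
    boundary = spec.baseline_s
    rng = np.random.default_rng(spec.seed)
    cols = {}
    gsr_5hz = None
    for ch in spec.channels:
        native_hz = GSR_NATIVE_HZ if (ch == "GSR" and spec.gsr_native_5hz) else 1
        nn = n * native_hz
        t = np.arange(nn, dtype=float) / native_hz
        m = np.interp(t, np.arange(n, dtype=float),
                      _mean_trajectory(n, boundary, p0.means[ch], p1.means[ch],
                                       p1.lag_s))
        amp0 = p0.drift_amp.get(ch, 0.0)
        amp1 = p1.drift_amp.get(ch, 0.0)
        # each phase oscillates at its own state's period with an
        # independent random phase offset (both drawn regardless of
        # amplitude, to keep the rng stream layout fixed)
        ph0 = rng.uniform(0.0, p0.drift_period_s)
        ph1 = rng.uniform(0.0, p1.drift_period_s)
        pre = t < boundary
        drift = np.where(
            pre,
            amp0 * np.sin(2.0 * np.pi * (t + ph0) / p0.drift_period_s),
            amp1 * np.sin(2.0 * np.pi * (t + ph1) / p1.drift_period_s))
        sd = np.where(t < boundary, p0.sds[ch], p1.sds[ch])
        x = m + drift + sd * rng.standard_normal(nn)
        if native_hz > 1:
            gsr_5hz = x
            x = x.reshape(n, native_hz).mean(axis=1)
        cols[ch] = x

    data = pd.DataFrame(cols, index=pd.RangeIndex(n, name="time_s"))
    states = np.where(np.arange(n) < boundary,
                      spec.baseline_state, spec.stimulated_state).astype(object)
    sess = PhysioSession(data=data, states=states, boundary=boundary,
                         subject=spec.subject, seed=spec.seed, gsr_5hz=gsr_5hz)
    sess.validate()
    return sess


def subject_seed(cohort_seed: int, subject: str, baseline: str, stimulated: str) -> int:
    """Deterministic per-session seed: cohort seed + CRC32 of the identity."""
    tag = f"{subject}:{baseline}->{stimulated}".encode()
    return (int(cohort_seed) + zlib.crc32(tag)) % (2 ** 31)


def simulate_cohort(n_subjects: int,
                    channels: tuple[str, ...],
                    transitions: list[tuple[str, str]],
                    seed: int = 0,
                    profiles: dict[str, StateProfile] | None = None,
                    baseline_s: int = 420,
                    stimulation_s: int = 420) -> list[PhysioSession]:
    """Simulate ``n_subjects`` x ``len(transitions)`` sessions.

    ``transitions`` is a list of ordered (baseline, stimulated) state pairs;
    per-session seeds are derived deterministically from the cohort seed.
    """
    if not transitions:
        raise ConfigurationError("transitions must be non-empty")
    if n_subjects < 1:
        raise ConfigurationError("need at least one subject")
    sessions = []
    for i in range(n_subjects):
        subject = f"S{i + 1:02d}"
        for (a, b) in transitions:
            spec = SessionSpec(
                subject=subject, channels=tuple(channels),
                baseline_state=a, stimulated_state=b,
                baseline_s=baseline_s, stimulation_s=stimulation_s,
                seed=subject_seed(seed, subject, a, b),
            )
            sessions.append(simulate_session(spec, profiles))
    return sessions


def all_transitions(include_self: bool = False) -> list[tuple[str, str]]:
    """All ordered state pairs (12 without self-transitions, 16 with)."""
    return [(a, b) for a in STATES for b in STATES if include_self or a != b]


def scale_separation(profiles: dict[str, StateProfile],
                     factor: float) -> dict[str, StateProfile]:
    """Shrink/expand inter-state mean separation around the grand mean.

    ``factor`` = 1 leaves the profiles unchanged; 0 collapses all states onto
    the channel-wise grand mean (an undetectable change).  Used to build
    difficulty ladders in tests and experiments.
    """
    channels = next(iter(profiles.values())).means.keys()
    center = {ch: np.mean([p.means[ch] for p in profiles.values()])
              for ch in channels}
    out = {}
    for state, p in profiles.items():
        means = {ch: center[ch] + factor * (p.means[ch] - center[ch])
                 for ch in channels}
        out[state] = replace(p, means=means)
    return out
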