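"""Synthetic manual-material-handling sessions.

Generates labeled multi-rate recordings with the statistical structure of a
real MMH acquisition: 8 kinematic channels at 240 Hz carrying class-specific
motion motifs, 2 raw sEMG channels at 2000 Hz whose burst amplitude grows
with the handled load, per-subject gain/noise variability, and an activity
label stream dominated by the neutral N-pose class.

The generator is a test bed, not a biomechanical model: motif shapes are
fixed analytic primitives (half-cosine excursions for lifts and placements,
smoothed boxcars for sustained carrying/holding) parameterized only by
amplitude and duration. Everything is a pure function of the arguments and
the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .activities import (
    ActivityClass,
    CHANNEL_NAMES,
    KIN_RATE_HZ,
    N_KIN_CHANNELS,
    SEMG_RATE_HZ,
)


class InvalidProtocolError(ValueError):
    """Raised for empty protocols or non-positive activity durations."""


@dataclass(frozen=True)
class ProtocolStep:
    """One activity bout: the class, its duration and the handled load."""

    activity: ActivityClass
    duration_s: float
    load_kg: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.activity, ActivityClass):
            raise InvalidProtocolError(
                f"unknown activity class {self.activity!r}"
            )
        if self.duration_s <= 0:
            raise InvalidProtocolError(
                f"activity duration must be positive, got {self.duration_s}"
            )
        if self.load_kg < 0:
            raise InvalidProtocolError(
                f"load must be non-negative, got {self.load_kg}"
            )


#: A protocol is an ordered list of (activity, duration, load) bouts.
Protocol = list[ProtocolStep]


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generative parameters.

    amplitude_scale scales every kinematic motif (taller/shorter movers),
    semg_gain scales muscle activation, mvc is the simulated maximum
    voluntary contraction in raw sEMG units (the later normalization
    reference), noise_sd is a dimensionless measurement-noise level
    expressed as a fraction of each channel's nominal dynamic range.
    """

    subject_id: str
    amplitude_scale: float = 1.0
    semg_gain: float = 1.0
    mvc: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0 or self.semg_gain <= 0 or self.mvc <= 0:
            raise ValueError(
                "amplitude_scale, semg_gain and mvc must be positive"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class RawSession:
    """One subject's multi-rate labeled recording.

    kin is (8, T) at 240 Hz, semg is (2, T') at ``semg_rate_hz`` raw (un-
    processed) sEMG, labels is a length-T int vector aligned to the
    kinematic clock. channel_names is the canonical early-fusion order.
    """

    subject_id: str
    kin: np.ndarray
    semg: np.ndarray
    labels: np.ndarray
    kin_rate_hz: float = KIN_RATE_HZ
    semg_rate_hz: float = SEMG_RATE_HZ
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    #: subject MVC calibration value recorded alongside the session; the
    #: normalization reference for the sEMG chain
    mvc: float = 1.0

    def __post_init__(self) -> None:
        if self.kin.shape[0] != N_KIN_CHANNELS:
            raise ValueError(f"kin must have 8 rows, got {self.kin.shape}")
        if self.kin.shape[1] != self.labels.shape[0]:
            raise ValueError("kin sample count must equal labels length")
        dur_kin = self.kin.shape[1] / self.kin_rate_hz
        dur_semg = self.semg.shape[1] / self.semg_rate_hz
        if abs(dur_kin - dur_semg) > 1.0 / self.kin_rate_hz:
            raise ValueError(
                "sEMG and kinematic streams disagree in duration: "
                f"{dur_semg:.4f}s vs {dur_kin:.4f}s"
            )


# ---------------------------------------------------------------------------
# Motif tables
# ---------------------------------------------------------------------------

#: Baseline (N-pose) value per kinematic channel:
#: flexion angles in degrees, positions in m, velocity m/s, acceleration m/s2.
_BASELINE = np.array([5.0, 5.0, 10.0, 5.0, 0.10, 0.0, 0.0, 1.00])

#: Peak motif excursion per class and kinematic channel (added to baseline,
#: scaled by the subject amplitude and the class's temporal shape).
#: Columns follow CHANNEL_NAMES[:8]; rows are ActivityClass order 0..6.
_PEAK = np.array(
    [
        # chest shoulder elbow  knee  handp handa pvel  pz
        [0.0,   0.0,    0.0,   0.0,  0.00, 0.0,  0.0,  0.00],   # N
        [60.0,  10.0,   20.0,  85.0, 0.30, 3.0,  0.0, -0.40],   # LF
        [5.0,   20.0,   70.0,  5.0,  0.35, 0.0,  0.0,  0.00],   # K
        [10.0,  50.0,   25.0,  5.0,  0.25, 2.0,  0.0,  0.02],   # PT
        [15.0,  30.0,   55.0,  10.0, 0.20, 2.0,  0.0,  0.05],   # LT
        [8.0,   10.0,   30.0,  0.0,  0.15, 0.0,  1.2,  0.00],   # W
        [50.0,  15.0,   25.0,  75.0, 0.22, 2.5,  0.0, -0.35],   # PF
    ]
)

#: Nominal dynamic range per kinematic channel, used to express the
#: measurement-noise level in comparable units across heterogeneous channels.
_CHANNEL_SCALE = np.array([20.0, 20.0, 20.0, 20.0, 0.05, 0.5, 0.2, 0.05])

#: Classes whose motif is a half-cosine bump (0 -> peak -> 0).
_BUMP_CLASSES = {
    ActivityClass.LF,
    ActivityClass.PT,
    ActivityClass.LT,
    ActivityClass.PF,
}

#: Classes holding a smoothed-boxcar plateau for the whole bout.
_PLATEAU_CLASSES = {ActivityClass.K, ActivityClass.W}

#: Muscle activation level (fraction of MVC drive) per class, and the
#: within-bout activation profile kind.
_EMG_ACTIVITY = {
    ActivityClass.N: (0.05, "flat"),
    ActivityClass.LF: (0.60, "rise"),
    ActivityClass.K: (1.00, "flat"),
    ActivityClass.PT: (0.50, "fall"),
    ActivityClass.LT: (0.55, "rise"),
    ActivityClass.W: (0.70, "flat"),
    ActivityClass.PF: (0.50, "fall"),
}

#: Relative gain of the two recorded muscles (biceps, brachioradialis).
_MUSCLE_GAIN = np.array([1.0, 0.8])


def _time_shape(cls: ActivityClass, n: int, fs: float) -> np.ndarray:
    """Within-bout temporal shape in [0, 1] for the kinematic motif."""
    t = np.arange(n) / fs
    dur = n / fs
    if cls in _BUMP_CLASSES:
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * t / dur))
    if cls in _PLATEAU_CLASSES:
        ramp = max(1, min(int(0.15 * fs), n // 4))
        shape = np.ones(n)
        shape[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
        shape[n - ramp:] = np.linspace(1.0, 0.0, ramp)
        return shape
    return np.zeros(n)


def _emg_profile(kind: str, n: int) -> np.ndarray:
    """Within-bout activation profile (flat / rising / falling)."""
    if kind == "rise":
        return np.linspace(0.3, 1.0, n)
    if kind == "fall":
        return np.linspace(1.0, 0.3, n)
    return np.ones(n)


def _bandlimited_carrier(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Zero-mean unit-RMS stochastic sEMG carrier band-limited to 20-450 Hz."""
    white = rng.standard_normal(n + 400)
    sos = signal.butter(4, [20.0, 450.0], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, white)[400:]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_session(protocol: Protocol, params: SubjectParams) -> RawSession:
    """Generate one subject's labeled multi-rate recording.

    The label stream is the concatenation of the protocol bouts sampled at
    240 Hz. Each bout carries its class's kinematic motif scaled by the
    subject's ``amplitude_scale``; raw sEMG is a band-limited stochastic
    carrier whose envelope follows the class activation profile and grows
    monotonically with ``load_kg`` (soft-saturated below the MVC), plus a
    50 Hz mains component and white sensor noise. Identical arguments
    (including the seed) reproduce the session bit-for-bit.
    """
    if not protocol:
        raise InvalidProtocolError("protocol must contain at least one bout")
    for step in protocol:
        if not isinstance(step, ProtocolStep):
            raise InvalidProtocolError(
                "protocol entries must be ProtocolStep instances"
            )

    rng = np.random.default_rng(params.seed)
    kin_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    semg_parts: list[np.ndarray] = []

    for step in protocol:
        n_kin = int(round(step.duration_s * KIN_RATE_HZ))
        n_semg = int(round(step.duration_s * SEMG_RATE_HZ))
        shape = _time_shape(step.activity, n_kin, KIN_RATE_HZ)
        peak = _PEAK[int(step.activity)] * params.amplitude_scale

        kin = _BASELINE[:, None] + peak[:, None] * shape[None, :]

        # Carrying gets a gait oscillation on the knee and a vertical
        # pelvis bob on top of the sustained transversal velocity.
        if step.activity is ActivityClass.W:
            t = np.arange(n_kin) / KIN_RATE_HZ
            kin[3] += 15.0 * params.amplitude_scale * np.abs(np.sin(2 * np.pi * 0.9 * t)) * shape
            kin[7] += 0.03 * params.amplitude_scale * np.sin(2 * np.pi * 1.8 * t) * shape
        # Bump classes: hand acceleration follows the curvature of the
        # hand-position motif (cosine), not the bump itself.
        if step.activity in _BUMP_CLASSES:
            t = np.arange(n_kin) / KIN_RATE_HZ
            dur = n_kin / KIN_RATE_HZ
            kin[5] = _BASELINE[5] + _PEAK[int(step.activity), 5] * \
                params.amplitude_scale * np.cos(2 * np.pi * t / dur)

        kin += (params.noise_sd * _CHANNEL_SCALE)[:, None] * \
            rng.standard_normal((N_KIN_CHANNELS, n_kin))

        # --- raw sEMG at the native rate ---
        act, prof_kind = _EMG_ACTIVITY[step.activity]
        profile = _emg_profile(prof_kind, n_semg)
        drive = act * params.semg_gain * (0.15 + 0.06 * step.load_kg)
        envelope = params.mvc * np.tanh(drive) * profile
        semg = np.empty((2, n_semg))
        for m in range(2):
            carrier = _bandlimited_carrier(rng, n_semg, SEMG_RATE_HZ)
            t = np.arange(n_semg) / SEMG_RATE_HZ
            mains = 0.02 * params.mvc * np.sin(2 * np.pi * 50.0 * t)
            sensor = params.noise_sd * 0.02 * params.mvc * \
                rng.standard_normal(n_semg)
            semg[m] = _MUSCLE_GAIN[m] * envelope * carrier + mains + sensor

        kin_parts.append(kin)
        semg_parts.append(semg)
        label_parts.append(np.full(n_kin, int(step.activity), dtype=np.int8))

    return RawSession(
        subject_id=params.subject_id,
        kin=np.concatenate(kin_parts, axis=1),
        semg=np.concatenate(semg_parts, axis=1),
        labels=np.concatenate(label_parts),
        mvc=params.mvc,
    )


def default_protocol(load_kg: float = 10.0, cycles: int = 2) -> Protocol:
    """A realistic MMH cycle: rest, floor lift, hold, carry, place on table,
    rest, table lift, carry, place on floor, rest. Repeated ``cycles`` times.
    """
    cycle = [
        ProtocolStep(ActivityClass.N, 4.0, 0.0),
        ProtocolStep(ActivityClass.LF, 2.0, load_kg),
        ProtocolStep(ActivityClass.K, 3.0, load_kg),
        ProtocolStep(ActivityClass.W, 4.0, load_kg),
        ProtocolStep(ActivityClass.PT, 2.0, load_kg),
        ProtocolStep(ActivityClass.N, 3.0, 0.0),
        ProtocolStep(ActivityClass.LT, 2.0, load_kg),
        ProtocolStep(ActivityClass.W, 4.0, load_kg),
        ProtocolStep(ActivityClass.PF, 2.0, load_kg),
        ProtocolStep(ActivityClass.N, 4.0, 0.0),
    ]
    return cycle * cycles


def _pad_protocol_for_imbalance(
    protocol: Protocol, n_fraction: float
) -> Protocol:
    """Append a trailing N-pose rest so the N-class time share reaches
    ``n_fraction`` (with a 2% safety margin against label rounding)."""
    total = sum(s.duration_s for s in protocol)
    n_time = sum(
        s.duration_s for s in protocol if s.activity is ActivityClass.N
    )
    target = min(max(n_fraction * 1.02, n_fraction + 0.005), 0.999)
    if n_time / total >= target:
        return list(protocol)
    extra = (target * total - n_time) / (1.0 - target)
    return list(protocol) + [ProtocolStep(ActivityClass.N, extra, 0.0)]


def generate_cohort(
    n_subjects: int,
    protocol_template: Protocol | None = None,
    master_seed: int = 0,
    imbalance_n_fraction: float = 0.5,
) -> list[RawSession]:
    """Generate a cohort of subjects with deterministic per-subject
    variability drawn from ``master_seed``.

    Each subject receives a distinct id S01, S02, ... and parameters drawn
    from documented uniform ranges (amplitude 0.85-1.15, sEMG gain 0.8-1.2,
    MVC 0.5-1.5, noise 0.03-0.07). The protocol is padded with a trailing
    N-pose rest so the cohort-level N-class sample share is at least
    ``imbalance_n_fraction``.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    if not (0.0 < imbalance_n_fraction < 1.0):
        raise ValueError("imbalance_n_fraction must be in (0, 1)")
    if protocol_template is None:
        protocol_template = default_protocol()

    protocol = _pad_protocol_for_imbalance(
        protocol_template, imbalance_n_fraction
    )
    rng = np.random.default_rng(master_seed)
    sessions = []
    for i in range(n_subjects):
        params = SubjectParams(
            subject_id=f"S{i + 1:02d}",
            amplitude_scale=float(rng.uniform(0.85, 1.15)),
            semg_gain=float(rng.uniform(0.8, 1.2)),
            mvc=float(rng.uniform(0.5, 1.5)),
            noise_sd=float(rng.uniform(0.03, 0.07)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sessions.append(generate_session(protocol, params))
    return sessions
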