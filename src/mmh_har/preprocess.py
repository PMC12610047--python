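"""sEMG conditioning, channel fusion and fixed-window segmentation.

The sEMG chain is the classic surface-EMG envelope pipeline: 50 Hz notch,
20-500 Hz Butterworth band-pass, full-wave rectification, normalization to
the subject's maximum voluntary contraction, and a 250 ms sliding RMS
envelope. The envelope is computed at the native sEMG rate (the band-pass
needs the full bandwidth) and only then resampled onto the 240 Hz kinematic
clock. Fused 10-channel series are cut into non-overlapping 1 s windows
(10 x 240), each labeled by the majority class within the window.

All filters are applied forward-backward (zero phase) so the envelope stays
aligned with the label stream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import gcd

import numpy as np
from scipy import signal

from .activities import (
    ActivityClass,
    CHANNEL_NAMES,
    KIN_RATE_HZ,
    N_CHANNELS,
    N_CLASSES,
    WINDOW_SAMPLES,
)
from .synth import RawSession

logger = logging.getLogger(__name__)


class NyquistViolationError(ValueError):
    """A filter corner frequency is at or above fs/2."""


@dataclass
class FusedSeries:
    """Early-fused 10 x T series at 240 Hz with an aligned label stream.

    Rows follow the canonical channel order: 8 kinematic channels then the
    2 RMS-sEMG channels (which are non-negative after rectification and
    MVC normalization).
    """

    data: np.ndarray
    labels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(
                f"fused data must be ({N_CHANNELS}, T), got {self.data.shape}"
            )
        if self.data.shape[1] != self.labels.shape[0]:
            raise ValueError("fused data length must equal labels length")


@dataclass(frozen=True)
class Segment:
    """One 10 x 240 window with its class label and provenance."""

    x: np.ndarray
    y: ActivityClass
    subject_id: str

    def __post_init__(self) -> None:
        if self.x.shape != (N_CHANNELS, WINDOW_SAMPLES):
            raise ValueError(
                f"segment must be ({N_CHANNELS}, {WINDOW_SAMPLES}), "
                f"got {self.x.shape}"
            )


@dataclass
class SegmentSet:
    """A collection of segments; the unit flowing through balancing,
    training and evaluation."""

    segments: list[Segment] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[ActivityClass, int]:
        counts = {cls: 0 for cls in ActivityClass}
        for seg in self.segments:
            counts[seg.y] += 1
        return counts

    @property
    def subject_ids(self) -> list[str]:
        """Sorted registry of the subject ids present."""
        return sorted({seg.subject_id for seg in self.segments})

    def __len__(self) -> int:
        return len(self.segments)

    def xy_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (n, 10, 240) float32 inputs and (n,) int labels."""
        if not self.segments:
            return (
                np.empty((0, N_CHANNELS, WINDOW_SAMPLES), dtype=np.float32),
                np.empty(0, dtype=np.int64),
            )
        x = np.stack([s.x for s in self.segments]).astype(np.float32)
        y = np.array([int(s.y) for s in self.segments], dtype=np.int64)
        return x, y

    def subset(self, indices) -> "SegmentSet":
        return SegmentSet([self.segments[i] for i in indices])


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def notch_filter(
    x: np.ndarray, fs: float, f0: float = 50.0, q: float = 25.0
) -> np.ndarray:
    """Zero-phase IIR notch at ``f0`` Hz (mains interference removal).

    The default quality factor is chosen so that a 2 s mains-frequency
    probe is attenuated by at least 20 dB *including* the forward-backward
    filter's edge transients, while tones a decade away pass unscathed."""
    if not 0 < f0 < fs / 2:
        raise NyquistViolationError(
            f"notch frequency {f0} Hz must lie in (0, {fs / 2}) Hz"
        )
    b, a = signal.iirnotch(f0, q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float))


def bandpass_butterworth(
    x: np.ndarray, fs: float, lo: float = 20.0, hi: float = 500.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass between ``lo`` and ``hi`` Hz."""
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= fs / 2:
        raise NyquistViolationError(
            f"band edge {hi} Hz must be below Nyquist {fs / 2} Hz"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def mvc_normalize(x: np.ndarray, mvc: float) -> np.ndarray:
    """Scale to fractions of the subject's maximum voluntary contraction."""
    if mvc <= 0:
        raise ValueError(f"MVC must be positive, got {mvc}")
    return np.asarray(x, dtype=float) / mvc


def rms_envelope(
    x: np.ndarray, fs: float, window_ms: float = 250.0
) -> np.ndarray:
    """Centered sliding-window RMS envelope, same length as the input.

    The window shrinks to the available overlap at the edges, so no padding
    values are fabricated. Window length is round(window_ms * fs / 1000)
    samples and must be at least 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute an RMS envelope of an empty series")
    w = int(round(window_ms * fs / 1000.0))
    if w < 1:
        raise ValueError(
            f"window of {window_ms} ms spans <1 sample at fs={fs} Hz"
        )
    n = x.size
    sq = x * x
    left = (w - 1) // 2          # samples before the center
    right = w - left             # samples from the center on (inclusive)
    out = np.empty(n)
    if n >= w:
        # interior: full windows via a strided view (no copy)
        windows = np.lib.stride_tricks.sliding_window_view(sq, w)
        out[left:left + windows.shape[0]] = np.sqrt(windows.mean(axis=1))
        edge_idx = list(range(left)) + list(range(left + windows.shape[0], n))
    else:
        edge_idx = range(n)
    for i in edge_idx:
        a, b = max(0, i - left), min(n, i + right)
        out[i] = np.sqrt(sq[a:b].mean())
    return out


def resample_to_240(x: np.ndarray, fs_in: float) -> np.ndarray:
    """Polyphase resampling onto the 240 Hz kinematic clock.

    Only downsampling (or identity) is supported; the envelope is smooth by
    construction so the polyphase anti-aliasing filter is benign.
    """
    x = np.asarray(x, dtype=float)
    if fs_in < KIN_RATE_HZ:
        raise ValueError(
            f"upsampling not supported: fs_in={fs_in} < {KIN_RATE_HZ} Hz"
        )
    fs_int = int(round(fs_in))
    if abs(fs_in - fs_int) > 1e-9:
        raise ValueError(f"fs_in must be an integer rate, got {fs_in}")
    if fs_int == KIN_RATE_HZ:
        return x.copy()
    g = gcd(KIN_RATE_HZ, fs_int)
    up, down = KIN_RATE_HZ // g, fs_int // g
    return signal.resample_poly(x, up, down, padtype="line")


# ---------------------------------------------------------------------------
# Chain, fusion, segmentation
# ---------------------------------------------------------------------------

def process_semg_channel(
    raw: np.ndarray, fs: float, mvc: float,
    notch_hz: float = 50.0, band: tuple[float, float] = (20.0, 500.0),
    rms_window_ms: float = 250.0,
) -> np.ndarray:
    """The full single-channel chain: notch -> band-pass -> rectify ->
    MVC normalize -> RMS envelope -> resample to 240 Hz."""
    hi = min(band[1], 0.95 * fs / 2)  # keep the band physical at low rates
    x = notch_filter(raw, fs, notch_hz)
    x = bandpass_butterworth(x, fs, band[0], hi)
    x = rectify(x)
    x = mvc_normalize(x, mvc)
    x = rms_envelope(x, fs, rms_window_ms)
    return resample_to_240(x, fs)


def preprocess_session(
    session: RawSession, mvc: float | None = None
) -> FusedSeries:
    """Run the sEMG chain on both muscles and fuse with the kinematics.

    ``mvc`` defaults to the calibration value stored with the session.
    """
    if mvc is None:
        mvc = session.mvc
    t = session.kin.shape[1]
    proc = np.empty((2, t))
    for m in range(2):
        env = process_semg_channel(
            session.semg[m], session.semg_rate_hz, mvc
        )
        # rounding during generation can leave the envelope one sample
        # short/long of the kinematic clock; trim or hold the last value
        if env.size >= t:
            proc[m] = env[:t]
        else:
            proc[m, :env.size] = env
            proc[m, env.size:] = env[-1]
    return fuse_channels(session, proc)


def fuse_channels(session: RawSession, semg_processed: np.ndarray) -> FusedSeries:
    """Vertically stack kinematics and processed sEMG (early fusion)."""
    if semg_processed.shape != (2, session.kin.shape[1]):
        raise ValueError(
            "alignment error: processed sEMG shape "
            f"{semg_processed.shape} does not match kinematics "
            f"(2, {session.kin.shape[1]})"
        )
    data = np.vstack([session.kin, semg_processed])
    return FusedSeries(
        data=data, labels=session.labels.copy(), subject_id=session.subject_id
    )


def _window_label(window_labels: np.ndarray) -> ActivityClass:
    """Majority label; ties broken toward the window's center sample (or,
    if the center label is not among the tied leaders, the lowest code)."""
    counts = np.bincount(window_labels, minlength=N_CLASSES)
    top = counts.max()
    leaders = np.flatnonzero(counts == top)
    if leaders.size == 1:
        return ActivityClass(int(leaders[0]))
    center = int(window_labels[window_labels.size // 2])
    if center in leaders:
        return ActivityClass(center)
    return ActivityClass(int(leaders[0]))


def segment_windows(
    fs: FusedSeries, win: int = WINDOW_SAMPLES, stride: int = WINDOW_SAMPLES
) -> SegmentSet:
    """Cut the fused series into fixed windows (1 s, no overlap by default).

    Emits floor((T - win)/stride) + 1 segments; a trailing remainder shorter
    than ``win`` is discarded. A series shorter than one window yields an
    empty set with a logged warning rather than an error.
    """
    t = fs.data.shape[1]
    if t < win:
        logger.warning(
            "series of %d samples is shorter than one %d-sample window; "
            "emitting an empty segment set", t, win,
        )
        warnings.warn("series shorter than one window: empty segment set")
        return SegmentSet([])
    segments = []
    for start in range(0, t - win + 1, stride):
        sl = slice(start, start + win)
        segments.append(
            Segment(
                x=fs.data[:, sl].copy(),
                y=_window_label(fs.labels[sl]),
                subject_id=fs.subject_id,
            )
        )
    return SegmentSet(segments)


def sessions_to_segments(
    sessions: list[RawSession], mvcs: dict[str, float] | None = None
) -> SegmentSet:
    """Preprocess and window a whole cohort into one segment pool."""
    segs: list[Segment] = []
    for sess in sessions:
        mvc = (mvcs or {}).get(sess.subject_id)
        fused = preprocess_session(sess, mvc=mvc)
        segs.extend(segment_windows(fused).segments)
    return SegmentSet(segs)
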