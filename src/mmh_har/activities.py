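"""Activity classes and the canonical channel layout.

The seven manual-material-handling activities and their stable integer
encoding live here; every other module imports this one rather than
hard-coding codes or channel positions.
"""

from __future__ import annotations

from enum import IntEnum


class ActivityClass(IntEnum):
    """The 7 MMH activity classes with their stable 0..6 encoding.

    N   - N-pose (neutral standing posture)
    LF  - Lifting from the Floor
    K   - Keeping lifted (holding the load)
    PT  - Placing on the Table
    LT  - Lifting from the Table
    W   - Carrying (walking with the load)
    PF  - Placing on the Floor
    """

    N = 0
    LF = 1
    K = 2
    PT = 3
    LT = 4
    W = 5
    PF = 6


N_CLASSES = len(ActivityClass)

#: Kinematic sampling rate (Hz); also the rate of the fused input.
KIN_RATE_HZ = 240

#: Default synthetic raw-sEMG sampling rate (Hz). Chosen so that the
#: 20-500 Hz surface-EMG band is below Nyquist.
SEMG_RATE_HZ = 2000

#: Samples per 1 s analysis window at the kinematic rate.
WINDOW_SAMPLES = 240

#: Canonical early-fusion row order: 8 kinematic channels followed by the
#: 2 RMS-sEMG channels. Index in this list == row index everywhere.
CHANNEL_NAMES = (
    "chest_flexion",
    "shoulder_flexion",
    "elbow_flexion",
    "knee_flexion",
    "hand_pos_front",
    "hand_acc_front",
    "pelvis_vel_transversal",
    "pelvis_pos_vertical",
    "semg_rms_biceps",
    "semg_rms_brachioradialis",
)

N_KIN_CHANNELS = 8
N_SEMG_CHANNELS = 2
N_CHANNELS = N_KIN_CHANNELS + N_SEMG_CHANNELS

#: Row/column class order used when exporting confusion matrices, matching
#: the order the per-class results are conventionally tabulated in.
CONFUSION_EXPORT_ORDER = (
    ActivityClass.N,
    ActivityClass.LT,
    ActivityClass.PT,
    ActivityClass.LF,
    ActivityClass.PF,
    ActivityClass.K,
    ActivityClass.W,
)


def class_from_symbol(symbol: str) -> ActivityClass:
    """Look up an activity by its symbol, e.g. ``"LF"``.

    Raises
    ------
    KeyError
        If the symbol is not one of the 7 class symbols.
    """
    try:
        return ActivityClass[symbol]
    except KeyError:
        raise KeyError(
            f"unknown activity class {symbol!r}; expected one of "
            f"{[c.name for c in ActivityClass]}"
        ) from None
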