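"""Human activity recognition for manual material handling.

Synthetic labeled MMH sessions, the sEMG/kinematic preprocessing chain,
class balancing, recurrent/convolutional classifiers with a numpy training
runtime, evaluation protocols (70-30 split, subject increment, LOSO) and
an analytic network-complexity profiler.
"""

__version__ = "0.1.0"

from .activities import ActivityClass, CHANNEL_NAMES, KIN_RATE_HZ
from .balance import BalanceConfig, balance_dataset
from .complexity import (
    ComplexityReport, count_learnables, count_ma, count_mac,
    latency_estimate, memory_mb, profile,
)
from .evaluate import (
    EvalResult, confusion, loso, macro_f1, split_70_30, subject_increment,
)
from .models import (
    SpDAEConfig, TrainConfig, TrainedModel, build_bilstm, build_deepconvlstm,
    build_rcnn, build_recurrent_spdae, build_spdae, predict, train,
)
from .preprocess import (
    FusedSeries, Segment, SegmentSet, preprocess_session, segment_windows,
    sessions_to_segments,
)
from .specs import ArchitectureSpec, LayerSpec
from .synth import (
    Protocol, ProtocolStep, RawSession, SubjectParams, default_protocol,
    generate_cohort, generate_session,
)
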