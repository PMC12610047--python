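"""Shared fixtures.

The study cohort (6 subjects, 8 protocol cycles, low noise) is the
separable-by-construction dataset the end-to-end training checks run on;
it is generated once per session. Smaller fixtures serve the fast unit
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mmh_har.preprocess import SegmentSet, sessions_to_segments
from mmh_har.synth import default_protocol, generate_cohort

STUDY_SEED = 42


@pytest.fixture(scope="session")
def study_cohort():
    """6 synthetic subjects, ~4 min of activity each, N-pose dominant."""
    return generate_cohort(
        6, default_protocol(cycles=8), master_seed=STUDY_SEED,
        imbalance_n_fraction=0.5,
    )


@pytest.fixture(scope="session")
def study_segments(study_cohort) -> SegmentSet:
    return sessions_to_segments(study_cohort)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects, one protocol cycle: fast plumbing fixture."""
    return generate_cohort(
        3, default_protocol(cycles=1), master_seed=7,
        imbalance_n_fraction=0.4,
    )


@pytest.fixture(scope="session")
def tiny_segments(tiny_cohort) -> SegmentSet:
    return sessions_to_segments(tiny_cohort)
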