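"""Class balancing: down-sample the dominant class, augment the rest.

MMH recordings are dominated by the neutral N-pose; left alone, a
classifier learns to over-predict it. The remedy implemented here is the
standard pair of moves: classes above a target count are down-sampled
uniformly without replacement, classes below it are topped up by
replicating their segments round-robin with additive white Gaussian noise
(sd expressed per channel as a fraction of that channel's within-segment
sd, so heterogeneous channel units are respected). Originals always survive
unmodified; only the synthetic replicates carry noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activities import ActivityClass
from .preprocess import Segment, SegmentSet


class MissingClassError(ValueError):
    """A class required for balancing has zero segments."""


@dataclass(frozen=True)
class BalanceConfig:
    """Balancing policy.

    target_count_rule: "median_class" or an explicit integer target.
    noise_sd_fraction: augmentation noise sd as a fraction of each
        channel's per-segment sd.
    max_ratio: acceptance bound on max/min class count after balancing.
    """

    target_count_rule: str | int = "median_class"
    noise_sd_fraction: float = 0.05
    seed: int = 0
    max_ratio: float = 1.1

    def __post_init__(self) -> None:
        if self.noise_sd_fraction <= 0:
            raise ValueError("noise_sd_fraction must be positive")
        if self.max_ratio < 1:
            raise ValueError("max_ratio must be >= 1")
        if isinstance(self.target_count_rule, int):
            if self.target_count_rule < 1:
                raise ValueError("fixed target count must be >= 1")
        elif self.target_count_rule != "median_class":
            raise ValueError(
                "target_count_rule must be 'median_class' or an integer"
            )


def _indices_of(ss: SegmentSet, cls: ActivityClass) -> list[int]:
    return [i for i, seg in enumerate(ss.segments) if seg.y == cls]


def downsample_class(
    ss: SegmentSet, cls: ActivityClass, target: int, seed: int = 0
) -> SegmentSet:
    """Uniformly subsample ``cls`` to ``target`` segments (others untouched)."""
    idx = _indices_of(ss, cls)
    if target > len(idx):
        raise ValueError(
            f"target {target} exceeds current count {len(idx)} of {cls.name}"
        )
    rng = np.random.default_rng(seed)
    keep = set(np.array(idx)[rng.permutation(len(idx))[:target]].tolist())
    kept = [
        seg for i, seg in enumerate(ss.segments)
        if seg.y != cls or i in keep
    ]
    return SegmentSet(kept)


def augment_class(
    ss: SegmentSet, cls: ActivityClass, target: int, cfg: BalanceConfig
) -> SegmentSet:
    """Top up ``cls`` to ``target`` segments by noisy replication.

    Source segments are cycled round-robin; each replicate adds i.i.d.
    Gaussian noise with per-channel sd = noise_sd_fraction x the source
    segment's per-channel sd.
    """
    idx = _indices_of(ss, cls)
    if not idx:
        raise MissingClassError(f"cannot augment empty class {cls.name}")
    if target < len(idx):
        raise ValueError(
            f"target {target} is below current count {len(idx)} of {cls.name}"
        )
    rng = np.random.default_rng(cfg.seed)
    new_segments = list(ss.segments)
    for k in range(target - len(idx)):
        src = ss.segments[idx[k % len(idx)]]
        ch_sd = src.x.std(axis=1, keepdims=True)
        noise = rng.standard_normal(src.x.shape) * (
            cfg.noise_sd_fraction * ch_sd
        )
        new_segments.append(
            Segment(x=src.x + noise, y=src.y, subject_id=src.subject_id)
        )
    return SegmentSet(new_segments)


def balance_dataset(ss: SegmentSet, cfg: BalanceConfig) -> SegmentSet:
    """Equalize all 7 class counts to the target rule, then shuffle.

    Every class must be represented; after balancing all counts equal the
    target, so the max/min ratio is 1 <= cfg.max_ratio.
    """
    counts = ss.class_counts
    missing = [cls.name for cls, c in counts.items() if c == 0]
    if missing:
        raise MissingClassError(
            f"cannot balance: no segments for class(es) {', '.join(missing)}"
        )
    if cfg.target_count_rule == "median_class":
        target = int(np.median(sorted(counts.values())))
    else:
        target = int(cfg.target_count_rule)
    target = max(target, 1)

    out = ss
    for step, cls in enumerate(ActivityClass):
        c = out.class_counts[cls]
        sub_seed = cfg.seed * 131 + step  # distinct per-class streams
        if c > target:
            out = downsample_class(out, cls, target, seed=sub_seed)
        elif c < target:
            sub_cfg = BalanceConfig(
                target_count_rule=cfg.target_count_rule,
                noise_sd_fraction=cfg.noise_sd_fraction,
                seed=sub_seed,
                max_ratio=cfg.max_ratio,
            )
            out = augment_class(out, cls, target, sub_cfg)

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(out.segments))
    return SegmentSet([out.segments[i] for i in order])
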