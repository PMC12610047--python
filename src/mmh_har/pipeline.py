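"""End-to-end pipeline: synth -> preprocess -> balance -> train -> eval.

``run_pipeline`` executes the full chain from a validated
:class:`RunConfig`, writing every artifact plus a manifest (config hash,
per-stage seeds, package version, artifact paths) into the run directory.
``make_fixtures`` builds the small canned segment set and tiny trained
checkpoint the test suite reuses.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np

from . import __version__
from .balance import BalanceConfig, balance_dataset
from .config import RunConfig, config_hash, stage_seed
from .evaluate import (
    EvalResult, evaluate_model, export_confusion_csv, loso, split_70_30,
)
from .io import save_segments_hdf5, save_session_hdf5
from .models import (
    TrainConfig, build_bilstm, build_deepconvlstm, build_rcnn, predict,
    save_model, train,
)
from .preprocess import SegmentSet, sessions_to_segments
from .synth import default_protocol, generate_cohort

logger = logging.getLogger(__name__)

ARCH_BUILDERS = {
    "bilstm": build_bilstm,
    "rcnn": build_rcnn,
    "deepconvlstm": build_deepconvlstm,
}


def _train_cfg(cfg: RunConfig, seed: int) -> TrainConfig:
    t = cfg.train
    return TrainConfig(
        max_epochs=t.max_epochs, batch_size=t.batch_size,
        initial_lr=t.initial_lr, lr_drop_factor=t.lr_drop_factor,
        lr_drop_period=t.lr_drop_period, l2=t.l2, seed=seed,
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    seeds = {
        stage: stage_seed(cfg.seed, stage)
        for stage in ("synth", "balance", "split", "train")
    }

    logger.info("synth: %d subjects", cfg.synth.n_subjects)
    sessions = generate_cohort(
        cfg.synth.n_subjects,
        default_protocol(cfg.synth.load_kg, cfg.synth.cycles),
        master_seed=seeds["synth"],
        imbalance_n_fraction=cfg.synth.imbalance_n_fraction,
    )
    sess_dir = out / "sessions"
    sess_dir.mkdir(exist_ok=True)
    for s in sessions:
        save_session_hdf5(s, sess_dir / f"{s.subject_id}.h5")

    logger.info("preprocess: windowing %d sessions", len(sessions))
    segments = sessions_to_segments(sessions)
    save_segments_hdf5(segments, out / "segments.h5")

    bal_cfg = BalanceConfig(
        target_count_rule=cfg.balance.target_count_rule,
        noise_sd_fraction=cfg.balance.noise_sd_fraction,
        seed=seeds["balance"], max_ratio=cfg.balance.max_ratio,
    )
    builder = ARCH_BUILDERS[cfg.train.arch]
    train_cfg = _train_cfg(cfg, seeds["train"])

    if cfg.eval.protocol == "loso":
        folds = loso(
            segments, lambda: builder(cfg.train.hidden_units), train_cfg,
            balance_cfg=bal_cfg,
        )
        results = {
            sid: res.to_dict() for sid, res in folds
        }
        results["mean_macro_f1"] = float(
            np.mean([res.macro_f1 for _, res in folds])
        )
        (out / "eval.json").write_text(json.dumps(results, indent=2))
    else:
        train_set, test_set = split_70_30(segments, seed=seeds["split"])
        train_set = balance_dataset(train_set, bal_cfg)
        save_segments_hdf5(train_set, out / "train_balanced.h5")
        model = train(builder(cfg.train.hidden_units), train_set, train_cfg)
        save_model(model, out / "model.npz")
        result = evaluate_model(model, test_set)
        (out / "eval.json").write_text(json.dumps(result.to_dict(), indent=2))
        export_confusion_csv(result.cm, out / "confusion.csv")

    manifest = {
        "config_hash": config_hash(cfg),
        "config": cfg.model_dump(),
        "seeds": seeds,
        "version": __version__,
        "python": platform.python_version(),
        "artifacts": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def make_fixtures(
    seed: int = 0, n_subjects: int = 3, epochs: int = 3,
) -> tuple[SegmentSet, "object"]:
    """Small canned segment set plus a tiny trained checkpoint.

    Covers all 7 classes, generates in seconds, and is bit-reproducible
    for a given seed."""
    sessions = generate_cohort(
        n_subjects, default_protocol(cycles=1), master_seed=seed,
        imbalance_n_fraction=0.4,
    )
    segments = sessions_to_segments(sessions)
    cfg = TrainConfig(max_epochs=epochs, seed=seed)
    model = train(build_bilstm(8), segments, cfg)
    return segments, model
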