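"""Metrics and experimental protocols.

Classification quality is summarized by the confusion matrix and the macro
F1-score (the unweighted mean of per-class F1), which treats all seven
activity classes equally regardless of their frequency — the right choice
when the raw class distribution is dominated by the neutral pose.

Three protocols are provided: a stratified 70-30 split of the segment
pool, subject-increment curves (grow the training cohort one subject at a
time, several repeats per size), and leave-one-subject-out (LOSO)
cross-validation, where each fold tests on one entirely unseen subject.
Balancing is always applied to the training portion only; the test set
keeps its natural class distribution.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .activities import ActivityClass, CONFUSION_EXPORT_ORDER, N_CLASSES
from .balance import BalanceConfig, balance_dataset
from .models import TrainConfig, TrainedModel, predict, train
from .preprocess import SegmentSet
from .specs import ArchitectureSpec

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion(
    y_true: Sequence[int], y_pred: Sequence[int], n_classes: int = N_CLASSES
) -> np.ndarray:
    """Confusion counts; rows = true class, columns = predicted class."""
    yt = np.asarray(y_true, dtype=np.int64)
    yp = np.asarray(y_pred, dtype=np.int64)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (yt, yp), 1)
    return cm


def _per_class_prf(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tp = np.diag(cm).astype(float)
    pred = cm.sum(axis=0).astype(float)
    true = cm.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred > 0, tp / pred, 0.0)
        recall = np.where(true > 0, tp / true, 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall), 0.0,
        )
    return precision, recall, f1


def macro_f1(cm: np.ndarray) -> float:
    """Unweighted mean of per-class F1 computed from the confusion matrix.

    A class absent from both truth and predictions contributes F1 = 0 and
    triggers a logged warning (conservative zero-division policy)."""
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise ValueError("confusion matrix is all zeros")
    absent = (cm.sum(axis=0) == 0) & (cm.sum(axis=1) == 0)
    if absent.any():
        logger.warning(
            "classes %s absent from truth and predictions; scored F1=0",
            np.flatnonzero(absent).tolist(),
        )
    _, _, f1 = _per_class_prf(cm)
    return float(f1.mean())


def accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    return float(np.diag(cm).sum() / cm.sum())


def macro_precision(cm: np.ndarray) -> float:
    precision, _, _ = _per_class_prf(cm)
    return float(precision.mean())


def micro_f1(cm: np.ndarray) -> float:
    """Micro-averaged F1; equals accuracy for single-label classification."""
    cm = np.asarray(cm)
    tp = np.diag(cm).sum()
    fp = cm.sum() - tp
    return float(2 * tp / (2 * tp + 2 * fp)) if cm.sum() else 0.0


@dataclass
class EvalResult:
    """Confusion matrix plus the derived summary metrics; every metric is
    recomputable from the stored matrix."""

    cm: np.ndarray
    macro_f1: float
    accuracy: float
    macro_precision: float
    per_class_f1: dict[ActivityClass, float]

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "EvalResult":
        cm = confusion(y_true, y_pred)
        _, _, f1 = _per_class_prf(cm)
        return cls(
            cm=cm,
            macro_f1=macro_f1(cm),
            accuracy=accuracy(cm),
            macro_precision=macro_precision(cm),
            per_class_f1={c: float(f1[int(c)]) for c in ActivityClass},
        )

    def to_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "per_class_f1": {c.name: v for c, v in self.per_class_f1.items()},
            "confusion": self.cm.tolist(),
        }


def export_confusion_csv(cm: np.ndarray, path) -> None:
    """Write the confusion matrix with rows/columns in the conventional
    tabulation order (N, LT, PT, LF, PF, K, W)."""
    order = [int(c) for c in CONFUSION_EXPORT_ORDER]
    names = [c.name for c in CONFUSION_EXPORT_ORDER]
    reordered = np.asarray(cm)[np.ix_(order, order)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred"] + names)
        for name, row in zip(names, reordered):
            writer.writerow([name] + row.tolist())


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def split_70_30(
    ss: SegmentSet, seed: int = 0, train_fraction: float = 0.7
) -> tuple[SegmentSet, SegmentSet]:
    """Stratified-by-class 70-30 split, deterministic per seed.

    Classes with fewer than 2 segments cannot be stratified; they stay
    whole in the training portion with a logged warning."""
    if len(ss) < 10:
        raise ValueError(f"need at least 10 segments to split, got {len(ss)}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    _, y = ss.xy_arrays()
    for cls in range(N_CLASSES):
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            continue
        if idx.size < 2:
            logger.warning(
                "class %s has <2 segments; kept whole in train",
                ActivityClass(cls).name,
            )
            train_idx.extend(idx.tolist())
            continue
        perm = idx[rng.permutation(idx.size)]
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return ss.subset(sorted(train_idx)), ss.subset(sorted(test_idx))


def evaluate_model(model: TrainedModel, test_set: SegmentSet) -> EvalResult:
    _, y_true = test_set.xy_arrays()
    _, y_pred = predict(model, test_set)
    return EvalResult.from_predictions(y_true, y_pred)


def train_and_eval(
    spec: ArchitectureSpec, ss: SegmentSet, cfg: TrainConfig,
    balance_cfg: BalanceConfig | None = None, seed: int = 0,
) -> tuple[TrainedModel, EvalResult]:
    """Balance (train portion only) -> 70-30 split -> train -> evaluate."""
    train_set, test_set = split_70_30(ss, seed=seed)
    if balance_cfg is not None:
        train_set = balance_dataset(train_set, balance_cfg)
    model = train(spec, train_set, cfg)
    return model, evaluate_model(model, test_set)


def _subjects_subset(ss: SegmentSet, keep: set[str]) -> SegmentSet:
    return SegmentSet([s for s in ss.segments if s.subject_id in keep])


def subject_increment(
    ss: SegmentSet,
    arch_builder: Callable[[], ArchitectureSpec],
    cfg: TrainConfig,
    balance_cfg: BalanceConfig | None = None,
    repeats: int = 3,
) -> list[dict]:
    """Learning curve over cohort size: for k = 1..n subjects, pool the
    first k subjects, run balance -> split -> train -> eval with
    ``repeats`` different seeds (both split and initialization are
    re-drawn), and report mean and sd of macro-F1 per k."""
    subjects = ss.subject_ids
    if not subjects:
        raise ValueError("segment set has no subjects")
    spec = arch_builder()
    results = []
    for k in range(1, len(subjects) + 1):
        pool = _subjects_subset(ss, set(subjects[:k]))
        scores = []
        for r in range(repeats):
            seed = cfg.seed + 1000 * k + r
            run_cfg = TrainConfig(
                optimizer=cfg.optimizer, max_epochs=cfg.max_epochs,
                batch_size=cfg.batch_size, initial_lr=cfg.initial_lr,
                lr_drop_factor=cfg.lr_drop_factor,
                lr_drop_period=cfg.lr_drop_period, l2=cfg.l2,
                seed=seed, lr_floor=cfg.lr_floor,
            )
            bal = None
            if balance_cfg is not None:
                bal = BalanceConfig(
                    target_count_rule=balance_cfg.target_count_rule,
                    noise_sd_fraction=balance_cfg.noise_sd_fraction,
                    seed=seed, max_ratio=balance_cfg.max_ratio,
                )
            _, res = train_and_eval(spec, pool, run_cfg, bal, seed=seed)
            scores.append(res.macro_f1)
        results.append({
            "n_subjects": k,
            "mean_macro_f1": float(np.mean(scores)),
            "sd_macro_f1": float(np.std(scores, ddof=1)) if repeats > 1 else 0.0,
            "scores": scores,
        })
    return results


def loso(
    ss: SegmentSet,
    arch_builder: Callable[[], ArchitectureSpec],
    cfg: TrainConfig,
    balance_cfg: BalanceConfig | None = None,
) -> list[tuple[str, EvalResult]]:
    """Leave-one-subject-out: one fold per subject, testing on the held-out
    subject only. Training folds are balanced; subject leakage is asserted
    impossible on every fold."""
    subjects = ss.subject_ids
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    spec = arch_builder()
    folds: list[tuple[str, EvalResult]] = []
    for i, held_out in enumerate(subjects):
        test_set = _subjects_subset(ss, {held_out})
        if len(test_set) == 0:
            raise ValueError(f"subject {held_out} has zero segments")
        train_set = _subjects_subset(ss, set(subjects) - {held_out})
        assert held_out not in train_set.subject_ids, (
            f"subject leakage in fold {held_out}"
        )
        if balance_cfg is not None:
            train_set = balance_dataset(train_set, balance_cfg)
        fold_cfg = TrainConfig(
            optimizer=cfg.optimizer, max_epochs=cfg.max_epochs,
            batch_size=cfg.batch_size, initial_lr=cfg.initial_lr,
            lr_drop_factor=cfg.lr_drop_factor,
            lr_drop_period=cfg.lr_drop_period, l2=cfg.l2,
            seed=cfg.seed + i, lr_floor=cfg.lr_floor,
        )
        model = train(spec, train_set, fold_cfg)
        folds.append((held_out, evaluate_model(model, test_set)))
    return folds


def hyperparameter_sweep(
    arch_builder: Callable[[int], ArchitectureSpec],
    hu_grid: Sequence[int],
    eps_grid: Sequence[int],
    ss: SegmentSet,
    cfg: TrainConfig,
    balance_cfg: BalanceConfig | None = None,
) -> np.ndarray:
    """Grid of macro-F1 over hidden-units x epochs (a checkerboard).

    Cell (i, j) trains ``arch_builder(hu_grid[i])`` for ``eps_grid[j]``
    epochs with a per-cell seed. Training errors are re-raised with the
    cell coordinates attached."""
    if not len(hu_grid) or not len(eps_grid):
        raise ValueError("hu_grid and eps_grid must be non-empty")
    grid = np.zeros((len(hu_grid), len(eps_grid)))
    for i, hu in enumerate(hu_grid):
        for j, eps in enumerate(eps_grid):
            cell_cfg = TrainConfig(
                optimizer=cfg.optimizer, max_epochs=eps,
                batch_size=cfg.batch_size, initial_lr=cfg.initial_lr,
                lr_drop_factor=cfg.lr_drop_factor,
                lr_drop_period=cfg.lr_drop_period, l2=cfg.l2,
                seed=cfg.seed + 100 * i + j, lr_floor=cfg.lr_floor,
            )
            try:
                _, res = train_and_eval(
                    arch_builder(hu), ss, cell_cfg, balance_cfg,
                    seed=cell_cfg.seed,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"sweep cell (hu={hu}, eps={eps}) failed: {exc}"
                ) from exc
            grid[i, j] = res.macro_f1
    return grid


def sweep_to_csv(
    grid: np.ndarray, hu_grid: Sequence[int], eps_grid: Sequence[int], path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["hu\\eps"] + [str(e) for e in eps_grid])
        for hu, row in zip(hu_grid, grid):
            writer.writerow([hu] + [f"{v:.6f}" for v in row])


def sweep_from_csv(path) -> tuple[np.ndarray, list[int], list[int]]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    eps_grid = [int(e) for e in rows[0][1:]]
    hu_grid = [int(r[0]) for r in rows[1:]]
    grid = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return grid, hu_grid, eps_grid


def sweep_heatmap(
    grid: np.ndarray, hu_grid: Sequence[int], eps_grid: Sequence[int], path
) -> None:
    """Checkerboard heatmap of the sweep (matplotlib, file output only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(eps_grid) + 2,
                                    0.8 * len(hu_grid) + 2))
    im = ax.imshow(grid, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(eps_grid)), [str(e) for e in eps_grid])
    ax.set_yticks(range(len(hu_grid)), [str(h) for h in hu_grid])
    ax.set_xlabel("epochs")
    ax.set_ylabel("hidden units")
    for i in range(len(hu_grid)):
        for j in range(len(eps_grid)):
            ax.text(j, i, f"{grid[i, j]:.2f}", ha="center", va="center",
                    color="w", fontsize=8)
    fig.colorbar(im, ax=ax, label="macro F1")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
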