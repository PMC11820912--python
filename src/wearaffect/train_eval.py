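"""Subject-wise training and evaluation protocol.

Splits are always by participant — no subject contributes to both sides of
any split, which the training loop asserts.  Optimization is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with a learning rate decaying linearly from
1e-3 to 0 over the epoch budget, L2 regularisation 1e-5, dropout 0.2, at
most 100 epochs and early stopping after 10 epochs without validation
improvement.  Because early stopping on the test side would leak, a
subject-wise slice of the training side (10% of its subjects, at least one)
serves as the validation set.

Metrics are reported in percent: accuracy, macro precision and macro F1
(unweighted class means), plus a row-normalised confusion matrix where each
cell is the proportion of that true label.  A class absent from both truth
and prediction is excluded from the macro means with a warning (scoring it
zero instead is selectable); a class that is present but never predicted
contributes precision 0.
"""

from __future__ import annotations

import csv
import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import SEGMENT_COLUMNS, Segment
from .network import AdamOptimizer, ModelConfig, TransformerClassifier

__all__ = [
    "TrainConfig",
    "EvalReport",
    "TASKS",
    "split_by_subject",
    "linear_decay_lr",
    "EarlyStopping",
    "segments_to_arrays",
    "train",
    "evaluate",
    "evaluate_predictions",
    "run_modality_ablation",
    "run_grid",
    "ABLATION_SUBSETS",
    "reports_to_csv",
]

#: task name -> (label extractor over a Segment.labels dict, n_classes).
#: extractors return a 0-based class index or None (instance excluded).
TASKS = {
    "panas_binary": (lambda lab: lab["panas_class"], 2),
    "valence_5": (lambda lab: lab["valence_class"] - 1, 5),
    "arousal_5": (lambda lab: lab["arousal_class"] - 1, 5),
    "valence_binary": (lambda lab: lab["valence_binary"], 2),
    "arousal_binary": (lambda lab: lab["arousal_binary"], 2),
}

#: modality subsets in canonical report order (singles, pairs, full).
ABLATION_SUBSETS = (
    ("hr",),
    ("gsr",),
    ("accel",),
    ("hr", "gsr"),
    ("gsr", "accel"),
    ("hr", "accel"),
    ("hr", "gsr", "accel"),
)


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the protocol above)."""

    lr0: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    split_ratio: float = 0.8
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class EvalReport:
    """Metrics for one experiment cell."""

    task: str
    modalities: tuple
    accuracy: float  # percent
    macro_precision: float  # percent
    macro_f1: float  # percent
    confusion: np.ndarray  # (C, C), rows = true label proportions
    n_test: int
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "modalities": list(self.modalities),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "n_test": self.n_test,
            "per_class": self.per_class,
        }


def split_by_subject(segments, ratio: float, seed: int) -> tuple[list[Segment], list[Segment]]:
    """Partition segments into train/test by a seeded permutation of the
    subject ids; ``round(ratio · n_subjects)`` subjects train."""
    segments = list(segments)
    subjects = sorted({s.subject_id for s in segments})
    if len(subjects) < 2:
        raise ValueError("subject-wise splitting needs at least two subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_train = int(round(ratio * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    train_ids = {subjects[i] for i in perm[:n_train]}
    test_ids = {subjects[i] for i in perm[n_train:]}
    assert not (train_ids & test_ids), "subject leakage in split"
    train = [s for s in segments if s.subject_id in train_ids]
    test = [s for s in segments if s.subject_id in test_ids]
    return train, test


def linear_decay_lr(lr0: float, epoch: int, max_epochs: int) -> float:
    """``lr0 · (1 − epoch/max_epochs)`` with 0-based epoch index."""
    return lr0 * (1.0 - epoch / max_epochs)


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement.

    Epochs are 1-based; ``update`` returns True when training should stop
    at the end of the current epoch.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, metric: float) -> bool:
        self.epoch += 1
        if metric > self.best:
            self.best = metric
            self.best_epoch = self.epoch
        return self.epoch - self.best_epoch >= self.patience


def segments_to_arrays(segments, task: str, modalities=SEGMENT_COLUMNS):
    """Stack segments into (X, y, subject_ids); instances whose label is
    undefined for the task (e.g. PANAS ties) are excluded."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
    extractor, _ = TASKS[task]
    cols = [SEGMENT_COLUMNS.index(m) for m in modalities]
    X, y, subj = [], [], []
    for s in segments:
        label = extractor(s.labels)
        if label is None:
            continue
        X.append(s.matrix[:, cols])
        y.append(int(label))
        subj.append(s.subject_id)
    if not X:
        raise ValueError(f"no labelled instances for task {task!r}")
    return np.stack(X), np.array(y, dtype=int), np.array(subj)


def _carve_validation(X, y, subj, val_fraction: float, rng: np.random.Generator):
    subjects = sorted(set(subj))
    n_val = max(1, int(round(val_fraction * len(subjects))))
    if n_val >= len(subjects):
        raise ValueError("too few training subjects to carve a validation set")
    perm = rng.permutation(len(subjects))
    val_ids = {subjects[i] for i in perm[:n_val]}
    val_mask = np.isin(subj, sorted(val_ids))
    return (X[~val_mask], y[~val_mask]), (X[val_mask], y[val_mask])


def _fit_arrays(model, tc: TrainConfig, Xtr, ytr, Xval, yval, rng):
    """Core loop: mini-batch Adam with linear lr decay, early stopping on
    validation accuracy, best-validation checkpointing."""
    opt = AdamOptimizer(
        model.parameters(),
        lr=tc.lr0,
        beta1=tc.beta1,
        beta2=tc.beta2,
        eps=tc.eps,
        weight_decay=tc.weight_decay,
    )
    stopper = EarlyStopping(tc.early_stop_patience)
    history = {"epoch": [], "lr": [], "train_loss": [], "val_accuracy": []}
    best_state = model.get_state()
    # checkpoint selection: highest validation accuracy, ties broken toward
    # the lower training loss (a small validation set saturates early and
    # would otherwise freeze a barely-trained model)
    best_key = (-np.inf, -np.inf)
    n = len(ytr)
    for epoch in range(tc.max_epochs):
        opt.lr = linear_decay_lr(tc.lr0, epoch, tc.max_epochs)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            model.zero_grad()
            losses.append(model.loss_and_grad(Xtr[idx], ytr[idx], train=True))
            opt.step()
        val_acc = float(np.mean(model.predict(Xval) == yval))
        history["epoch"].append(epoch + 1)
        history["lr"].append(opt.lr)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        stop = stopper.update(val_acc)
        key = (val_acc, -history["train_loss"][-1])
        if key > best_key:
            best_key = key
            best_state = model.get_state()
        if stop:
            break
    model.set_state(best_state)
    history["best_epoch"] = stopper.best_epoch
    history["stopped_epoch"] = stopper.epoch
    return history


def train(model_config: ModelConfig, train_config: TrainConfig, train_segments, val_segments, task: str):
    """Fit a classifier on pre-split train/validation segments; returns
    ``(model, history)`` with the best-validation checkpoint loaded."""
    Xtr, ytr, _ = segments_to_arrays(train_segments, task, model_config.modalities)
    Xval, yval, _ = segments_to_arrays(val_segments, task, model_config.modalities)
    model = TransformerClassifier(model_config, seed=train_config.seed)
    rng = np.random.default_rng(train_config.seed + 1)
    history = _fit_arrays(model, train_config, Xtr, ytr, Xval, yval, rng)
    return model, history


def evaluate_predictions(y_true, y_pred, n_classes: int, absent_class_policy: str = "exclude") -> dict:
    """Accuracy / macro precision / macro F1 (percent) and the
    row-normalised confusion matrix, from per-class counts."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    counts = np.zeros((n_classes, n_classes), dtype=float)
    np.add.at(counts, (y_true, y_pred), 1.0)

    accuracy = float(np.trace(counts) / counts.sum())
    per_class = {}
    precisions, f1s = [], []
    for c in range(n_classes):
        tp = counts[c, c]
        fp = counts[:, c].sum() - tp
        fn = counts[c, :].sum() - tp
        present = (tp + fp + fn) > 0
        if not present:
            if absent_class_policy == "exclude":
                warnings.warn(
                    f"class {c} absent from truth and prediction; excluded from macro means",
                    stacklevel=2,
                )
                continue
            prec = rec = f1 = 0.0
        else:
            prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
            rec = tp / (tp + fn) if (tp + fn) > 0 else 0.0
            f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        per_class[c] = {"precision": prec, "recall": rec, "f1": f1, "support": int(counts[c, :].sum())}
        precisions.append(prec)
        f1s.append(f1)

    row_sums = counts.sum(axis=1, keepdims=True)
    confusion = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    return {
        "accuracy": 100.0 * accuracy,
        "macro_precision": 100.0 * float(np.mean(precisions)),
        "macro_f1": 100.0 * float(np.mean(f1s)),
        "confusion": confusion,
        "per_class": per_class,
        "n": int(counts.sum()),
    }


def evaluate(model: TransformerClassifier, test_segments, task: str, absent_class_policy: str = "exclude") -> EvalReport:
    """Score a fitted classifier on held-out segments."""
    Xte, yte, _ = segments_to_arrays(test_segments, task, model.config.modalities)
    y_pred = model.predict(Xte)
    _, n_classes = TASKS[task]
    m = evaluate_predictions(yte, y_pred, n_classes, absent_class_policy)
    return EvalReport(
        task=task,
        modalities=tuple(model.config.modalities),
        accuracy=m["accuracy"],
        macro_precision=m["macro_precision"],
        macro_f1=m["macro_f1"],
        confusion=m["confusion"],
        n_test=m["n"],
        per_class=m["per_class"],
    )


def _fit_and_score(segments, task, model_config, train_config):
    """One experiment cell on a shared subject split."""
    model_config = replace(model_config, n_classes=TASKS[task][1])
    train_side, test_side = split_by_subject(segments, train_config.split_ratio, train_config.seed)
    X, y, subj = segments_to_arrays(train_side, task, model_config.modalities)
    rng = np.random.default_rng(train_config.seed + 2)
    (Xtr, ytr), (Xval, yval) = _carve_validation(X, y, subj, train_config.val_fraction, rng)
    model = TransformerClassifier(model_config, seed=train_config.seed)
    history = _fit_arrays(model, train_config, Xtr, ytr, Xval, yval, np.random.default_rng(train_config.seed + 1))
    report = evaluate(model, test_side, task)
    return model, history, report


def run_modality_ablation(segments, tasks, model_config: ModelConfig | None = None, train_config: TrainConfig | None = None):
    """One run per (modality subset × task) on a shared split and seed.

    Single-modality and pairwise cells instantiate a model with only the
    named branches (not a zero-masked full model).
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    reports = []
    for subset in ABLATION_SUBSETS:
        for task in tasks:
            cfg = replace(model_config, modalities=subset)
            _, _, report = _fit_and_score(segments, task, cfg, train_config)
            reports.append(report)
    return reports


def run_grid(segments, batch_sizes, inner_dims, tasks, model_config: ModelConfig | None = None, train_config: TrainConfig | None = None):
    """Cartesian hyperparameter sweep with shared splits and seeds; the
    inner dimension sets the attention head count."""
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    rows = []
    for bs, inner in itertools.product(batch_sizes, inner_dims):
        row = {"batch_size": bs, "inner_dimension": inner}
        for task in tasks:
            cfg = replace(model_config, inner_dimension=inner)
            tc = replace(train_config, batch_size=bs)
            _, _, report = _fit_and_score(segments, task, cfg, tc)
            row[f"{task}_acc"] = report.accuracy
            row[f"{task}_f1"] = report.macro_f1
        rows.append(row)
    return rows


def reports_to_csv(reports, path) -> None:
    """Serialize EvalReports (or grid rows) to a flat CSV."""
    rows = [r.to_dict() if isinstance(r, EvalReport) else dict(r) for r in reports]
    for r in rows:
        r.pop("confusion", None)
        r.pop("per_class", None)
        if isinstance(r.get("modalities"), list):
            r["modalities"] = "+".join(r["modalities"])
    fieldnames = sorted({k for r in rows for k in r})
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
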