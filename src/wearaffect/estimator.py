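"""Model/Results surface over the classifier and the training protocol.

``AffectiveStateModel`` is constructed from data (a list of segments or an
archive on disk) plus configuration; ``fit()`` runs the subject-wise
protocol — carve a validation slice from the training subjects, optimize
with Adam under linear learning-rate decay and early stopping — and returns
an ``AffectiveStateResults`` carrying the fitted parameters, the training
history, evaluation and prediction methods, a text ``summary()`` and
plotting helpers.
"""

from __future__ import annotations

import json
from dataclasses import replace

import numpy as np

from . import io as _io
from . import train_eval as _te
from .network import ModelConfig, TransformerClassifier
from .train_eval import EvalReport, TrainConfig

__all__ = ["AffectiveStateModel", "AffectiveStateResults"]


class AffectiveStateModel:
    """An affective-state classification problem bound to data.

    Parameters
    ----------
    segments
        labelled :class:`~wearaffect.io.Segment` objects (typically the
        subject-wise *training* side of a split).
    task
        one of ``panas_binary``, ``valence_5``, ``arousal_5``,
        ``valence_binary``, ``arousal_binary``.
    model_config, train_config
        architecture and optimisation settings; defaults follow the
        reference protocol.
    """

    def __init__(
        self,
        segments,
        task: str = "panas_binary",
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        if task not in _te.TASKS:
            raise ValueError(f"unknown task {task!r}; choose from {sorted(_te.TASKS)}")
        self.segments = list(segments)
        if not self.segments:
            raise ValueError("no segments supplied")
        self.task = task
        _, n_classes = _te.TASKS[task]
        self.model_config = model_config or ModelConfig(n_classes=n_classes)
        if self.model_config.n_classes != n_classes:
            raise ValueError(
                f"model_config.n_classes={self.model_config.n_classes} does not match task {task!r} ({n_classes})"
            )
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_archive(cls, path, task: str = "panas_binary", **kwargs) -> "AffectiveStateModel":
        """Build from a processed-segment archive on disk."""
        return cls(_io.read_segment_archive(path), task=task, **kwargs)

    @property
    def subjects(self) -> list[str]:
        return sorted({s.subject_id for s in self.segments})

    def fit(self, seed: int | None = None) -> "AffectiveStateResults":
        """Train with a subject-wise validation carve-out; returns results
        holding the best-validation checkpoint."""
        tc = self.train_config if seed is None else replace(self.train_config, seed=seed)
        X, y, subj = _te.segments_to_arrays(self.segments, self.task, self.model_config.modalities)
        rng = np.random.default_rng(tc.seed + 2)
        (Xtr, ytr), (Xval, yval) = _te._carve_validation(X, y, subj, tc.val_fraction, rng)
        network = TransformerClassifier(self.model_config, seed=tc.seed)
        history = _te._fit_arrays(network, tc, Xtr, ytr, Xval, yval, np.random.default_rng(tc.seed + 1))
        return AffectiveStateResults(self, network, history)


class AffectiveStateResults:
    """Fitted parameters, history and diagnostics of one training run."""

    def __init__(self, model: AffectiveStateModel, network: TransformerClassifier, history: dict):
        self.model = model
        self.network = network
        self.history = history

    # -- inference ---------------------------------------------------------
    def predict(self, segments) -> np.ndarray:
        X, _, _ = _te.segments_to_arrays(segments, self.model.task, self.network.config.modalities)
        return self.network.predict(X)

    def predict_proba(self, segments) -> np.ndarray:
        X, _, _ = _te.segments_to_arrays(segments, self.model.task, self.network.config.modalities)
        return self.network.predict_proba(X)

    def evaluate(self, test_segments) -> EvalReport:
        """Score on held-out (subject-disjoint) segments."""
        return _te.evaluate(self.network, test_segments, self.model.task)

    # -- reporting ---------------------------------------------------------
    def summary(self, report: EvalReport | None = None) -> str:
        cfg, tc = self.network.config, self.model.train_config
        h = self.history
        lines = [
            "Affective-state classifier".center(62),
            "=" * 62,
            f"{'Task:':<24}{self.model.task}",
            f"{'Modalities:':<24}{'+'.join(cfg.modalities)}",
            f"{'Encoder:':<24}{cfg.n_layers} layers, {cfg.n_heads} heads, width {cfg.d_model}",
            f"{'Parameters:':<24}{self.network.n_parameters}",
            f"{'Training subjects:':<24}{len(self.model.subjects)}",
            f"{'Epochs run:':<24}{h['stopped_epoch']} (best epoch {h['best_epoch']})",
            f"{'Best val accuracy:':<24}{100 * max(h['val_accuracy']):.2f}%",
            f"{'Final train loss:':<24}{h['train_loss'][-1]:.4f}",
            f"{'Optimizer:':<24}Adam lr0={tc.lr0} wd={tc.weight_decay} batch={tc.batch_size}",
        ]
        if report is not None:
            lines += [
                "-" * 62,
                f"{'Test accuracy:':<24}{report.accuracy:.2f}%  (n={report.n_test})",
                f"{'Macro precision:':<24}{report.macro_precision:.2f}%",
                f"{'Macro F1:':<24}{report.macro_f1:.2f}%",
            ]
        lines.append("=" * 62)
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: weights plus a config snapshot, in HDF5."""
        import h5py

        from dataclasses import asdict

        with h5py.File(path, "w") as f:
            f.attrs["task"] = self.model.task
            f.attrs["model_config"] = json.dumps(asdict(self.network.config))
            f.attrs["history"] = json.dumps(self.history)
            for i, arr in enumerate(self.network.get_state()):
                f.create_dataset(f"param_{i:04d}", data=arr)

    @staticmethod
    def load_network(path) -> tuple[TransformerClassifier, dict]:
        """Rebuild the fitted network (and history) from a checkpoint."""
        import h5py

        with h5py.File(path, "r") as f:
            cfg_dict = json.loads(f.attrs["model_config"])
            cfg_dict["modalities"] = tuple(cfg_dict["modalities"])
            for key in ("kernel_sizes", "strides"):
                cfg_dict[key] = tuple(cfg_dict[key])
            cfg = ModelConfig(**cfg_dict)
            state = [f[k][()] for k in sorted(f.keys())]
            history = json.loads(f.attrs["history"])
        network = TransformerClassifier(cfg, seed=0)
        network.set_state(state)
        return network, history

    # -- plotting ----------------------------------------------------------
    def plot_history(self, ax=None):
        """Training loss and validation accuracy per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train loss")
        ax2 = ax.twinx()
        ax2.plot(self.history["epoch"], self.history["val_accuracy"], color="C1", label="val accuracy")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy")
        ax2.set_ylabel("validation accuracy")
        ax.axvline(self.history["best_epoch"], ls="--", color="grey", lw=0.8)
        return ax

    def plot_confusion(self, report: EvalReport, ax=None):
        """Row-normalised confusion matrix (rows = true labels)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        C = report.confusion
        im = ax.imshow(C, vmin=0, vmax=1, cmap="Blues")
        for i in range(C.shape[0]):
            for j in range(C.shape[1]):
                ax.text(j, i, f"{C[i, j]:.2f}", ha="center", va="center", fontsize=8)
        ax.set_xlabel("predicted label")
        ax.set_ylabel("true label")
        ax.set_title(report.task)
        plt.colorbar(im, ax=ax)
        return ax
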