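"""Desk-scale experiment presets: one place defining the reduced problem
sizes used for fully synthetic end-to-end runs.

The study-shape defaults live in :class:`~wearaffect.synthetic.SimConfig`
(12 subjects × 1 day × 10 prompts, 300-second windows); this module adds
the matching classifier size — a narrow encoder (width 32, 2 layers,
4 heads) that trains in seconds on one CPU while keeping every
architectural element of the full model — and a runner that executes the
complete protocol: simulate → condition → subject-wise split → fit →
evaluate.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .estimator import AffectiveStateModel
from .network import ModelConfig
from .preprocess import PreprocessConfig
from .synthetic import SimConfig, iter_subjects
from .train_eval import TASKS, TrainConfig, split_by_subject

__all__ = ["desk_model_config", "build_segments", "run_desk_experiment"]


def desk_model_config(n_classes: int = 2, modalities=("hr", "gsr", "accel"), **overrides) -> ModelConfig:
    """The reduced-width architecture used for synthetic desk-scale runs."""
    kwargs = dict(
        modalities=tuple(modalities),
        embed_dim=8,
        cnn_hidden=16,
        d_model=32,
        n_layers=2,
        n_heads=4,
        ffn_dim=64,
        dropout=0.2,
        n_classes=n_classes,
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def build_segments(sim_cfg: SimConfig, pre_cfg: PreprocessConfig | None = None):
    """Simulate every subject and run the conditioning chain in memory."""
    from .preprocess import preprocess_subject

    pre_cfg = pre_cfg or PreprocessConfig(window_s=sim_cfg.window_s)
    segments = []
    for _, channels, esm in iter_subjects(sim_cfg):
        segs, _ = preprocess_subject(channels, esm, pre_cfg)
        segments.extend(segs)
    return segments


def run_desk_experiment(
    seed: int,
    task: str = "panas_binary",
    sim_cfg: SimConfig | None = None,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
):
    """Full protocol at desk scale; returns ``(results, report)``.

    The same integer seeds the generator, the subject split, the weight
    initialisation and the batch shuffling, so a run is reproducible
    end to end.
    """
    sim_cfg = replace(sim_cfg, seed=seed) if sim_cfg is not None else SimConfig(seed=seed)
    segments = build_segments(sim_cfg)
    train_cfg = replace(train_cfg, seed=seed) if train_cfg is not None else TrainConfig(seed=seed)
    model_cfg = model_cfg or desk_model_config(n_classes=TASKS[task][1])
    train_side, test_side = split_by_subject(segments, train_cfg.split_ratio, seed)
    results = AffectiveStateModel(
        train_side, task=task, model_config=model_cfg, train_config=train_cfg
    ).fit()
    report = results.evaluate(test_side)
    return results, report
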