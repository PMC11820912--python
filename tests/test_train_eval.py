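"""Splitting, early stopping, metrics and the experiment runners."""

import numpy as np
import pytest

from wearaffect.network import ModelConfig, TransformerClassifier
from wearaffect.train_eval import (
    ABLATION_SUBSETS,
    EarlyStopping,
    TrainConfig,
    _fit_arrays,
    evaluate_predictions,
    linear_decay_lr,
    reports_to_csv,
    run_grid,
    run_modality_ablation,
    segments_to_arrays,
    split_by_subject,
)
from conftest import make_esm, make_segment


def _segments(n_subjects=10, per_subject=3, T=24):
    segs = []
    for i in range(n_subjects):
        for k in range(per_subject):
            segs.append(make_segment(subject_id=f"sub-{i:03d}", esm_timestamp=1e9 + 1000 * i + k, T=T))
    return segs


class TestSplit:
    def test_eight_two_subject_counts(self):
        train, test = split_by_subject(_segments(10), 0.8, seed=0)
        assert len({s.subject_id for s in train}) == 8
        assert len({s.subject_id for s in test}) == 2

    def test_seed_reproducibility_and_variation(self):
        segs = _segments(10)
        a1 = {s.subject_id for s in split_by_subject(segs, 0.8, 5)[1]}
        a2 = {s.subject_id for s in split_by_subject(segs, 0.8, 5)[1]}
        assert a1 == a2
        others = [{s.subject_id for s in split_by_subject(segs, 0.8, k)[1]} for k in range(10)]
        assert any(o != a1 for o in others)

    def test_no_subject_overlap(self):
        train, test = split_by_subject(_segments(9), 0.8, seed=3)
        assert not ({s.subject_id for s in train} & {s.subject_id for s in test})

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            split_by_subject(_segments(1), 0.8, 0)


def test_linear_decay_halves_at_midpoint():
    assert linear_decay_lr(1e-3, 50, 100) == pytest.approx(5e-4)
    assert linear_decay_lr(1e-3, 0, 100) == pytest.approx(1e-3)


def test_early_stopping_fires_exactly_at_patience():
    """Validation trace .5, then ten flat .6 epochs: best is epoch 2 and
    the stop signal arrives at epoch 12."""
    stopper = EarlyStopping(patience=10)
    trace = [0.5] + [0.6] * 19
    stop_epochs = [e + 1 for e, v in enumerate(trace) if stopper.update(v)]
    assert stop_epochs[0] == 12
    assert stopper.best_epoch == 2


class TestMetrics:
    def test_perfect_prediction(self):
        m = evaluate_predictions([0, 1, 0, 1], [0, 1, 0, 1], 2)
        assert m["accuracy"] == 100.0
        assert m["macro_f1"] == 100.0
        assert np.allclose(m["confusion"], np.eye(2))

    def test_hand_computed_binary_counts(self):
        # confusion counts [[2, 0], [1, 1]]: acc 3/4, precisions (2/3, 1),
        # recalls (1, 1/2), F1s (0.8, 2/3)
        y_true = [0, 0, 1, 1]
        y_pred = [0, 0, 0, 1]
        m = evaluate_predictions(y_true, y_pred, 2)
        assert m["accuracy"] == pytest.approx(75.0)
        assert m["macro_precision"] == pytest.approx(83.33, abs=0.01)
        assert m["macro_f1"] == pytest.approx(73.33, abs=0.01)

    def test_all_one_class_predictor_on_balanced_data(self):
        # predicted-empty class keeps defined recall 0, scoring F1 0
        m = evaluate_predictions([0, 0, 1, 1], [0, 0, 0, 0], 2)
        assert m["accuracy"] == pytest.approx(50.0)
        assert m["macro_f1"] == pytest.approx((66.67 + 0.0) / 2, abs=0.01)

    def test_class_absent_everywhere_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="class 2"):
            m = evaluate_predictions([0, 1], [0, 1], 3)
        assert m["macro_f1"] == 100.0

    def test_matches_sklearn_on_random_pairs(self, rng):
        from sklearn.metrics import f1_score, precision_score

        for _ in range(40):
            C = int(rng.choice([2, 5]))
            n = 40
            y_true = rng.integers(0, C, n)
            y_pred = rng.integers(0, C, n)
            if len(np.unique(np.concatenate([y_true, y_pred]))) < C:
                continue
            m = evaluate_predictions(y_true, y_pred, C)
            assert m["macro_precision"] == pytest.approx(
                100 * precision_score(y_true, y_pred, average="macro", zero_division=0)
            )
            assert m["macro_f1"] == pytest.approx(
                100 * f1_score(y_true, y_pred, average="macro", zero_division=0)
            )

    def test_accuracy_consistent_with_confusion_matrix(self, rng):
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        m = evaluate_predictions(y_true, y_pred, 3)
        support = np.array([np.sum(y_true == c) for c in range(3)], dtype=float)
        acc_from_cm = np.sum(np.diag(m["confusion"]) * support) / support.sum()
        assert m["accuracy"] == pytest.approx(100 * acc_from_cm)
        present = support > 0
        assert np.allclose(m["confusion"][present].sum(axis=1), 1.0)


def _toy_training_setup(rng, n=24, T=16):
    y = np.arange(n) % 2
    X = rng.normal(size=(n, T, 3)) + (1.5 * (2 * y - 1))[:, None, None]
    cfg = ModelConfig(embed_dim=3, cnn_hidden=4, d_model=8, n_layers=1, n_heads=2,
                      ffn_dim=8, dropout=0.2, n_classes=2)
    return X, y, cfg


def test_training_history_is_deterministic(rng):
    X, y, cfg = _toy_training_setup(rng)
    tc = TrainConfig(max_epochs=8, early_stop_patience=4, batch_size=8, seed=3)
    histories = []
    for _ in range(2):
        model = TransformerClassifier(cfg, seed=3)
        histories.append(
            _fit_arrays(model, tc, X[:16], y[:16], X[16:], y[16:], np.random.default_rng(3))
        )
    assert histories[0] == histories[1]


def test_nan_loss_aborts_with_diagnostic(rng):
    X, y, cfg = _toy_training_setup(rng)
    model = TransformerClassifier(cfg, seed=0)
    model.head.W.data[...] = np.inf
    with pytest.raises(FloatingPointError), np.errstate(invalid="ignore"):
        model.loss_and_grad(X, y)


class TestRunners:
    def _planted_segments(self, rng, n_subjects=6, per_subject=6, T=24):
        """HR channel carries a clean class shift; GSR/ACCEL are noise."""
        from wearaffect.labels import label_set

        segs = []
        for i in range(n_subjects):
            for k in range(per_subject):
                pos = (i + k) % 2 == 1
                esm = make_esm(
                    subject_id=f"sub-{i:03d}",
                    timestamp=1e9 + 1000 * i + k,
                    items={n: (5 if pos else 1) for n in ("inspired", "active", "determined", "attentive")},
                    valence=5 if pos else 1,
                    arousal=5 if pos else 1,
                )
                s = make_segment(subject_id=esm.subject_id, esm_timestamp=esm.timestamp, T=T,
                                 labels=label_set(esm).to_dict())
                s.matrix[:] = rng.normal(size=(T, 3))
                s.matrix[:, 0] += 3.0 if pos else -3.0
                segs.append(s)
        return segs

    def _small_cfgs(self):
        mc = ModelConfig(embed_dim=3, cnn_hidden=4, d_model=8, n_layers=1, n_heads=2,
                         ffn_dim=8, dropout=0.1, n_classes=2)
        tc = TrainConfig(max_epochs=6, early_stop_patience=3, batch_size=8, seed=0)
        return mc, tc

    def test_ablation_produces_ordered_cells(self, rng):
        segs = self._planted_segments(rng)
        mc, tc = self._small_cfgs()
        reports = run_modality_ablation(segs, ["panas_binary"], mc, tc)
        assert len(reports) == len(ABLATION_SUBSETS) == 7
        assert [r.modalities for r in reports] == list(ABLATION_SUBSETS)

    def test_hr_branch_beats_noise_branch_on_hr_planted_signal(self, rng):
        from wearaffect.train_eval import _fit_and_score

        segs = self._planted_segments(rng, n_subjects=8, per_subject=8)
        mc, _ = self._small_cfgs()
        tc = TrainConfig(max_epochs=25, early_stop_patience=10, batch_size=8, seed=1)
        from dataclasses import replace

        _, _, hr_rep = _fit_and_score(segs, "panas_binary", replace(mc, modalities=("hr",)), tc)
        _, _, acc_rep = _fit_and_score(segs, "panas_binary", replace(mc, modalities=("accel",)), tc)
        assert hr_rep.accuracy > acc_rep.accuracy

    def test_grid_cells_and_serialization(self, rng, tmp_path):
        import csv

        segs = self._planted_segments(rng)
        mc, tc = self._small_cfgs()
        rows = run_grid(segs, [8, 16], [2, 4], ["panas_binary"], mc, tc)
        assert len(rows) == 4
        assert {(r["batch_size"], r["inner_dimension"]) for r in rows} == {(8, 2), (8, 4), (16, 2), (16, 4)}
        out = tmp_path / "grid.csv"
        reports_to_csv(rows, out)
        with open(out) as fh:
            parsed = list(csv.DictReader(fh))
        assert len(parsed) == 4 and "panas_binary_acc" in parsed[0]


def test_segments_to_arrays_excludes_undefined_labels():
    segs = _segments(4, per_subject=2)
    for s in segs[:3]:
        s.labels["panas_class"] = None
    X, y, subj = segments_to_arrays(segs, "panas_binary")
    assert len(y) == len(segs) - 3
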