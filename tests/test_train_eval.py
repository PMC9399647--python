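import numpy as np
import pytest

from ladgcn.fusion_head import cross_entropy
from ladgcn.train_eval import (
    TrainConfig,
    TrainedModel,
    compute_metrics,
    evaluate,
    init_model,
    stratified_split,
    train,
)


class TestComputeMetrics:
    def test_confusion_table_example(self):
        # class 0 one-vs-rest: TP=3, FP=1, FN=2
        y_true = [0, 0, 0, 0, 0, 1]
        y_pred = [0, 0, 0, 1, 1, 0]
        rep = compute_metrics(y_true, y_pred, 2)
        row = rep.per_class.iloc[0]
        assert (row.TP, row.FP, row.FN) == (3, 1, 2)
        assert row.P == pytest.approx(75.0)
        assert row.R == pytest.approx(60.0)
        assert row.F1S == pytest.approx(66.67, abs=0.01)

    def test_perfect_predictions_score_100(self):
        y = [0, 1, 2, 0, 1, 2]
        rep = compute_metrics(y, y, 3)
        assert rep.accuracy == 100.0
        assert np.allclose(rep.per_class[["P", "R", "F1S"]].values, 100.0)

    def test_never_predicted_class_gets_zero_precision_with_warning(self):
        with pytest.warns(UserWarning):
            rep = compute_metrics([0, 0, 1], [0, 0, 0], 2)
        assert rep.per_class.iloc[1].P == 0.0

    def test_matches_sklearn_one_vs_rest(self):
        from sklearn.metrics import accuracy_score, precision_recall_fscore_support

        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        rep = compute_metrics(y_true, y_pred, 4)
        p, r, f1, _ = precision_recall_fscore_support(y_true, y_pred, labels=range(4), zero_division=0)
        assert np.allclose(rep.per_class.P / 100, p, atol=1e-12)
        assert np.allclose(rep.per_class.R / 100, r, atol=1e-12)
        assert np.allclose(rep.per_class.F1S / 100, f1, atol=1e-12)
        assert rep.accuracy / 100 == pytest.approx(accuracy_score(y_true, y_pred))

    def test_micro_accuracy_equals_confusion_trace_ratio(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 3, 90)
        y_pred = rng.integers(0, 3, 90)
        rep = compute_metrics(y_true, y_pred, 3)
        assert rep.accuracy == pytest.approx(100 * np.trace(rep.confusion) / rep.confusion.sum())

    def test_f1_is_harmonic_mean_of_p_and_r(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, 120)
        y_pred = rng.integers(0, 3, 120)
        rep = compute_metrics(y_true, y_pred, 3)
        for _, row in rep.per_class.iterrows():
            if row.P + row.R > 0:
                assert row.F1S == pytest.approx(2 * row.P * row.R / (row.P + row.R), abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [], 2)


class TestSplit:
    def test_stratified_split_is_deterministic_and_partitions(self):
        labels = np.repeat([0, 1, 2], 20)
        s1 = stratified_split(labels, (0.7, 0.15, 0.15), seed=3)
        s2 = stratified_split(labels, (0.7, 0.15, 0.15), seed=3)
        for a, b in zip(s1, s2):
            assert np.array_equal(a, b)
        merged = np.concatenate(s1)
        assert np.array_equal(np.sort(merged), np.arange(60))
        for c in range(3):
            assert (labels[s1[0]] == c).sum() == 14


class TestTraining:
    def test_initial_loss_near_log_n_classes(self, small_samples):
        samples, labels, class_names = small_samples
        model = init_model("gcn_only", class_names, samples[0].feats.shape[1], seed=0)
        model.feat_norm.fit(np.concatenate([s.feats for s in samples]))
        loss = cross_entropy(model.predict_proba(samples[:12]), labels[:12])
        assert abs(loss - np.log(3)) / np.log(3) < 0.2

    def test_single_class_manifest_rejected(self, small_samples):
        samples, labels, class_names = small_samples
        idx = np.flatnonzero(labels == 0)
        with pytest.raises(ValueError):
            train([samples[i] for i in idx], labels[idx], class_names, TrainConfig(epochs=1))

    def test_training_log_is_bit_identical_across_runs(self, small_samples):
        samples, labels, class_names = small_samples
        cfg = TrainConfig(mode="gcn_only", epochs=3, seed=4)
        log1 = train(samples, labels, class_names, cfg).log
        log2 = train(samples, labels, class_names, cfg).log
        assert log1.to_csv(index=False) == log2.to_csv(index=False)

    def test_gcn_only_predictions_ignore_tile_image_tensor(self, small_samples):
        import dataclasses

        samples, labels, class_names = small_samples
        res = train(samples, labels, class_names, TrainConfig(mode="gcn_only", epochs=5, seed=0))
        rng = np.random.default_rng(0)
        scrambled = [
            dataclasses.replace(s, image_small=rng.permutation(s.image_small.ravel()).reshape(s.image_small.shape))
            for s in samples[:10]
        ]
        assert np.array_equal(res.model.predict(samples[:10]), res.model.predict(scrambled))

    def test_overfit_small_training_split(self, small_samples):
        samples, labels, class_names = small_samples
        res = train(samples, labels, class_names, TrainConfig(mode="gcn_only", epochs=30, seed=1))
        tr = res.split["train"]
        rep, preds = evaluate(res.model, [samples[i] for i in tr], labels[tr])
        assert rep.accuracy >= 95.0
        assert len(preds) == tr.size
        assert set(preds.columns) == {"tile", "true", "pred", "prob_0", "prob_1", "prob_2"}

    def test_checkpoint_roundtrip_preserves_predictions(self, small_samples, tmp_path):
        samples, labels, class_names = small_samples
        res = train(samples, labels, class_names, TrainConfig(mode="gcn_only", epochs=3, seed=2))
        probs = res.model.predict_proba(samples[:8])
        path = tmp_path / "model.npz"
        res.model.save(path)
        back = TrainedModel.load(path)
        assert back.mode == "gcn_only"
        assert back.class_names == class_names
        assert np.allclose(back.predict_proba(samples[:8]), probs, atol=1e-12)
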