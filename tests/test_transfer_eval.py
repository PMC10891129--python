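"""Tests of the freeze semantics, fold bookkeeping and CV protocol."""

import numpy as np
import pytest

from conformnet import (
    LayeredModelSpec,
    TrainingConfig,
    TransferConfig,
    adapt_classifier_head,
    apply_transfer_mode,
    build_model,
    five_fold_cv,
    fold_assignment,
    predict_label,
    predict_proba,
    pretrain_source,
    train_classifier,
)

SPEC2 = LayeredModelSpec(n_classes=2, weight_seed=0)
SPEC4 = LayeredModelSpec(n_classes=4, weight_seed=0)


def fast_training(seed=0, epochs=1):
    return TrainingConfig(learning_rate=1e-3, epochs=epochs, batch_size=8, seed=seed)


def weights_equal(a, b):
    return len(a) == len(b) and all(np.array_equal(u, v) for u, v in zip(a, b))


class TestSpecValidation:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            LayeredModelSpec(conv_blocks=())
        with pytest.raises(ValueError):
            LayeredModelSpec(dropout_rate=1.0)
        with pytest.raises(ValueError):
            LayeredModelSpec(n_classes=1)
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0.0)


class TestFoldAssignment:
    def test_partition_invariants_across_sizes(self):
        for n in range(5, 301, 7):
            fa = fold_assignment(n, 5, seed=n)
            sizes = fa.sizes()
            assert sum(sizes) == n
            assert max(sizes) - min(sizes) <= 1
            covered = np.concatenate([fa.fold_indices(f) for f in range(5)])
            assert sorted(covered) == list(range(n))

    def test_default_corpus_fold_sizes(self):
        assert sorted(fold_assignment(224, 5, seed=0).sizes()) == [44, 45, 45, 45, 45]

    def test_ten_items_make_folds_of_two(self):
        assert fold_assignment(10, 5, seed=1).sizes() == [2, 2, 2, 2, 2]

    def test_stratified_mode_balances_classes(self):
        labels = ["healthy"] * 50 + ["T2D"] * 50
        fa = fold_assignment(100, 5, seed=2, labels=labels)
        arr = np.asarray(labels)
        for f in range(5):
            fold_labels = arr[fa.fold_indices(f)]
            assert abs((fold_labels == "healthy").sum() - (fold_labels == "T2D").sum()) <= 1

    def test_too_small_corpus_rejected(self):
        with pytest.raises(ValueError):
            fold_assignment(4, 5, seed=0)


class TestPredictLabel:
    def test_threshold_rule(self):
        assert predict_label(0.7) == "healthy"
        assert predict_label(0.5) == "T2D"  # strict inequality
        assert predict_label(0.2) == "T2D"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            predict_label(1.3)


class TestHeadAdaptation:
    def test_conv_base_untouched_and_head_rebuilt(self):
        model = build_model(SPEC4)
        conv_before = model.conv_weights()
        old_head = [p.copy() for layer in model.head_layers for p in layer.params.values()]
        adapt_classifier_head(model, 2, head_seed=9)
        assert weights_equal(model.conv_weights(), conv_before)
        assert model.head_layers[-1].params["b"].shape == (2,)
        new_first = model.head_layers[0].params["W"]
        assert not np.array_equal(new_first, old_head[0])

    def test_adaptation_is_idempotent_in_shape(self):
        model = build_model(SPEC4)
        adapt_classifier_head(model, 2, head_seed=1)
        adapt_classifier_head(model, 2, head_seed=2)
        assert model.head_layers[-1].params["b"].shape == (2,)
        out = predict_proba(model, np.random.default_rng(0).random((3, 32, 32, 3)).astype("float32"))
        assert out.shape == (3, 2)

    def test_invalid_class_count_rejected(self):
        with pytest.raises(ValueError):
            adapt_classifier_head(build_model(SPEC4), 1)


class TestTransferModes:
    def test_tfe_freezes_all_blocks(self):
        model = apply_transfer_mode(build_model(SPEC2), TransferConfig(mode="TFE"))
        assert all(
            not layer.trainable for b in range(model.n_blocks) for layer in model.block_layers(b)
        )
        assert all(layer.trainable for layer in model.head_layers)

    def test_tft_freezes_bottom_blocks_only(self):
        model = apply_transfer_mode(
            build_model(SPEC2), TransferConfig(mode="TFT", freeze_blocks=2)
        )
        assert all(not l.trainable for l in model.block_layers(0))
        assert all(not l.trainable for l in model.block_layers(1))
        assert all(l.trainable for l in model.block_layers(2))

    def test_tft_rejects_freezing_everything(self):
        with pytest.raises(ValueError):
            apply_transfer_mode(build_model(SPEC2), TransferConfig(mode="TFT", freeze_blocks=3))

    def test_scratch_reinitializes_and_freezes_nothing(self):
        model = build_model(SPEC2)
        before = model.all_weights()
        model = apply_transfer_mode(model, TransferConfig(mode="SCRATCH", training=fast_training()))
        assert all(layer.trainable for layer in model.layers if layer.params)
        assert not weights_equal(model.all_weights(), before)


class TestTrainingContracts:
    def test_tfe_training_leaves_conv_base_bit_identical(self, tiny_corpus):
        model = build_model(SPEC2)
        apply_transfer_mode(model, TransferConfig(mode="TFE", training=fast_training()))
        conv_before = model.conv_weights()
        head_before = [l.params["W"].copy() for l in model.head_layers if "W" in l.params]
        train_classifier(model, tiny_corpus, TransferConfig(mode="TFE", training=fast_training()))
        assert weights_equal(model.conv_weights(), conv_before)
        head_after = [l.params["W"] for l in model.head_layers if "W" in l.params]
        assert not weights_equal(head_after, head_before)

    def test_tft_training_freezes_bottom_and_moves_top(self, tiny_corpus):
        config = TransferConfig(mode="TFT", freeze_blocks=2, training=fast_training())
        model = apply_transfer_mode(build_model(SPEC2), config)
        bottom_before = [
            l.params["W"].copy() for b in (0, 1) for l in model.block_layers(b) if "W" in l.params
        ]
        top_before = [l.params["W"].copy() for l in model.block_layers(2) if "W" in l.params]
        train_classifier(model, tiny_corpus, config)
        bottom_after = [
            l.params["W"] for b in (0, 1) for l in model.block_layers(b) if "W" in l.params
        ]
        top_after = [l.params["W"] for l in model.block_layers(2) if "W" in l.params]
        assert weights_equal(bottom_after, bottom_before)
        assert not weights_equal(top_after, top_before)

    def test_scratch_training_moves_every_tensor(self, tiny_corpus):
        config = TransferConfig(mode="SCRATCH", training=fast_training(epochs=2))
        model = apply_transfer_mode(build_model(SPEC2), config)
        before = model.all_weights()
        train_classifier(model, tiny_corpus, config)
        after = model.all_weights()
        assert all(not np.array_equal(a, b) for a, b in zip(after, before))

    def test_zero_epochs_is_noop(self, tiny_corpus):
        config = TransferConfig(mode="SCRATCH", training=fast_training(epochs=0))
        model = apply_transfer_mode(build_model(SPEC2), config)
        before = model.all_weights()
        train_classifier(model, tiny_corpus, config)
        assert weights_equal(model.all_weights(), before)

    def test_training_is_deterministic(self, tiny_corpus):
        results = []
        for _ in range(2):
            config = TransferConfig(mode="SCRATCH", training=fast_training(epochs=1))
            model = apply_transfer_mode(build_model(SPEC2), config)
            train_classifier(model, tiny_corpus, config)
            results.append(model.all_weights())
        assert weights_equal(results[0], results[1])


class TestPretraining:
    def test_class_count_mismatch_rejected(self, tiny_source_corpus):
        with pytest.raises(ValueError):
            pretrain_source(SPEC2, tiny_source_corpus, fast_training())

    def test_zero_epochs_equals_initialization(self, tiny_source_corpus):
        trained = pretrain_source(SPEC4, tiny_source_corpus, fast_training(epochs=0))
        assert weights_equal(trained.all_weights(), build_model(SPEC4).all_weights())

    def test_source_training_beats_chance(self, tiny_source_corpus):
        model = pretrain_source(
            SPEC4, tiny_source_corpus, TrainingConfig(learning_rate=1e-3, epochs=15, batch_size=8, seed=0)
        )
        proba = predict_proba(model, tiny_source_corpus.images)
        acc = (proba.argmax(1) == tiny_source_corpus.label_indices).mean()
        assert acc > 0.25


class TestFiveFoldCV:
    def test_every_item_tested_exactly_once(self, tiny_corpus):
        config = TransferConfig(mode="SCRATCH", training=fast_training(epochs=1))
        report = five_fold_cv(tiny_corpus, SPEC2, config, split_seed=3)
        assert report.combined_confusion.total == len(tiny_corpus)
        assert len(report.per_fold) == 5
        assert sum(cm.total for cm, _ in report.per_fold) == len(tiny_corpus)
        assert set(report.averages) == {"BAC", "ACC", "PRE", "REC", "F1"}
        frame = report.metrics_frame()
        assert len(frame) == 5

    def test_transfer_modes_require_source_model(self, tiny_corpus):
        with pytest.raises(ValueError):
            five_fold_cv(tiny_corpus, SPEC2, TransferConfig(mode="TFE"), split_seed=0)

    def test_too_small_corpus_rejected(self, tiny_corpus):
        from conformnet.synthetic_data import NetworkImageCorpus

        small = NetworkImageCorpus(
            images=tiny_corpus.images[:3],
            labels=tiny_corpus.labels[:3],
            class_names=tiny_corpus.class_names,
            class_params={},
            image_size=32,
            seed=0,
        )
        with pytest.raises(ValueError):
            five_fold_cv(small, SPEC2, TransferConfig(mode="SCRATCH"), split_seed=0)
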