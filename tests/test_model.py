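"""Fusion, dense head, loss, splitting, early stopping, training, evaluation."""

import numpy as np
import pytest

from deeppn import (
    BranchFeatureVector,
    DeepPNClassifier,
    DenseHeadParams,
    EarlyStopper,
    FusedFeature,
    LabeledDataset,
    ModelConfig,
    NucleotideSequence,
    TrainConfig,
    binary_cross_entropy,
    build_sequence_graph,
    chebnet_forward,
    cnn_forward,
    fuse,
    predict_proba,
    roc_auc,
    scaled_laplacian,
    split_dataset,
)
from deeppn.model import _Network


def make_dataset(n_pos, n_neg, length=15, seed=0, motif="UGCAUG"):
    rng = np.random.default_rng(seed)
    bases = "ACGU"
    records = []
    for i in range(n_pos):
        s = "".join(rng.choice(list(bases), size=length))
        pos = int(rng.integers(0, length - len(motif) + 1))
        s = s[:pos] + motif + s[pos + len(motif):]
        records.append((NucleotideSequence(f"p{i}", s), 1))
    for i in range(n_neg):
        s = "".join(rng.choice(list(bases), size=length))
        records.append((NucleotideSequence(f"n{i}", s.replace("UGCAUG", "UGCAUA")), 0))
    return LabeledDataset(tuple(records))


TINY_MODEL = ModelConfig(
    window_length=15, kernel_size=3, cnn_filters=(3, 4), cheb_channels=(3, 4),
    embed_channels=4, hidden_sizes=(8, 4), dropout_rate=0.2,
)


class TestFuse:
    def test_concatenation_order_and_length(self, rng):
        cheb = BranchFeatureVector(values=rng.normal(size=8), origin="chebnet")
        cnn = BranchFeatureVector(values=rng.normal(size=12), origin="cnn")
        fused = fuse(cheb, cnn)
        assert fused.values.size == 20
        assert np.array_equal(fused.values[:8], cheb.values)
        assert np.array_equal(fused.values[8:], cnn.values)

    def test_single_branch_ablation(self, rng):
        cheb = BranchFeatureVector(values=rng.normal(size=8), origin="chebnet")
        assert np.array_equal(fuse(cheb, None).values, cheb.values)

    def test_no_branch_rejected(self):
        with pytest.raises(ValueError):
            fuse(None, None)


class TestPredictProba:
    def _head(self, d, rng=None, scale=1.0):
        r = rng or np.random.default_rng(0)
        return DenseHeadParams(
            w1=scale * r.normal(size=(d, 6)), b1=np.zeros(6),
            w2=scale * r.normal(size=(6, 3)), b2=np.zeros(3),
            w3=scale * r.normal(size=(3, 1)), b3=np.zeros(1),
            dropout_rate=0.5,
        )

    def test_zero_weights_give_half(self):
        head = self._head(4, scale=0.0)
        p = predict_proba(FusedFeature(np.ones(4)), head)
        assert p == pytest.approx(0.5)

    def test_eval_mode_deterministic(self, rng):
        head = self._head(5, rng)
        H = FusedFeature(rng.normal(size=5))
        assert predict_proba(H, head) == predict_proba(H, head)

    def test_probability_monotone_in_final_bias(self, rng):
        head = self._head(5, rng)
        H = FusedFeature(rng.normal(size=5))
        probs = []
        for bias in (-5.0, 0.0, 5.0, 20.0):
            h2 = DenseHeadParams(
                w1=head.w1, b1=head.b1, w2=head.w2, b2=head.b2,
                w3=head.w3, b3=np.array([bias]), dropout_rate=0.5,
            )
            probs.append(predict_proba(H, h2))
        assert probs == sorted(probs)
        assert probs[-1] > 0.999

    def test_inconsistent_head_dimensions_rejected(self):
        with pytest.raises(ValueError):
            DenseHeadParams(
                w1=np.zeros((4, 6)), b1=np.zeros(6), w2=np.zeros((5, 3)),
                b2=np.zeros(3), w3=np.zeros((3, 1)), b3=np.zeros(1),
            )


class TestBinaryCrossEntropy:
    def test_near_perfect_prediction_is_near_zero(self):
        loss = binary_cross_entropy(np.array([1.0 - 1e-7]), np.array([1.0]))
        assert loss.sum == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_probabilities_closed_form(self):
        n = 9
        loss = binary_cross_entropy(np.full(n, 0.5), np.array([0, 1] * 4 + [1], dtype=float))
        assert loss.sum == pytest.approx(n * np.log(2), abs=1e-12)
        assert loss.mean == pytest.approx(np.log(2), abs=1e-12)

    def test_direct_formula(self):
        loss = binary_cross_entropy(np.array([0.8, 0.3]), np.array([1.0, 0.0]))
        assert loss.sum == pytest.approx(-(np.log(0.8) + np.log(0.7)), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binary_cross_entropy(np.array([0.5]), np.array([1.0, 0.0]))


class TestSplitDataset:
    def test_eight_two_split(self):
        data = make_dataset(5, 5)
        train, test = split_dataset(data, ratio=0.8, seed=3)
        assert (train.n, test.n) == (8, 2)

    def test_seed_reproducible(self):
        data = make_dataset(10, 10)
        a1, b1 = split_dataset(data, 0.8, seed=7)
        a2, b2 = split_dataset(data, 0.8, seed=7)
        assert [s.id for s, _ in a1.records] == [s.id for s, _ in a2.records]
        assert [s.id for s, _ in b1.records] == [s.id for s, _ in b2.records]

    def test_partition_is_disjoint_and_exhaustive(self):
        data = make_dataset(7, 9)
        train, test = split_dataset(data, 0.8, seed=1)
        train_ids = {s.id for s, _ in train.records}
        test_ids = {s.id for s, _ in test.records}
        assert not train_ids & test_ids
        assert train_ids | test_ids == {s.id for s, _ in data.records}

    def test_stratification_preserves_balance(self):
        data = make_dataset(50, 50)
        train, test = split_dataset(data, 0.8, seed=2)
        assert int(train.labels.sum()) == 40
        assert int(test.labels.sum()) == 10

    def test_single_class_rejected(self):
        records = tuple((NucleotideSequence(f"s{i}", "ACGUA"), 1) for i in range(6))
        with pytest.raises(ValueError):
            split_dataset(LabeledDataset(records), 0.8, seed=0)


class TestEarlyStopper:
    def test_scripted_sequence_stops_after_epoch_four(self):
        # 0.70, 0.80, 0.79, 0.78 with patience 2: two consecutive decreases
        # below the best (epoch 2) end training; epoch 2 is restored
        for min_delta in (0.0, 0.008):
            stopper = EarlyStopper(patience=2, min_delta=min_delta)
            outcomes = [stopper.update(e, m) for e, m in enumerate([0.70, 0.80, 0.79, 0.78], 1)]
            assert outcomes == [False, False, False, True]
            assert stopper.best_epoch == 2

    def test_plateau_does_not_stop(self):
        stopper = EarlyStopper(patience=2, min_delta=0.0)
        assert not any(stopper.update(e, 0.5) for e in range(1, 10))

    def test_burn_in_defers_stop_but_tracks_best(self):
        stopper = EarlyStopper(patience=2, min_delta=0.0, start_from_epoch=5)
        metrics = [0.70, 0.80, 0.79, 0.78, 0.77, 0.76]
        outcomes = [stopper.update(e, m) for e, m in enumerate(metrics, 1)]
        assert outcomes == [False, False, False, False, False, True]
        assert stopper.best_epoch == 2

    def test_stop_at_best_plus_patience_for_strictly_decreasing_tail(self):
        stopper = EarlyStopper(patience=3, min_delta=0.0)
        metrics = [0.6, 0.9, 0.85, 0.8, 0.7]
        stops = [stopper.update(e, m) for e, m in enumerate(metrics, 1)]
        assert stops.index(True) + 1 == stopper.best_epoch + 3


class TestTraining:
    def _config(self, **kw):
        defaults = dict(
            seed=0, max_epochs=3, early_stop_start_epoch=0, early_stop_min_delta=0.0,
            monitor_fraction=0.2,
        )
        defaults.update(kw)
        return TrainConfig(**defaults)

    def test_capacity_on_separable_toy_set(self):
        # positives carry a G-run visible inside the tiny net's receptive
        # field; negatives contain no G at all, so the classes are exactly
        # separable by a single learned 3-mer detector
        r = np.random.default_rng(4)
        records = []
        for i in range(5):
            s = "".join(r.choice(list("ACU"), size=15))
            pos = int(r.integers(0, 15 - 5 + 1))
            records.append((NucleotideSequence(f"p{i}", s[:pos] + "GGGGG" + s[pos + 5:]), 1))
        for i in range(5):
            records.append(
                (NucleotideSequence(f"n{i}", "".join(r.choice(list("ACU"), size=15))), 0)
            )
        data = LabeledDataset(tuple(records))
        clf = DeepPNClassifier(
            TINY_MODEL,
            self._config(max_epochs=400, early_stop_patience=400, ablation="cnn_only",
                         monitor="test"),
        )
        clf.fit(data, test_data=data)
        assert clf.evaluate(data).accuracy == 1.0

    def test_history_bit_identical_across_runs(self):
        data = make_dataset(15, 15, seed=5)
        histories = []
        for _ in range(2):
            clf = DeepPNClassifier(TINY_MODEL, self._config(seed=9))
            histories.append(clf.fit(data))
        a, b = histories
        assert [(r.epoch, r.train_loss, r.monitor_metric) for r in a.records] == [
            (r.epoch, r.train_loss, r.monitor_metric) for r in b.records
        ]

    def test_train_loss_decreases_on_learnable_data(self):
        data = make_dataset(25, 25, seed=6)
        clf = DeepPNClassifier(TINY_MODEL, self._config(max_epochs=8, early_stop_patience=8))
        history = clf.fit(data)
        losses = history.train_losses
        assert min(losses[-3:]) < losses[0]

    @pytest.mark.parametrize("ablation", ["deeppn", "chebnet_only", "cnn_only"])
    def test_ablations_train_end_to_end_with_expected_dims(self, ablation):
        data = make_dataset(10, 10, seed=7)
        clf = DeepPNClassifier(TINY_MODEL, self._config(max_epochs=2, ablation=ablation))
        clf.fit(data)
        L = TINY_MODEL.window_length
        cheb_dim = L * TINY_MODEL.cheb_channels[1]
        l2 = L - 2 * (TINY_MODEL.kernel_size - 1)
        cnn_dim = l2 * TINY_MODEL.cnn_filters[1]
        expected = {"deeppn": cheb_dim + cnn_dim, "chebnet_only": cheb_dim, "cnn_only": cnn_dim}
        assert clf.network.fused_dim == expected[ablation]
        probs = clf.predict_proba(data.sequences)
        assert probs.shape == (20,) and np.all((probs > 0) & (probs < 1))

    def test_monitor_test_mode_requires_test_data(self):
        data = make_dataset(10, 10)
        clf = DeepPNClassifier(TINY_MODEL, self._config(monitor="test"))
        with pytest.raises(ValueError, match="test_data"):
            clf.fit(data)

    def test_single_class_training_rejected(self):
        records = tuple((NucleotideSequence(f"s{i}", "ACGUACG"), 1) for i in range(8))
        clf = DeepPNClassifier(TINY_MODEL, self._config())
        with pytest.raises(ValueError, match="both classes"):
            clf.fit(LabeledDataset(records))


class TestEvaluation:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0])) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # coarse grid to force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert roc_auc(scores, labels) == pytest.approx(wins / (pos.size * neg.size))

    def test_single_class_auc_absent_in_report(self):
        data = make_dataset(6, 6, seed=8)
        clf = DeepPNClassifier(
            TINY_MODEL,
            TrainConfig(seed=0, max_epochs=1, early_stop_start_epoch=0, monitor_fraction=0.2),
        )
        clf.fit(data)
        pos_only = LabeledDataset(tuple(r for r in data.records if r[1] == 1))
        report = clf.evaluate(pos_only)
        assert report.auc is None
        assert 0 <= report.accuracy <= 1


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path):
        data = make_dataset(8, 8, seed=9)
        clf = DeepPNClassifier(
            TINY_MODEL,
            TrainConfig(seed=1, max_epochs=2, early_stop_start_epoch=0, monitor_fraction=0.2),
        )
        clf.fit(data)
        path = tmp_path / "ckpt.npz"
        clf.save(path)
        loaded = DeepPNClassifier.load(path)
        a = clf.predict_proba(data.sequences)
        b = loaded.predict_proba(data.sequences)
        assert np.array_equal(a, b)


class TestBatchedMatchesFunctional:
    def test_network_forward_equals_composed_operations(self, rng):
        cfg = ModelConfig(
            window_length=10, kernel_size=3, cnn_filters=(3, 4), cheb_channels=(3, 4),
            embed_channels=4, hidden_sizes=(6, 4), dropout_rate=0.0, dtype="float64",
        )
        net = _Network(cfg, "deeppn", rng)
        X = (rng.random((1, 10, 4)) < 0.25).astype(float)
        batched = net.forward(X, training=False)[0][0]

        lt = scaled_laplacian(build_sequence_graph(10, 1), "exact")
        cheb_vec = chebnet_forward(
            X[0], lt, net.preprocess_params(), net.cheb_layer(1), net.cheb_layer(2), cfg.slope
        )
        cnn_vec = cnn_forward(X[0], net.conv_layer(1), net.conv_layer(2), cfg.slope)
        composed = predict_proba(fuse(cheb_vec, cnn_vec), net.head_params(), slope=cfg.slope)
        assert batched == pytest.approx(composed, abs=1e-12)
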