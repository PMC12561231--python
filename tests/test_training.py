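"""Splitting, negative sampling, metrics, optimization and ranking."""

import numpy as np
import pytest

from htinet import (
    EvalReport,
    HTIModel,
    TrainConfig,
    compute_metrics,
    counterfactual_eval,
    desk_representation_config,
    desk_train_config,
    kfold,
    rank_candidates,
    sample_negatives,
    split_edges,
    train_model,
)
from htinet.training import aupr_score, auc_score, _prepare_graph

PAIRS_100 = [(f"H{i}", f"T{i}") for i in range(100)]


class TestSplitEdges:
    def test_ninety_ten(self):
        train, test = split_edges(PAIRS_100, TrainConfig(seed=1))
        assert len(train) == 90 and len(test) == 10
        assert set(train) | set(test) == set(PAIRS_100)
        assert not set(train) & set(test)

    def test_same_seed_same_split(self):
        a = split_edges(PAIRS_100, TrainConfig(seed=5))
        b = split_edges(PAIRS_100, TrainConfig(seed=5))
        assert a == b

    def test_reference_scale_floor_arithmetic(self):
        pairs = [(f"H{i}", f"T{i}") for i in range(7902)]
        train, test = split_edges(pairs, TrainConfig(seed=0))
        assert (len(train), len(test)) == (7112, 790)

    def test_too_few_edges(self):
        with pytest.raises(ValueError):
            split_edges(PAIRS_100[:5], TrainConfig())


class TestKfold:
    def test_partition_properties(self):
        folds = kfold(100, 10, seed=3)
        assert len(folds) == 10
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(100))
        assert all(len(f) == 10 for f in folds)

    @pytest.mark.parametrize("n", range(10, 101, 13))
    def test_fold_sizes_differ_by_at_most_one(self, n):
        sizes = [len(f) for f in kfold(n, 10, seed=0)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == n

    def test_k_exceeding_n(self):
        with pytest.raises(ValueError):
            kfold(5, 10, seed=0)


class TestSampleNegatives:
    HERBS = [f"H{i}" for i in range(10)]
    TARGETS = [f"T{j}" for j in range(9)]

    def test_disjoint_from_positives_and_exact_count(self):
        pos = {("H0", "T0"), ("H1", "T3")}
        negs = sample_negatives(self.HERBS, self.TARGETS, pos, 50, seed=2)
        assert len(negs) == 50
        assert len(set(negs)) == 50
        assert not set(negs) & pos

    def test_exhausted_pool(self):
        pos = {(h, t) for h in self.HERBS for t in self.TARGETS}
        with pytest.raises(ValueError):
            sample_negatives(self.HERBS, self.TARGETS, pos, 1, seed=0)

    def test_seed_determinism(self):
        pos = {("H0", "T0")}
        a = sample_negatives(self.HERBS, self.TARGETS, pos, 20, seed=7)
        b = sample_negatives(self.HERBS, self.TARGETS, pos, 20, seed=7)
        assert a == b


class TestMetrics:
    def test_hand_confusion_table(self):
        """TP=3, FP=1, FN=1, TN=5 -> P=R=F1=0.75, ACC=0.8."""
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.15, 0.1, 0.05])
        labels = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        rep = compute_metrics(scores, labels, threshold=0.5)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(0.75)
        assert rep.acc == pytest.approx(0.8)

    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        rep = compute_metrics(scores, labels)
        assert rep.auc == 1.0 and rep.aupr == 1.0 and rep.f1 == 1.0

    def test_all_positive_predictions_on_balanced_set(self):
        scores = np.full(10, 0.9)
        labels = np.array([1, 0] * 5)
        rep = compute_metrics(scores, labels)
        assert rep.recall == 1.0 and rep.acc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0.5, 0.6]), np.array([1, 1]))

    def test_auc_aupr_match_sklearn_reference(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = rng.random(n)
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            assert auc_score(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-6
            )
            assert aupr_score(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-6
            )

    def test_report_fields_in_unit_interval(self):
        rng = np.random.default_rng(1)
        rep = compute_metrics(rng.random(30), (rng.random(30) < 0.5).astype(int))
        for v in rep.as_dict().values():
            assert 0.0 <= v <= 1.0


class TestRankCandidates:
    def test_top_k_rows_and_ranks(self):
        S = np.array([[0.9, 0.1, 0.5], [0.2, 0.8, 0.4]])
        table = rank_candidates(S, ["H1", "H2"], ["T1", "T2", "T3"], k=3)
        assert len(table) == 6
        h1 = table[table.herb == "H1"]
        assert list(h1.target) == ["T1", "T3", "T2"]
        assert list(h1["rank"]) == [1, 2, 3]

    def test_eight_herbs_top3_gives_24_rows(self):
        rng = np.random.default_rng(0)
        S = rng.random((8, 10))
        table = rank_candidates(S, [f"H{i}" for i in range(8)], [f"T{j}" for j in range(10)], 3)
        assert len(table) == 24

    def test_equal_scores_tie_break_by_target_id(self):
        S = np.full((1, 4), 0.5)
        table = rank_candidates(S, ["H1"], ["T4", "T1", "T3", "T2"], k=4)
        assert list(table.target) == ["T1", "T2", "T3", "T4"]

    def test_agrees_with_full_sort_oracle(self):
        rng = np.random.default_rng(5)
        S = rng.random((4, 7))
        ids = [f"T{j}" for j in range(7)]
        table = rank_candidates(S, [f"H{i}" for i in range(4)], ids, k=7)
        for i in range(4):
            expected = [ids[j] for j in np.argsort(-S[i], kind="stable")]
            got = list(table[table.herb == f"H{i}"].target)
            assert got == expected


def _tiny_model(small_synth, seed=0):
    g = _prepare_graph(small_synth.graph)
    rc = desk_representation_config(node_dim=16, out_dim=8, heads=2, layers=2, k_dense=1)
    return HTIModel(g, rc, hidden_size=8, seed=seed)


class TestTrainModel:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, small_synth):
        model = _tiny_model(small_synth)
        before = [p.data.copy() for p in model.parameters()]
        pos = [p for p in small_synth.positives if p not in small_synth.held_out][:20]
        negs = sample_negatives(
            model.herb_ids, model.target_ids, set(small_synth.positives), 20, 1
        )
        cfg = desk_train_config(
            seed=0, learning_rate=0.0, weight_decay=0.0, head_weight_decay=None,
            epochs=3, patience=3, lr_decay_factor=1.0,
        )
        train_model(model, pos + negs[:10], np.r_[np.ones(20), np.zeros(10)],
                    pos[:5] + negs[10:15], np.r_[np.ones(5), np.zeros(5)], cfg)
        after = [p.data for p in model.parameters()]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)

    def test_fixed_seed_identical_loss_trajectories(self, small_synth):
        histories = []
        for _ in range(2):
            model = _tiny_model(small_synth, seed=3)
            pos = [p for p in small_synth.positives if p not in small_synth.held_out][:20]
            negs = sample_negatives(
                model.herb_ids, model.target_ids, set(small_synth.positives), 30, 5
            )
            cfg = desk_train_config(seed=3, epochs=5, patience=5)
            h = train_model(
                model, pos + negs[:20], np.r_[np.ones(20), np.zeros(20)],
                pos[:5] + negs[20:25], np.r_[np.ones(5), np.zeros(5)], cfg,
            )
            histories.append(h)
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["val_loss"] == histories[1]["val_loss"]

    def test_best_validation_criterion_non_increasing(self, small_synth):
        model = _tiny_model(small_synth, seed=1)
        pos = [p for p in small_synth.positives if p not in small_synth.held_out][:20]
        negs = sample_negatives(
            model.herb_ids, model.target_ids, set(small_synth.positives), 30, 2
        )
        cfg = desk_train_config(seed=1, epochs=8, patience=8, early_stop_metric="loss")
        h = train_model(
            model, pos + negs[:20], np.r_[np.ones(20), np.zeros(20)],
            pos[:5] + negs[20:25], np.r_[np.ones(5), np.zeros(5)], cfg,
        )
        running = np.minimum.accumulate(h["val_loss"])
        assert (np.diff(running) <= 1e-12).all()
        assert h["best_epoch"] >= 0


class TestCounterfactual:
    def test_zero_hidden_fraction_empty_report(self, small_synth):
        out = counterfactual_eval(
            small_synth.graph, small_synth.positives, 0.0, desk_train_config(seed=0)
        )
        assert out == {"correct": 0, "incorrect": 0, "hidden": []}

    def test_counts_partition_hidden_set(self, small_synth):
        cfg = desk_train_config(seed=2, epochs=8, patience=8)
        rc = desk_representation_config(node_dim=16, out_dim=8, heads=2, layers=2, k_dense=1)
        out = counterfactual_eval(
            small_synth.graph, small_synth.positives, 0.1, cfg, rep_config=rc
        )
        assert out["correct"] + out["incorrect"] == len(out["hidden"])
        assert len(out["hidden"]) == round(0.1 * len(small_synth.positives))


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(test_fraction=1.5)
    with pytest.raises(ValueError):
        TrainConfig(patience=300, epochs=200)
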