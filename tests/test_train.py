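"""Split protocol, metric suite (vs brute-force and sklearn oracles), and the
training loop."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import precision_recall_fscore_support

from sersnet import (
    ARCHITECTURES,
    CLASSES,
    ConfusionMatrix,
    GeneratorConfig,
    NetworkConfig,
    TrainingConfig,
    build_network,
    dataset_to_arrays,
    evaluate,
    f1_score,
    generate_dataset,
    generate_spectrum,
    metrics,
    per_class_counts,
    split_dataset,
    train,
)
from sersnet.simulate import flatten_spectra
from sersnet.train import DatasetSplit, evaluation_summary


def balanced_labels(n_per_class):
    return [c for c in CLASSES for _ in range(n_per_class)]


class TestSplitDataset:
    def test_400_spectra_split_120_210_70(self):
        split = split_dataset(balanced_labels(100), seed=0)
        assert len(split.prediction) == 120
        assert len(split.training) == 210
        assert len(split.validation) == 70

    def test_stratified_within_class(self):
        labels = balanced_labels(100)
        split = split_dataset(labels, seed=4)
        arr = np.asarray(labels, dtype=object)
        for c in CLASSES:
            n_pred = (arr[split.prediction] == c).sum()
            n_val = (arr[split.validation] == c).sum()
            n_train = (arr[split.training] == c).sum()
            assert n_pred == 30
            assert n_val in (17, 18)
            assert n_train + n_val == 70

    def test_deterministic_given_seed(self):
        labels = balanced_labels(25)
        a, b = split_dataset(labels, seed=9), split_dataset(labels, seed=9)
        np.testing.assert_array_equal(a.prediction, b.prediction)
        np.testing.assert_array_equal(a.training, b.training)
        np.testing.assert_array_equal(a.validation, b.validation)

    def test_partition_covers_everything_over_many_seeds(self):
        # set-arithmetic check, including an unbalanced class design
        labels = balanced_labels(25) + ["BaP+Pyr"] * 13
        n = len(labels)
        for seed in range(100):
            s = split_dataset(labels, seed=seed)
            union = (set(s.training.tolist()) | set(s.validation.tolist())
                     | set(s.prediction.tolist()))
            assert union == set(range(n))
            assert len(s.training) + len(s.validation) + len(s.prediction) == n

    def test_class_too_small_rejected(self):
        labels = balanced_labels(3) + ["BaP+Pyr"] * 6
        with pytest.raises(ValueError, match="too few"):
            split_dataset(labels, seed=0)

    def test_group_split_keeps_replicates_together(self):
        labels = balanced_labels(30)
        groups = [f"{c}_{i // 5}" for c, i in
                  zip(labels, list(range(30)) * 4)]
        split = split_dataset(labels, seed=3, group_ids=groups)
        assignment = {}
        for name, idx in (("t", split.training), ("v", split.validation),
                          ("p", split.prediction)):
            for i in idx:
                assert groups[i] not in assignment or assignment[groups[i]] == name
                assignment[groups[i]] = name

    def test_overlapping_subsets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DatasetSplit(np.array([0, 1]), np.array([1, 2]), np.array([3]))


class TestPerClassCounts:
    def test_diagonal_matrix_has_no_errors(self):
        cm = ConfusionMatrix(np.diag([5, 6, 7, 8]), list(CLASSES))
        for k in range(4):
            tp, tn, fp, fn = per_class_counts(cm, k)
            assert fp == 0 and fn == 0
            assert tp == cm.counts[k, k]

    @given(st.integers(0, 2**32 - 1))
    def test_counts_partition_the_total(self, seed):
        cm = ConfusionMatrix(
            np.random.default_rng(seed).integers(0, 20, (4, 4)), list(CLASSES)
        )
        for k in range(4):
            assert sum(per_class_counts(cm, k)) == cm.total

    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_enumeration(self, seed):
        counts = np.random.default_rng(seed).integers(0, 15, (4, 4))
        cm = ConfusionMatrix(counts, list(CLASSES))
        for k in range(4):
            tp = fp = fn = tn = 0
            for i in range(4):
                for j in range(4):
                    c = int(counts[i, j])
                    if i == k and j == k:
                        tp += c
                    elif j == k:
                        fp += c
                    elif i == k:
                        fn += c
                    else:
                        tn += c
            assert per_class_counts(cm, k) == (tp, tn, fp, fn)


class TestMetrics:
    @pytest.mark.parametrize(
        "precision,recall,expected_f1",
        [
            (96.97, 84.21, 90.14),
            (93.75, 96.77, 95.24),
            (86.21, 100.0, 92.59),
            (100.0, 100.0, 100.0),
            (100.0, 93.94, 96.88),
            (96.88, 100.0, 98.42),
            (100.0, 86.84, 92.96),
            (100.0, 91.67, 95.65),
            (89.66, 100.0, 94.55),
        ],
    )
    def test_harmonic_f1_reproduces_published_values(self, precision, recall, expected_f1):
        assert round(f1_score(precision, recall), 2) == expected_f1

    def test_accuracy_is_trace_over_total(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 25, (4, 4))
            if counts.sum() == 0:
                continue
            rep = metrics(ConfusionMatrix(counts, list(CLASSES)))
            assert rep.accuracy == pytest.approx(
                100.0 * np.trace(counts) / counts.sum()
            )

    @given(st.integers(0, 2**32 - 1))
    def test_f1_between_min_and_max_of_precision_recall(self, seed):
        counts = np.random.default_rng(seed).integers(0, 12, (4, 4))
        if counts.sum() == 0:
            counts[0, 0] = 1
        rep = metrics(ConfusionMatrix(counts, list(CLASSES)))
        for m in rep.per_class.values():
            if m.f1 is None:
                continue
            assert min(m.precision, m.recall) - 1e-9 <= m.f1
            assert m.f1 <= max(m.precision, m.recall) + 1e-9

    @given(st.integers(0, 2**32 - 1))
    def test_agrees_with_sklearn(self, seed):
        gen = np.random.default_rng(seed)
        y_true = gen.integers(0, 4, 60)
        y_pred = gen.integers(0, 4, 60)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, list(CLASSES))
        rep = metrics(cm)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(4), zero_division=np.nan
        )
        for k, name in enumerate(CLASSES):
            m = rep.per_class[name]
            for ours, ref in ((m.precision, p[k]), (m.recall, r[k])):
                if np.isnan(ref):
                    assert ours is None
                else:
                    assert ours == pytest.approx(100 * ref)
            if m.precision is not None and m.recall is not None and not np.isnan(f[k]):
                assert m.f1 == pytest.approx(100 * f[k])

    def test_undefined_metric_flagged_not_zeroed(self):
        # nothing predicted as class 3 and no true members either
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = counts[1, 1] = counts[2, 2] = 5
        rep = metrics(ConfusionMatrix(counts, list(CLASSES)))
        last = rep.per_class[CLASSES[3]]
        assert last.precision is None and last.recall is None and last.f1 is None

    def test_degenerate_always_one_class_predictor(self):
        y_true = np.repeat(np.arange(4), 10)
        y_pred = np.zeros(40, dtype=int)
        rep = metrics(ConfusionMatrix.from_predictions(y_true, y_pred, list(CLASSES)))
        assert rep.accuracy == pytest.approx(25.0)
        assert rep.per_class[CLASSES[0]].recall == pytest.approx(100.0)
        for name in CLASSES[1:]:
            assert rep.per_class[name].recall == pytest.approx(0.0)


def toy_dataset(n_per_class=2, grid_points=188):
    """Noise-free, one spectrum per (class, replicate): trivially separable."""
    from sersnet import WavenumberGrid
    from sersnet.simulate import CLASS_CONSTITUENTS, ANALYTES

    grid = WavenumberGrid(300, 1800, grid_points)
    cfg = GeneratorConfig(
        noise_sd=0.0, replicate_log_sd=0.0, baseline_amplitude=0.0,
        baseline_tilt=0.0, grid=grid,
    )
    spectra = []
    for label in CLASSES:
        conc = {a: 10.0 if a in CLASS_CONSTITUENTS[label] else 0.0 for a in ANALYTES}
        for i in range(n_per_class):
            s = generate_spectrum(conc, cfg, 0)
            s.label = label
            s.sample_id = f"{label}_{i}"
            spectra.append(s)
    return spectra, grid


class TestTraining:
    def test_memorizes_separable_toy_dataset(self):
        spectra, grid = toy_dataset(n_per_class=2)
        X, y, classes, _ = dataset_to_arrays(spectra, grid=grid)
        idx = np.arange(len(y))
        # train on one copy of each class, hold the duplicates out
        split = DatasetSplit(training=idx[::2], validation=idx[1::2][:2],
                             prediction=idx[1::2][2:], seed=0)
        net = build_network(
            NetworkConfig(architecture="squeezenet1d", input_length=grid.n_points,
                          seed=1))
        res = train(net, X, y, split, TrainingConfig(max_epochs=150, patience=150,
                                                     seed=1))
        # converged training accuracy (the best-validation snapshot may be an
        # earlier epoch; convergence is what this toy checks)
        assert res.history["acc_train"].iloc[-1] == 100.0

    def test_shape_mismatch_rejected_before_training(self, rng):
        net = build_network(NetworkConfig(architecture="squeezenet1d", input_length=100))
        X = rng.random((8, 64))
        y = np.zeros(8, dtype=int)
        split = DatasetSplit(np.arange(4), np.arange(4, 6), np.arange(6, 8))
        with pytest.raises(ValueError, match="expects"):
            train(net, X, y, split)

    def test_training_deterministic_given_seed(self):
        spectra, grid = toy_dataset(n_per_class=3)
        X, y, _, _ = dataset_to_arrays(spectra, grid=grid)
        idx = np.arange(len(y))
        split = DatasetSplit(idx[::3], idx[1::3], idx[2::3], seed=0)

        def run():
            net = build_network(
                NetworkConfig(architecture="shufflenet1d", input_length=grid.n_points,
                              seed=5))
            return train(net, X, y, split,
                         TrainingConfig(max_epochs=5, patience=5, seed=5))

        a, b = run(), run()
        for wa, wb in zip(a.network.get_weights(), b.network.get_weights()):
            np.testing.assert_array_equal(wa, wb)
        assert a.history.equals(b.history)


class TestEvaluate:
    def _fitted(self):
        spectra, grid = toy_dataset(n_per_class=3)
        X, y, classes, _ = dataset_to_arrays(spectra, grid=grid)
        idx = np.arange(len(y))
        split = DatasetSplit(idx[::3], idx[1::3], idx[2::3], seed=0)
        net = build_network(
            NetworkConfig(architecture="squeezenet1d", input_length=grid.n_points,
                          seed=2))
        res = train(net, X, y, split, TrainingConfig(max_epochs=120, patience=120,
                                                     seed=2))
        return res.network, X, y, split, classes

    def test_perfect_predictor_reports_100_and_diagonal_cm(self):
        net, X, y, split, classes = self._fitted()
        reports = evaluate(net, X, y, split, classes)
        for rep in reports.values():
            assert rep.accuracy == pytest.approx(100.0)
            assert np.all(rep.confusion.counts == np.diag(np.diag(rep.confusion.counts)))

    def test_report_accuracy_matches_recount_oracle(self):
        net, X, y, split, classes = self._fitted()
        reports = evaluate(net, X, y, split, classes)
        for name, idx in (("training", split.training),
                          ("validation", split.validation),
                          ("prediction", split.prediction)):
            recount = 100.0 * sum(
                int(net.predict(X[i][None, :])[0]) == y[i] for i in idx
            ) / len(idx)
            assert reports[name].accuracy == pytest.approx(recount)

    def test_confusion_matrix_row_sums_equal_support(self):
        net, X, y, split, classes = self._fitted()
        rep = evaluate(net, X, y, split, classes)["prediction"]
        supports = [(y[split.prediction] == k).sum() for k in range(len(classes))]
        np.testing.assert_array_equal(rep.confusion.counts.sum(axis=1), supports)
        assert rep.confusion.total == len(split.prediction)

    def test_empty_subset_rejected(self):
        net, X, y, split, classes = self._fitted()
        bad = DatasetSplit(split.training, split.validation,
                           np.array([], dtype=int), seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(net, X, y, bad, classes)

    def test_summary_mirrors_reports(self):
        net, X, y, split, classes = self._fitted()
        reports = evaluate(net, X, y, split, classes)
        summary = evaluation_summary(reports, architecture="squeezenet1d", seed=0)
        assert summary["acc_t"] == round(reports["training"].accuracy, 2)
        assert summary["acc_p"] == round(reports["prediction"].accuracy, 2)
        assert len(summary["per_class"]) == len(classes)


class TestEndToEndReducedScale:
    """All three architectures learn a reduced-scale synthetic dataset."""

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_architecture_classifies_synthetic_mixtures(self, arch, coarse_grid,
                                                        small_dataset_config):
        samples, _ = generate_dataset(small_dataset_config)
        spectra = flatten_spectra(samples)
        X, y, classes, _ = dataset_to_arrays(spectra, grid=coarse_grid)
        split = split_dataset([s.label for s in spectra], seed=1)
        net = build_network(
            NetworkConfig(architecture=arch, input_length=coarse_grid.n_points,
                          seed=1))
        res = train(net, X, y, split,
                    TrainingConfig(max_epochs=60, patience=60, seed=1))
        rep = evaluate(res.network, X, y, split, classes)
        assert rep["prediction"].accuracy > 90.0
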