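"""Confusion matrices, PCA sanity and the class-ladder loop."""

import numpy as np
import pytest

from writhenet.evaluation import (ConfusionMatrix, accuracy_vs_classes,
                                  evaluate, pca_projection)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(np.arange(3), 10)
        cm = ConfusionMatrix.from_predictions(y, y, ["a", "b", "c"])
        assert cm.accuracy == 1.0
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_counts_conserved_and_rows_match_class_sizes(self):
        rng = np.random.default_rng(0)
        y_true = np.repeat(np.arange(5), 40)
        y_pred = rng.integers(0, 5, 200)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, list("abcde"))
        assert cm.n_samples == 200
        assert np.all(cm.counts.sum(axis=1) == 40)

    def test_uniform_random_predictions_near_chance(self):
        rng = np.random.default_rng(1)
        y_true = np.repeat(np.arange(5), 400)
        y_pred = rng.integers(0, 5, 2000)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, list("abcde"))
        assert cm.accuracy == pytest.approx(0.2, abs=0.05)

    def test_most_confused_pair(self):
        counts = np.array([[10, 5], [1, 10]])
        cm = ConfusionMatrix(counts, ["x", "y"])
        assert cm.most_confused_pair() == ("x", "y", 5)

    def test_accuracy_recomputable_from_counts(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, 300)
        y_pred = rng.integers(0, 3, 300)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, list("abc"))
        assert cm.accuracy == pytest.approx(
            np.trace(cm.counts) / cm.counts.sum())


class TestPCA:
    def test_scores_centred_and_variance_ordered(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(200, 30)) * np.linspace(5, 0.1, 30)
        scores = pca_projection(data, 2)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-8)
        assert scores[:, 0].var() >= scores[:, 1].var()

    def test_unknot_and_figure_eight_cluster_together(self, five_knot_ensembles):
        # 0_1 and 4_1 share zero mean writhe, hence overlap in StA space
        from writhenet.features import featurize
        scores = {}
        for name in ("0_1", "3_1", "4_1"):
            t = featurize(five_knot_ensembles[name][:120], "sta_signed")
            scores[name] = t.values
        stacked = np.vstack([scores[n] for n in ("0_1", "3_1", "4_1")])
        proj = pca_projection(stacked, 2)
        n = 120
        cents = {name: proj[i * n:(i + 1) * n].mean(axis=0)
                 for i, name in enumerate(("0_1", "3_1", "4_1"))}
        d_unknot_fig8 = np.linalg.norm(cents["0_1"] - cents["4_1"])
        d_unknot_trefoil = np.linalg.norm(cents["0_1"] - cents["3_1"])
        assert d_unknot_fig8 < d_unknot_trefoil


class TestAccuracyVsClasses:
    def test_ladder_on_separable_synthetic_data(self):
        rng = np.random.default_rng(3)

        def dataset_fn(names, kind):
            from writhenet.models import ClassifierSpec, TrainConfig
            c = len(names)
            n = 120
            X, y = [], []
            for ci in range(c):
                centre = np.zeros(12)
                centre[ci] = 4.0
                X.append(rng.normal(size=(n, 12)) + centre)
                y.append(np.full(n, ci))
            X = np.vstack(X)
            y = np.concatenate(y)
            idx = rng.permutation(len(X))
            cut = int(0.8 * len(X))
            spec = ClassifierSpec(12, c)
            cfg = TrainConfig(seed=0, max_epochs=40)
            return (X[idx[:cut]], y[idx[:cut]], X[idx[cut:]], y[idx[cut:]],
                    spec, cfg)

        out = accuracy_vs_classes(dataset_fn, ["a", "b", "c"], ["only"])
        assert out["n_classes"] == [2, 3]
        assert all(acc >= 0.95 for acc in out["accuracy"]["only"])
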