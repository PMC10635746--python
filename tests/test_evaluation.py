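"""Fold splitting, confusion/metric arithmetic, ROC properties, and the
cross-validated experiment driver."""

import numpy as np
import pytest

import mldstnet as m
from mldstnet.errors import ContractError, ParameterError


class TestKFoldSplit:
    def test_115_samples_give_equal_test_folds(self):
        labels = ["benign"] * 64 + ["malignant"] * 51
        split = m.kfold_split(115, 5, seed=0, labels=labels)
        sizes = sorted(len(test) for _, test in split.folds)
        assert sizes == [23] * 5

    def test_partition_property(self):
        labels = (["benign"] * 20 + ["malignant"] * 17 + ["ignorant"] * 13)
        split = m.kfold_split(50, 5, seed=1, labels=labels)
        all_test = np.concatenate([np.array(t) for _, t in split.folds])
        assert sorted(all_test) == list(range(50))
        for train, test in split.folds:
            assert set(train).isdisjoint(test)
            assert sorted({*train, *test}) == list(range(50))

    def test_stratification_within_one_sample(self):
        labels = ["benign"] * 25 + ["malignant"] * 15 + ["ignorant"] * 10
        split = m.kfold_split(50, 5, seed=2, labels=labels)
        arr = np.array(labels)
        for _, test in split.folds:
            counts = {c: np.sum(arr[list(test)] == c) for c in m.CLASSES}
            assert counts["benign"] == 5 and counts["malignant"] == 3
            assert counts["ignorant"] == 2

    def test_deterministic(self):
        labels = ["benign", "malignant"] * 10
        assert m.kfold_split(20, 4, 7, labels) == m.kfold_split(20, 4, 7, labels)

    def test_n_below_k_rejected(self):
        with pytest.raises(ParameterError):
            m.kfold_split(3, 5, 0, ["benign", "malignant", "ignorant"])


class TestConfusion:
    def test_perfect_predictions(self):
        labs = ["benign", "malignant", "ignorant"] * 3
        cm = m.confusion(labs, labs, positive_class="benign")
        assert cm.fn == 0 and cm.fp == 0
        assert np.trace(cm.grid) == 9

    def test_flipped_predictions(self):
        true = ["benign"] * 4 + ["malignant"] * 4
        pred = ["malignant"] * 4 + ["benign"] * 4
        for pos in ("benign", "malignant"):
            cm = m.confusion(true, pred, positive_class=pos)
            assert cm.tp == 0 and cm.tn == 0

    def test_hand_tallied_fixture(self):
        true = ["benign"] * 5 + ["malignant"] * 3 + ["ignorant"] * 2
        pred = ["benign", "benign", "malignant", "benign", "ignorant",
                "malignant", "malignant", "benign", "ignorant", "benign"]
        cm = m.confusion(true, pred, positive_class="benign")
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (3, 2, 2, 3)
        assert cm.grid.tolist() == [[3, 1, 1], [1, 2, 0], [1, 0, 1]]

    def test_unknown_label_rejected(self):
        with pytest.raises(ContractError):
            m.confusion(["benign"], ["suspicious"])


class TestMetrics:
    def test_benign_cohort_arithmetic(self):
        """TP=63, FN=1, FP=0, TN=51: sensitivity 63/64, specificity 51/51,
        accuracy 114/115."""
        cm = m.ConfusionMatrix(
            grid=np.zeros((3, 3), dtype=int), positive_class="benign",
            tp=63, fn=1, fp=0, tn=51,
        )
        got = m.metrics(cm)
        assert got["sensitivity"] == pytest.approx(0.9844, abs=5e-5)
        assert got["specificity"] == pytest.approx(1.0)
        assert got["accuracy"] == pytest.approx(0.9913, abs=5e-5)

    def test_all_correct_gives_ones(self):
        cm = m.confusion(["benign", "malignant"] * 3, ["benign", "malignant"] * 3,
                         positive_class="malignant")
        assert all(v == 1.0 for v in m.metrics(cm).values())

    def test_balanced_errors_give_half_sensitivity(self):
        cm = m.ConfusionMatrix(grid=np.zeros((3, 3), dtype=int),
                               positive_class="benign", tp=5, fn=5, fp=0, tn=2)
        assert m.metrics(cm)["sensitivity"] == pytest.approx(0.5)

    def test_zero_denominator_reported_undefined(self):
        cm = m.ConfusionMatrix(grid=np.zeros((3, 3), dtype=int),
                               positive_class="benign", tp=0, fn=0, fp=1, tn=3)
        got = m.metrics(cm)
        assert got["sensitivity"] is None
        assert got["specificity"] == pytest.approx(0.75)


class TestROC:
    def test_perfect_separation_passes_top_left(self):
        true = ["benign"] * 5 + ["malignant"] * 5
        scores = [0.9, 0.8, 0.85, 0.95, 0.7, 0.1, 0.2, 0.15, 0.3, 0.05]
        pts = m.roc_curve(true, scores, "benign")
        assert (0.0, 1.0) in pts
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        true = ["benign" if b else "malignant" for b in rng.random(50) < 0.5]
        pts = m.roc_curve(true, rng.random(50), "benign")
        fprs = [p[0] for p in pts]
        tprs = [p[1] for p in pts]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(123)
        n = 4000
        true = ["benign" if b else "malignant" for b in rng.random(n) < 0.5]
        pts = m.roc_curve(true, rng.random(n), "benign")
        auc = np.trapezoid([p[1] for p in pts], [p[0] for p in pts])
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        true = ["benign" if b else "malignant" for b in rng.random(40) < 0.4]
        s = rng.random(40)
        assert m.roc_curve(true, s, "benign") == m.roc_curve(true, np.exp(3 * s), "benign")

    def test_sign_reversal_mirrors_curve(self):
        """Negating the scores reverses the ranking: the ROC point set maps
        onto the original under (f, t) -> (1-f, 1-t)."""
        rng = np.random.default_rng(6)
        true = ["benign" if b else "malignant" for b in rng.random(30) < 0.5]
        s = rng.normal(size=30)
        orig = set(m.roc_curve(true, s, "benign"))
        mirrored = {
            (round(1 - f, 12), round(1 - t, 12)) for f, t in m.roc_curve(true, -s, "benign")
        }
        assert {(round(f, 12), round(t, 12)) for f, t in orig} == mirrored

    def test_single_class_truth_rejected(self):
        with pytest.raises(ContractError):
            m.roc_curve(["benign"] * 5, [0.1] * 5, "benign")


@pytest.fixture(scope="module")
def small_cv(tiny_cnn_config):
    ds = m.generate_phantom_dataset(5, m.PhantomSpec(image_size=64), seed=21)
    kwargs = dict(
        mlp_config=m.MLPConfig(epochs=100),
        cnn_config=tiny_cnn_config,
        k=3,
        seed=9,
    )
    return ds, kwargs


class TestRunCVExperiment:
    def test_report_bit_reproducible(self, small_cv):
        ds, kwargs = small_cv
        a = m.run_cv_experiment(ds.images, ds.labels, **kwargs)
        b = m.run_cv_experiment(ds.images, ds.labels, **kwargs)
        assert a.to_json() == b.to_json()

    def test_pooled_counts_cover_dataset(self, small_cv):
        ds, kwargs = small_cv
        rep = m.run_cv_experiment(ds.images, ds.labels, **kwargs)
        for meth in ("mlp", "cnn", "fused"):
            assert int(np.sum(rep.methods[meth]["confusion"])) == len(ds)
        assert rep.counts["images"] == len(ds)
        assert rep.counts["fused_rows"] == len(ds)

    def test_roc_plot_written(self, small_cv, tmp_path):
        ds, kwargs = small_cv
        rep = m.run_cv_experiment(ds.images, ds.labels, **kwargs)
        from mldstnet.evaluation import plot_roc

        out = tmp_path / "roc.png"
        plot_roc(rep, out)
        assert out.exists() and out.stat().st_size > 0

    def test_too_few_samples_per_class_rejected(self):
        ds = m.generate_phantom_dataset(2, m.PhantomSpec(image_size=32), seed=0)
        with pytest.raises(ParameterError):
            m.run_cv_experiment(ds.images, ds.labels, k=5)
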