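"""Cross-validated evaluation of the single sources and the fused system.

Stratified k-fold (default 5) with pooled confusion matrices: every sample
is predicted exactly once, by models trained on the other folds, and one
confusion matrix per method is tallied over the pooled predictions.
Sensitivity/specificity are reported one-vs-rest for the benign and
malignant classes over the benign+malignant subpopulation (normal/ignorant
phantoms are excluded from those two ratios, mirroring a benign-vs-malignant
diagnostic readout); overall accuracy is the 3-class rate.

ROC curves use the class probability (for a single source) or the combined
mass of the positive class (for the fused method) as the score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import sklearn.metrics
from sklearn.model_selection import StratifiedKFold

from .classifiers import MLPConfig, MLPSource
from .cnn import CNNConfig, CNNSource
from .errors import ContractError, ParameterError
from .fusion import Frame, DISJOINT_SINGLETON, fuse_sources
from .glcm import GLCMSpec, features_for_dataset
from .image import GrayImage
from .phantom import CLASSES

__all__ = [
    "FoldSplit",
    "ConfusionMatrix",
    "EvalReport",
    "kfold_split",
    "confusion",
    "metrics",
    "roc_curve",
    "plot_roc",
    "run_cv_experiment",
]


@dataclass(frozen=True)
class FoldSplit:
    """Deterministic stratified k-fold partition of ``n`` sample indices."""

    k: int
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]  # (train, test) per fold
    seed: int
    stratified: bool = True

    def test_indices(self) -> list[np.ndarray]:
        return [np.asarray(test) for _, test in self.folds]


def kfold_split(n: int, k: int, seed: int, labels: Sequence[str]) -> FoldSplit:
    """Stratified k-fold split; each index lands in exactly one test fold."""
    if n < k:
        raise ParameterError(f"need at least k={k} samples, got {n}")
    if len(labels) != n:
        raise ParameterError(f"{len(labels)} labels for n={n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(
        (tuple(int(i) for i in tr), tuple(int(i) for i in te))
        for tr, te in skf.split(np.zeros(n), np.asarray(labels))
    )
    return FoldSplit(k=k, folds=folds, seed=seed)


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 count grid plus binary counts for a designated positive class."""

    grid: np.ndarray                # rows: true class, cols: predicted, CLASSES order
    positive_class: str | None = None
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return int(self.grid.sum()) if self.positive_class is None else (
            self.tp + self.fn + self.fp + self.tn
        )


def confusion(
    true_labels: Sequence[str],
    decided_labels: Sequence[str],
    positive_class: str | None = None,
) -> ConfusionMatrix:
    """Tally a pooled confusion matrix over aligned label sequences.

    With ``positive_class`` set, the binary TP/FN/FP/TN counts treat that
    class as positive and everything else as negative, over all samples
    passed in.
    """
    true_labels = list(true_labels)
    decided_labels = list(decided_labels)
    if len(true_labels) != len(decided_labels):
        raise ContractError(
            f"{len(true_labels)} true vs {len(decided_labels)} decided labels"
        )
    for lab in (*true_labels, *decided_labels):
        if lab not in CLASSES:
            raise ContractError(f"unknown label {lab!r}")
    grid = np.zeros((3, 3), dtype=np.int64)
    for t, d in zip(true_labels, decided_labels):
        grid[CLASSES.index(t), CLASSES.index(d)] += 1
    tp = fn = fp = tn = 0
    if positive_class is not None:
        if positive_class not in CLASSES:
            raise ContractError(f"unknown positive class {positive_class!r}")
        for t, d in zip(true_labels, decided_labels):
            if t == positive_class:
                tp += d == positive_class
                fn += d != positive_class
            else:
                fp += d == positive_class
                tn += d != positive_class
    return ConfusionMatrix(
        grid=grid, positive_class=positive_class, tp=int(tp), fn=int(fn),
        fp=int(fp), tn=int(tn),
    )


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity from binary counts.

    A ratio with a zero denominator is reported as ``None`` (undefined),
    never as 0.
    """
    if cm.positive_class is None:
        raise ContractError("metrics need a confusion matrix with a positive class")
    total = cm.tp + cm.fn + cm.fp + cm.tn
    if total == 0:
        raise ContractError("empty confusion matrix")
    out: dict[str, float | None] = {
        "accuracy": (cm.tp + cm.tn) / total,
        "sensitivity": cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None,
        "specificity": cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else None,
    }
    return out


def roc_curve(
    true_labels: Sequence[str], scores: Sequence[float], positive_class: str
) -> list[tuple[float, float]]:
    """ROC points (FPR, TPR), threshold swept over the scores.

    Sorted by FPR; includes (0,0) and (1,1).
    """
    y = np.array([lab == positive_class for lab in true_labels])
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ContractError("scores must be finite")
    if y.all() or not y.any():
        raise ContractError("ROC undefined: all samples share one class")
    fpr, tpr, _ = sklearn.metrics.roc_curve(y, s, drop_intermediate=False)
    pts = sorted({(float(f), float(t)) for f, t in zip(fpr, tpr)})
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


@dataclass
class EvalReport:
    """Cross-validated results for MLP, CNN and the fused method."""

    methods: dict            # method -> {"accuracy_overall", "confusion", "per_class"}
    roc: dict                # method -> {class -> [(fpr, tpr), ...]}
    counts: dict             # record-count audit of the pipeline stages
    seed: int = 0
    k: int = 5

    def to_json(self, indent: int | None = 2) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return _clean(obj.tolist())
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        return json.dumps(
            _clean(
                {
                    "k": self.k,
                    "seed": self.seed,
                    "methods": self.methods,
                    "roc": self.roc,
                    "counts": self.counts,
                }
            ),
            indent=indent,
            sort_keys=True,
        )


def plot_roc(report: "EvalReport", out_path) -> None:
    """One PNG: ROC curves of MLP, CNN and the fused method per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, cls in zip(axes, ("benign", "malignant")):
        for meth, pts in report.roc.items():
            if pts.get(cls):
                f, t = zip(*pts[cls])
                ax.plot(f, t, label=meth)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_title(f"ROC — {cls} positive")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def _method_summary(true_labels, pred_labels, scores_bm) -> tuple[dict, dict]:
    """Pooled summary for one method.

    ``scores_bm`` — (n, 3) array of class scores used for ROC.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    overall = float(np.mean(true_labels == pred_labels))
    cm3 = confusion(true_labels, pred_labels)
    # benign/malignant readout: ignorant/normal excluded
    bm = np.isin(true_labels, ("benign", "malignant"))
    per_class = {}
    roc_pts = {}
    for cls in ("benign", "malignant"):
        cm = confusion(true_labels[bm], pred_labels[bm], positive_class=cls)
        per_class[cls] = metrics(cm)
        idx = CLASSES.index(cls)
        try:
            roc_pts[cls] = roc_curve(true_labels[bm], scores_bm[bm, idx], cls)
        except ContractError:
            roc_pts[cls] = None
    summary = {
        "accuracy_overall": overall,
        "confusion": cm3.grid.tolist(),
        "per_class": per_class,
    }
    return summary, roc_pts


def run_cv_experiment(
    images: list[GrayImage],
    labels: list[str],
    mlp_config: MLPConfig = MLPConfig(),
    cnn_config: CNNConfig = CNNConfig(),
    glcm_spec: GLCMSpec = GLCMSpec(),
    frame: Frame = DISJOINT_SINGLETON,
    k: int = 5,
    seed: int = 0,
    features=None,
) -> EvalReport:
    """Train/evaluate MLP, CNN and their Dempster-Shafer fusion under k-fold CV.

    Per fold, both sources are trained on the train split and predict the
    test split; the two probability streams are fused per sample.  Pooled
    confusion matrices and metrics are reported for all three methods.
    Deterministic given ``seed`` (fold assignment and per-fold model seeds
    all derive from it).

    ``features`` may carry a precomputed feature table (as produced by
    :func:`mldstnet.glcm.features_for_dataset`) to skip re-extraction.
    """
    n = len(images)
    if len(labels) != n:
        raise ParameterError(f"{n} images vs {len(labels)} labels")
    label_counts = {c: labels.count(c) for c in set(labels)}
    if min(label_counts.values()) < k:
        raise ParameterError(
            f"each class needs at least k={k} samples, got {label_counts}"
        )
    if features is None:
        features = features_for_dataset(images, labels, glcm_spec)
    elif features.shape[0] != n:
        raise ContractError(
            f"precomputed feature table has {features.shape[0]} rows for {n} images"
        )
    X = features.drop(columns="label").to_numpy()
    split = kfold_split(n, k, seed, labels)
    labels_arr = np.asarray(labels)

    pred = {m: np.empty(n, dtype=object) for m in ("mlp", "cnn", "fused")}
    scores = {m: np.zeros((n, 3)) for m in ("mlp", "cnn", "fused")}
    ks = np.zeros(n)

    for fold_idx, (train_idx, test_idx) in enumerate(split.folds):
        tr = np.asarray(train_idx)
        te = np.asarray(test_idx)
        fold_seed = int(
            np.random.SeedSequence([seed, fold_idx]).generate_state(1)[0] % (2**31)
        )
        mlp = MLPSource(replace(mlp_config, seed=fold_seed)).fit(X[tr], labels_arr[tr])
        cnn = CNNSource(replace(cnn_config, seed=fold_seed)).fit(
            [images[i] for i in tr], list(labels_arr[tr])
        )
        p_mlp = mlp.predict_proba(X[te])
        p_cnn = cnn.predict_proba([images[i] for i in te])
        fused_labels, results = fuse_sources(p_mlp, p_cnn, frame)
        pred["mlp"][te] = [CLASSES[i] for i in np.argmax(p_mlp, axis=1)]
        pred["cnn"][te] = [CLASSES[i] for i in np.argmax(p_cnn, axis=1)]
        pred["fused"][te] = fused_labels
        scores["mlp"][te] = p_mlp
        scores["cnn"][te] = p_cnn
        scores["fused"][te] = np.stack([r.mass.as_array() for r in results])
        ks[te] = [r.k for r in results]

    methods = {}
    roc = {}
    for m in ("mlp", "cnn", "fused"):
        summary, roc_pts = _method_summary(labels_arr, pred[m].astype(str), scores[m])
        methods[m] = summary
        roc[m] = roc_pts
    methods["fused"]["mean_conflict"] = float(ks.mean())
    counts = {
        "images": n,
        "feature_rows": int(features.shape[0]),
        "probability_rows": {m: int(scores[m].shape[0]) for m in ("mlp", "cnn")},
        "fused_rows": int(scores["fused"].shape[0]),
    }
    return EvalReport(methods=methods, roc=roc, counts=counts, seed=seed, k=k)
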