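"""K-fold evaluation protocol and the TP/TN/FP/FN metric suite.

Per-class metrics come from the one-vs-rest reduction of the multiclass
confusion matrix:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * P * R / (P + R)

Averaging is macro by default (unweighted mean over classes); micro pools the
counts over classes, which makes micro recall identical to multiclass
accuracy; weighted weights each class by its true-count support. Classes with
a zero denominator get metric 0 and are flagged rather than producing NaN.

``cross_validate`` runs the full protocol: per fold, fit the zero-sparsity
selection mask on the training portion only (unless ``paper_mode`` fits it on
the whole corpus), train the network on masked training sequences, and score
the held-out fold. A cross-subject split (grouping folds by performer id) is
available as an alternative to stratified k-fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import network, selection
from .network import NetworkConfig, TrainConfig

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "CrossValidationResult",
    "stratified_kfold",
    "cross_subject_split",
    "confusion_matrix",
    "binary_counts",
    "metrics",
    "metrics_from_counts",
    "cross_validate",
]


@dataclass(frozen=True)
class FoldSplit:
    K: int
    assignments: np.ndarray  # per-sample fold id in 0..K-1
    seed: int
    stratified: bool = True

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass(frozen=True)
class MetricsReport:
    confusion: np.ndarray  # (C, C), rows true, columns predicted
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    accuracy: float  # multiclass accuracy = trace / total
    precision: float
    recall: float
    f1: float
    averaging: str = "macro"
    #: classes whose precision or recall had a zero denominator (reported as 0)
    undefined_classes: tuple[int, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "averaging": self.averaging,
        }


def stratified_kfold(labels: np.ndarray, K: int, seed: int = 0) -> FoldSplit:
    """Seed-deterministic stratified K-fold assignment.

    Folds partition the index set and preserve class proportions to within
    one sample. A class with fewer than K samples cannot appear in every fold
    (warned, not fatal).
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    counts = np.bincount(labels)
    thin = np.flatnonzero((counts > 0) & (counts < K))
    if thin.size:
        warnings.warn(
            f"class(es) {thin.tolist()} have fewer than K={K} samples; "
            "some folds will lack them", stacklevel=2)
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn repeats the thin-class warning
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), labels)):
            assignments[test_idx] = fold
    return FoldSplit(K=K, assignments=assignments, seed=seed, stratified=True)


def cross_subject_split(subject_ids: np.ndarray, K: int, seed: int = 0) -> FoldSplit:
    """Group folds by performer identity: all samples of a subject land in the
    same fold, so no subject appears in both train and test."""
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if K > subjects.size:
        raise ValueError(f"K={K} exceeds the number of subjects ({subjects.size})")
    rng = np.random.default_rng(seed)
    fold_of = dict(zip(subjects[rng.permutation(subjects.size)],
                       np.arange(subjects.size) % K))
    assignments = np.array([fold_of[s] for s in subject_ids], dtype=int)
    return FoldSplit(K=K, assignments=assignments, seed=seed, stratified=False)


def confusion_matrix(y_true, y_pred, C: int) -> np.ndarray:
    """counts[i, j] = number of samples with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= C):
            raise ValueError(f"{name} labels outside 0..{C - 1}")
    counts = np.zeros((C, C), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return counts


def binary_counts(conf: np.ndarray, c: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for class c."""
    conf = np.asarray(conf)
    tp = int(conf[c, c])
    fp = int(conf[:, c].sum()) - tp
    fn = int(conf[c, :].sum()) - tp
    tn = int(conf.sum()) - tp - fp - fn
    return tp, tn, fp, fn


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy/precision/recall/F1 from one set of binary counts."""
    total = tp + tn + fp + fn
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return {
        "accuracy": (tp + tn) / total if total else 0.0,
        "precision": p,
        "recall": r,
        "f1": 2 * p * r / (p + r) if p + r else 0.0,
    }


def metrics(conf: np.ndarray, averaging: str = "macro") -> MetricsReport:
    """Metric suite from a confusion matrix under macro/micro/weighted averaging."""
    conf = np.asarray(conf)
    C = conf.shape[0]
    total = int(conf.sum())
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1] or total < 1:
        raise ValueError("need a non-empty square confusion matrix")
    tp = np.diag(conf).astype(int)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    tn = total - tp - fp - fn
    undefined = tuple(np.flatnonzero((tp + fp == 0) | (tp + fn == 0)).tolist())
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        r = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        f1 = np.where(p + r > 0, 2 * p * r / np.maximum(p + r, 1e-300), 0.0)
    accuracy = float(tp.sum() / total)
    if averaging == "macro":
        P, R, F = p.mean(), r.mean(), f1.mean()
    elif averaging == "micro":
        d = metrics_from_counts(int(tp.sum()), int(tn.sum()), int(fp.sum()), int(fn.sum()))
        P, R, F = d["precision"], d["recall"], d["f1"]
    elif averaging == "weighted":
        w = conf.sum(axis=1) / total
        P, R, F = float(w @ p), float(w @ r), float(w @ f1)
    else:
        raise ValueError(f"unknown averaging {averaging!r}")
    return MetricsReport(
        confusion=conf, tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, precision=float(P), recall=float(R), f1=float(F),
        averaging=averaging, undefined_classes=undefined,
    )


@dataclass
class CrossValidationResult:
    folds: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]
    pooled_confusion: np.ndarray
    kept_counts: list[int]
    predictions: np.ndarray  # one prediction per sample, from its held-out fold

    def as_dict(self) -> dict:
        return {
            "folds": [f.as_dict() for f in self.folds],
            "mean": self.mean, "sd": self.sd,
            "kept_counts": self.kept_counts,
            "pooled_confusion": self.pooled_confusion.tolist(),
        }


def cross_validate(
    sequences: np.ndarray,
    labels: np.ndarray,
    net: NetworkConfig,
    opt: TrainConfig,
    K: int = 10,
    seed: int = 0,
    *,
    threshold: int = 90,
    zero_tol: float = 0.0,
    paper_mode: bool = False,
    split: FoldSplit | None = None,
    averaging: str = "macro",
) -> CrossValidationResult:
    """Full K-fold protocol on HoD sequences (n, T, n_features).

    Per fold the sparsity profile is computed over the *frames* of the
    training clips (each frame is one sample for the zero count) and the
    resulting I2I@threshold mask is applied to both partitions, so no
    test-set information leaks into selection; ``paper_mode`` instead fits
    one mask on the whole corpus. ``net.input_dim`` is overridden per fold by
    the kept-feature count. Identical inputs, seed and config reproduce the
    result exactly.
    """
    x = np.asarray(sequences, dtype=float)
    y = np.asarray(labels, dtype=int)
    if split is None:
        split = stratified_kfold(y, K, seed)
    C = net.n_classes
    reports: list[MetricsReport] = []
    kept_counts: list[int] = []
    predictions = np.full(y.size, -1, dtype=int)
    corpus_profile = selection.zero_fraction_profile(
        x.reshape(-1, x.shape[2]), tol=zero_tol) if paper_mode else None
    for fold in range(split.K):
        tr = split.train_indices(fold)
        te = split.test_indices(fold)
        profile = corpus_profile if paper_mode else selection.zero_fraction_profile(
            x[tr].reshape(-1, x.shape[2]), tol=zero_tol)
        mask = selection.select(profile, threshold)
        kept_counts.append(mask.n_kept)
        net_fold = replace(net, input_dim=mask.n_kept)
        opt_fold = replace(opt, seed=opt.seed + fold)
        model = network.train(
            (selection.apply_mask(x[tr], mask), y[tr]), net_fold, opt_fold)
        y_pred = network.predict(model, selection.apply_mask(x[te], mask))
        predictions[te] = y_pred
        reports.append(metrics(confusion_matrix(y[te], y_pred, C), averaging))
    keys = ("accuracy", "precision", "recall", "f1")
    vals = {k: np.array([getattr(r, k) for r in reports]) for k in keys}
    return CrossValidationResult(
        folds=reports,
        mean={k: float(v.mean()) for k, v in vals.items()},
        sd={k: float(v.std(ddof=1)) if split.K > 1 else 0.0 for k, v in vals.items()},
        pooled_confusion=np.sum([r.confusion for r in reports], axis=0),
        kept_counts=kept_counts,
        predictions=predictions,
    )
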