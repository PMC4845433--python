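"""Classification metrics, ROC/AUC, k-fold cross-validation and the
train-on-one-dataset / test-on-another protocol.

Accuracy, sensitivity, precision and the Matthews correlation coefficient
are computed from the confusion counts; AUC is computed by the rank
(Mann-Whitney) statistic with midrank tie handling, with the step-curve
integral available as an independent cross-check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .encoding import GlobalEncoder
from .seq_io import PairRecord, ProteinRecord
from .wsrc import WSRC


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-table counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        if t.shape != p.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tp=int(np.sum((t == 1) & (p == 1))),
            tn=int(np.sum((t == 0) & (p == 0))),
            fp=int(np.sum((t == 0) & (p == 1))),
            fn=int(np.sum((t == 1) & (p == 0))),
        )


@dataclass
class PointMetrics:
    """Metrics of one evaluated prediction set."""

    accuracy: float
    sensitivity: float
    precision: float
    mcc: float
    auc: float | None = None
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "mcc": self.mcc,
            "auc": self.auc,
        }
        if self.counts is not None:
            d["counts"] = asdict(self.counts)
        return d


_METRIC_KEYS = ("accuracy", "sensitivity", "precision", "mcc", "auc")


@dataclass
class CVReport:
    """Per-fold metrics with their mean and standard deviation.

    ``oof_scores``/``oof_labels`` hold the pooled out-of-fold decision
    scores and true labels (in dataset order) for ROC export.
    """

    folds: list[PointMetrics]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)
    oof_scores: np.ndarray | None = None
    oof_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.mean:
            for k in _METRIC_KEYS:
                vals = [getattr(f, k) for f in self.folds]
                if any(v is None for v in vals):
                    continue
                self.mean[k] = float(np.mean(vals))
                self.std[k] = float(np.std(vals))

    def as_dict(self) -> dict:
        return {
            "folds": [f.as_dict() for f in self.folds],
            "mean": self.mean,
            "std": self.std,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def table(self) -> str:
        """Human-readable per-fold table with an average row."""
        header = f"{'fold':>4} " + " ".join(f"{k:>12}" for k in _METRIC_KEYS)
        lines = [header]
        fmt = lambda v: "     n/a" if v is None else f"{v:12.4f}"
        for i, f in enumerate(self.folds, start=1):
            lines.append(
                f"{i:>4} " + " ".join(fmt(getattr(f, k)) for k in _METRIC_KEYS)
            )
        avg = " ".join(
            f"{self.mean[k]:6.4f}±{self.std[k]:.4f}" if k in self.mean else "  n/a"
            for k in _METRIC_KEYS
        )
        lines.append(f" avg {avg}")
        return "\n".join(lines)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(
            f"{name} denominator is zero; reporting 0", stacklevel=3
        )
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> PointMetrics:
    """Accuracy, sensitivity, precision and MCC from confusion counts.

    Degenerate denominators report 0 with a warning so a single bad fold
    cannot abort a cross-validation run.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    accuracy = (tp + tn) / counts.total
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    precision = _safe_div(tp, tp + fp, "precision")
    denom = np.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, denom, "MCC")
    return PointMetrics(
        accuracy=accuracy, sensitivity=sensitivity,
        precision=precision, mcc=mcc, counts=counts,
    )


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by the Mann-Whitney rank statistic with midrank ties.

    Equals the probability that a random positive outscores a random
    negative, ties counted half.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(t == 1))
    n_neg = int(np.sum(t == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = rankdata(s)  # midranks
    return float(
        (ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def roc_points(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard ROC step curve: (fpr, tpr, thresholds)."""
    t = np.asarray(labels, dtype=int)
    if len(np.unique(t)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, thr = roc_curve(t, np.asarray(scores, dtype=float))
    return fpr, tpr, thr


def auc_step_curve(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by trapezoidal integration of the ROC step curve (cross-check)."""
    fpr, tpr, _ = roc_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """AUC (rank statistic) plus the ROC step-curve points."""
    fpr, tpr, thr = roc_points(scores, labels)
    return auc_rank(scores, labels), fpr, tpr, thr


def write_roc_csv(scores, labels, path) -> None:
    """Write the ROC step curve as CSV columns fpr, tpr, threshold."""
    fpr, tpr, thr = roc_points(scores, labels)
    with open(path, "w") as fh:
        fh.write("fpr,tpr,threshold\n")
        for f, t, h in zip(fpr, tpr, thr):
            fh.write(f"{f:.10g},{t:.10g},{h:.10g}\n")


def plot_roc(scores, labels, path=None, ax=None, label: str | None = None):
    """Plot the ROC curve (AUC in the legend); save to ``path`` if given."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr, tpr, _ = roc_points(scores, labels)
    auc = auc_rank(scores, labels)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    name = label or "ROC"
    ax.plot(fpr, tpr, drawstyle="steps-post", label=f"{name} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def evaluate_predictions(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
) -> PointMetrics:
    """Metrics from prediction lists, with AUC when scores are given and
    both classes are present."""
    m = compute_metrics(ConfusionCounts.from_predictions(y_true, y_pred))
    if scores is not None and len(np.unique(np.asarray(y_true))) == 2:
        m.auc = auc_rank(scores, y_true)
    return m


def _protein_disjoint_folds(
    pairs: Sequence[PairRecord], k: int, seed: int
) -> list[np.ndarray]:
    """Assign proteins to k groups at random; keep pairs whose two proteins
    fall in the same group.  Straddling pairs are dropped with a warning —
    the price of guaranteeing no protein is shared across folds."""
    rng = np.random.default_rng(seed)
    prot_ids = sorted({p.id_a for p in pairs} | {p.id_b for p in pairs})
    group = {pid: int(g) for pid, g in zip(prot_ids, rng.integers(0, k, len(prot_ids)))}
    folds: list[list[int]] = [[] for _ in range(k)]
    dropped = 0
    for i, p in enumerate(pairs):
        if group[p.id_a] == group[p.id_b]:
            folds[group[p.id_a]].append(i)
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"protein-disjoint split dropped {dropped} straddling pair(s)",
            stacklevel=3,
        )
    if any(len(f) == 0 for f in folds):
        raise ValueError(
            "a protein-disjoint fold came out empty; use more data or fewer folds"
        )
    return [np.asarray(f, dtype=int) for f in folds]


def _clone_model(model: WSRC) -> WSRC:
    return WSRC(
        sigma=model.sigma, epsilon=model.epsilon,
        weight_mode=model.weight_mode,
        normalize_columns=model.normalize_columns,
        solver_tol=model.solver_tol, max_bisect=model.max_bisect,
        penalty=model.penalty,
    )


def _symmetrize(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Append the order-swapped version (b||a) of every pair row."""
    half = X.shape[1] // 2
    mirrored = np.hstack([X[:, half:], X[:, :half]])
    return np.vstack([X, mirrored]), np.concatenate([y, y])


def kfold_cross_validate(
    pairs: Sequence[PairRecord],
    proteins: Sequence[ProteinRecord],
    k: int = 5,
    encoder: GlobalEncoder | None = None,
    model: WSRC | None = None,
    seed: int = 0,
    protein_disjoint: bool = False,
    symmetrize: bool = False,
) -> CVReport:
    """Stratified k-fold cross-validation of the full encode+classify
    pipeline, reporting per-fold metrics and their mean and std.

    Folds are stratified by label (or, optionally, protein-disjoint) using
    the given seed; every pair is tested exactly once in the stratified
    scheme.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = np.array([p.label for p in pairs], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("cross-validation needs both classes present")
    encoder = encoder or GlobalEncoder()
    model = model or WSRC()
    X, y = encoder.encode_pairs(pairs, proteins)

    if protein_disjoint:
        test_folds = _protein_disjoint_folds(pairs, k, seed)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        test_folds = [test_idx for _, test_idx in skf.split(X, y)]

    all_idx = np.arange(len(pairs))
    fold_metrics: list[PointMetrics] = []
    oof_scores = np.full(len(pairs), np.nan)
    tested = np.zeros(len(pairs), dtype=bool)
    for test_idx in test_folds:
        train_mask = np.ones(len(pairs), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                "a training fold lost one class; enable stratification or "
                "use a larger dataset"
            )
        Xtr, ytr = X[train_idx], y[train_idx]
        if symmetrize:
            Xtr, ytr = _symmetrize(Xtr, ytr)
        fold_model = _clone_model(model).fit(Xtr, ytr)
        results = fold_model.predict_batch(X[test_idx])
        preds = [r.predicted_class for r in results]
        scores = [r.score for r in results]
        oof_scores[test_idx] = scores
        tested[test_idx] = True
        fold_metrics.append(evaluate_predictions(y[test_idx], preds, scores))
    return CVReport(
        folds=fold_metrics,
        oof_scores=oof_scores[tested],
        oof_labels=y[tested],
    )


def cross_species_evaluate(
    train_pairs: Sequence[PairRecord],
    train_proteins: Sequence[ProteinRecord],
    test_pairs: Sequence[PairRecord],
    test_proteins: Sequence[ProteinRecord],
    encoder: GlobalEncoder | None = None,
    model: WSRC | None = None,
    symmetrize: bool = False,
    _encoded_train: tuple[np.ndarray, np.ndarray] | None = None,
) -> PointMetrics:
    """Train on one dataset, test on another (independent-dataset protocol).

    Returns the full metric set when the test labels include both classes;
    with single-class test labels only accuracy (and sensitivity or
    specificity, as applicable) is meaningful and AUC is omitted.
    """
    if not test_pairs:
        raise ValueError("test pair set is empty")
    encoder = encoder or GlobalEncoder()
    model = model or WSRC()
    if _encoded_train is not None:
        Xtr, ytr = _encoded_train
    else:
        Xtr, ytr = encoder.encode_pairs(train_pairs, train_proteins)
    if symmetrize:
        Xtr, ytr = _symmetrize(Xtr, ytr)
    Xte, yte = encoder.encode_pairs(test_pairs, test_proteins)
    fitted = _clone_model(model).fit(Xtr, ytr)
    results = fitted.predict_batch(Xte)
    preds = [r.predicted_class for r in results]
    scores = [r.score for r in results]
    if len(np.unique(yte)) == 2:
        return evaluate_predictions(yte, preds, scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return compute_metrics(ConfusionCounts.from_predictions(yte, preds))
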