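"""K-fold cross-validation and confusion-matrix metrics.

The confusion matrix is oriented rows = predicted, columns = ground
truth.  Multi-class precision/recall/F1 reduce each class one-vs-rest
(TP, FP, FN, TN) and macro-average: precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 = 2PR/(P+R), accuracy = trace/total.  Macro averaging is
the package's documented choice (switchable to micro).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ARCHITECTURES, ModelConfig, TrainedModel, train
from .preprocess import WindowSet

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "kfold_split",
    "metrics_from_confusion",
    "crossvalidate",
    "compare_architectures",
]

METRIC_COLUMNS = ("accuracy", "precision", "recall", "f1", "loss")


@dataclass
class ConfusionMatrix:
    """K x K count table; rows = predicted label, columns = true label."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.labels = tuple(self.labels)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match labels")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_pred, y_true, labels) -> "ConfusionMatrix":
        labels = tuple(labels)
        idx = {c: i for i, c in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for p, t in zip(y_pred, y_true):
            counts[idx[p], idx[t]] += 1
        return cls(counts, labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> dict[str, int]:
        """Per-class TP/FP/FN/TN via one-vs-rest reduction."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[i, :].sum()) - tp  # predicted i, truth other
        fn = int(self.counts[:, i].sum()) - tp  # truth i, predicted other
        tn = self.total - tp - fp - fn
        return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"pred_{c}" for c in self.labels],
                            columns=[f"true_{c}" for c in self.labels])

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("cannot add confusion matrices with different labels")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


def metrics_from_confusion(cm: ConfusionMatrix, average: str = "macro") -> dict:
    """Accuracy plus averaged precision/recall/F1 from a confusion matrix.

    Classes with a zero denominator contribute 0 to the average and raise
    a quality flag in the returned dict.  ``average='binary'`` reports the
    positive-class (first label) precision/recall/F1 of a 2x2 matrix.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    k = len(cm.labels)
    accuracy = float(np.trace(cm.counts) / cm.total)
    flags = []
    if average == "binary":
        if k != 2:
            raise ValueError("binary averaging requires a 2x2 matrix")
        d = cm.one_vs_rest(0)
        precision = d["TP"] / (d["TP"] + d["FP"]) if d["TP"] + d["FP"] else 0.0
        recall = d["TP"] / (d["TP"] + d["FN"]) if d["TP"] + d["FN"] else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
    elif average == "micro":
        tp = sum(cm.one_vs_rest(i)["TP"] for i in range(k))
        fp = sum(cm.one_vs_rest(i)["FP"] for i in range(k))
        fn = sum(cm.one_vs_rest(i)["FN"] for i in range(k))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    elif average == "macro":
        precs, recs, f1s = [], [], []
        for i in range(k):
            d = cm.one_vs_rest(i)
            if d["TP"] + d["FP"] == 0:
                flags.append(f"zero_predicted_{cm.labels[i]}")
                p = 0.0
            else:
                p = d["TP"] / (d["TP"] + d["FP"])
            if d["TP"] + d["FN"] == 0:
                flags.append(f"zero_truth_{cm.labels[i]}")
                r = 0.0
            else:
                r = d["TP"] / (d["TP"] + d["FN"])
            precs.append(p)
            recs.append(r)
            f1s.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
        precision = float(np.mean(precs))
        recall = float(np.mean(recs))
        f1 = float(np.mean(f1s))
    else:
        raise ValueError(f"unknown averaging scheme {average!r}")
    return {"accuracy": accuracy, "precision": float(precision),
            "recall": float(recall), "f1": float(f1), "flags": flags}


def kfold_split(
    windowset: WindowSet,
    k: int = 10,
    grouping: str = "window",
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition of window indices.

    ``window`` grouping shuffles windows freely; ``subject`` grouping keeps
    every window of a subject inside one fold (no subject leakage between
    train and validation).  Fold sizes differ by at most one unit (windows
    or subjects respectively).
    """
    n = len(windowset)
    if n < k:
        raise ValueError(f"cannot split {n} windows into {k} folds")
    rng = np.random.default_rng(seed)
    if grouping == "window":
        perm = rng.permutation(n)
        val_folds = np.array_split(perm, k)
    elif grouping == "subject":
        subjects = np.unique(windowset.subject_ids)
        if len(subjects) < k:
            raise ValueError(
                f"subject grouping needs >= {k} subjects, got {len(subjects)}; "
                "use grouping='window' instead"
            )
        sperm = rng.permutation(subjects)
        sfolds = np.array_split(sperm, k)
        val_folds = [
            np.flatnonzero(np.isin(windowset.subject_ids, sf)) for sf in sfolds
        ]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    splits = []
    all_idx = np.arange(n)
    for vf in val_folds:
        mask = np.zeros(n, dtype=bool)
        mask[vf] = True
        splits.append((all_idx[~mask], np.sort(vf)))
    return splits


@dataclass
class EvalReport:
    """Cross-validation outcome: per-fold metrics and their aggregates."""

    per_fold: list[dict]
    accuracy: float
    precision: float
    recall: float
    f1: float
    loss: float
    confusion: ConfusionMatrix
    architecture: str
    config: ModelConfig
    k: int
    seed: int
    grouping: str = "window"
    models: list[TrainedModel] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{c: f[c] for c in METRIC_COLUMNS} for f in self.per_fold]
        df = pd.DataFrame(rows)
        df.index.name = "fold"
        return df

    def summary(self) -> dict:
        return {c: getattr(self, c) for c in METRIC_COLUMNS}


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


def crossvalidate(
    windowset: WindowSet,
    config: ModelConfig,
    architecture: str = "mcnn_lstm_attention",
    k: int = 10,
    seed: int = 0,
    grouping: str = "window",
    keep_models: bool = False,
) -> EvalReport:
    """Train/evaluate the architecture over a shuffled k-fold split.

    Each fold trains a fresh network (seed derived from the harness seed
    and the fold index), evaluates on its validation fold, and reports
    accuracy/precision/recall/F1 plus the final-epoch validation
    cross-entropy.  Aggregates are unweighted fold means; the confusion
    matrices are summed so every window is counted exactly once.
    """
    splits = kfold_split(windowset, k=k, grouping=grouping, seed=seed)
    labels = tuple(sorted(np.unique(windowset.labels)))
    per_fold = []
    total_cm = ConfusionMatrix(np.zeros((len(labels), len(labels)), dtype=int), labels)
    models = []
    for fold, (tr, va) in enumerate(splits):
        fold_config = config.with_(seed=_fold_seed(seed, fold))
        try:
            model = train(
                windowset.windows[tr], windowset.labels[tr], fold_config,
                architecture,
                validation=(windowset.windows[va], windowset.labels[va]),
            )
        except Exception as err:
            raise RuntimeError(f"fold {fold} failed to train: {err}") from err
        y_pred = model.predict(windowset.windows[va])
        cm = ConfusionMatrix.from_predictions(y_pred, windowset.labels[va], labels)
        m = metrics_from_confusion(cm)
        m["loss"] = float(model.history["val_loss"][-1])
        m["fold"] = fold
        per_fold.append(m)
        total_cm = total_cm + cm
        if keep_models:
            models.append(model)
    agg = {c: float(np.mean([f[c] for f in per_fold])) for c in METRIC_COLUMNS}
    return EvalReport(
        per_fold=per_fold, confusion=total_cm, architecture=architecture,
        config=config, k=k, seed=seed, grouping=grouping, models=models, **agg,
    )


def compare_architectures(
    windowset: WindowSet,
    config: ModelConfig,
    architectures: tuple[str, ...] = ARCHITECTURES,
    seeds: tuple[int, ...] = (0,),
    k: int = 10,
    grouping: str = "window",
) -> pd.DataFrame:
    """Cross-validated comparison table: one row per architecture, metric
    columns ordered Accuracy/Precision/Recall/F1/Loss, mean over seeds."""
    if len(architectures) < 2:
        raise ValueError("compare_architectures needs at least 2 architectures")
    rows = {}
    for arch in architectures:
        reports = [
            crossvalidate(windowset, config, arch, k=k, seed=s, grouping=grouping)
            for s in seeds
        ]
        rows[arch] = {
            c.capitalize() if c != "f1" else "F1 Score":
                float(np.mean([getattr(r, c) for r in reports]))
            for c in METRIC_COLUMNS
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df[["Accuracy", "Precision", "Recall", "F1 Score", "Loss"]]
    df.index.name = "Method"
    return df
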