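"""K-nearest-neighbour class prediction with abstention.

Two-class prediction in the GeneSpring class-prediction style: classifier
genes are ranked by a signal-to-noise score, the gene-set size is chosen by
leave-one-out cross-validation, and each prediction may abstain ("not
classified") via a p-value-ratio rule — the k nearest training neighbours are
scored per class with a hypergeometric enrichment tail p-value, and the call
is withheld unless the best class's p-value is at most ``p_ratio_cutoff``
times the runner-up's.

Performance is summarized per class as correct / incorrect / not-classified
counts; sensitivity and specificity carry exact Clopper-Pearson 95%
confidence intervals, with abstentions counted against the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix

__all__ = [
    "KnnConfig",
    "ClassifierModel",
    "ConfusionCounts",
    "PerformanceReport",
    "NOT_CLASSIFIED",
    "rank_genes",
    "knn_predict",
    "select_classifier_genes",
    "loocv_confusion",
    "performance_metrics",
    "clopper_pearson",
]

NOT_CLASSIFIED = "NOT_CLASSIFIED"


@dataclass(frozen=True)
class KnnConfig:
    k: int = 6
    p_ratio_cutoff: float = 0.5
    distance: Literal["euclidean", "correlation"] = "euclidean"
    ranking: Literal["signal_to_noise", "t_statistic"] = "signal_to_noise"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.p_ratio_cutoff <= 1.0):
            raise ValueError("p_ratio_cutoff must be in (0, 1]")


@dataclass
class ClassifierModel:
    """A trained two-class KNN model.

    Training expression is stored z-scored per gene (training mean/SD), so
    Euclidean distance is scale-free across genes.
    """

    classifier_genes: tuple[str, ...]
    classes: tuple[str, str]
    config: KnnConfig
    training_ids: tuple[str, ...]
    training_labels: tuple[str, ...]
    _z: np.ndarray = field(repr=False, default=None)  # samples x genes, z-scored
    _mean: np.ndarray = field(repr=False, default=None)
    _sd: np.ndarray = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "classifier_genes": list(self.classifier_genes),
            "classes": list(self.classes),
            "config": self.config.__dict__,
            "training_ids": list(self.training_ids),
            "training_labels": list(self.training_labels),
        }


@dataclass(frozen=True)
class ClassCounts:
    correct: int
    incorrect: int
    not_classified: int

    @property
    def total(self) -> int:
        return self.correct + self.incorrect + self.not_classified


@dataclass(frozen=True)
class ConfusionCounts:
    per_class: Mapping[str, ClassCounts]

    def accuracy(self) -> float:
        correct = sum(c.correct for c in self.per_class.values())
        total = sum(c.total for c in self.per_class.values())
        return correct / total


@dataclass(frozen=True)
class PerformanceReport:
    """Percentages rounded to the nearest integer; CI bounds in percent."""

    sensitivity: int
    specificity: int
    accuracy: int
    ci_sensitivity: tuple[float, float]
    ci_specificity: tuple[float, float]


def _score_genes(xa: np.ndarray, xb: np.ndarray, ranking: str) -> np.ndarray:
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    sa = xa.std(axis=0, ddof=1) if xa.shape[0] > 1 else np.zeros(xa.shape[1])
    sb = xb.std(axis=0, ddof=1) if xb.shape[0] > 1 else np.zeros(xb.shape[1])
    if ranking == "signal_to_noise":
        denom = sa + sb
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(denom > 0, (ma - mb) / denom, 0.0)
        # equal means with zero variance carry no discrimination: score 0;
        # unequal means with zero variance separate perfectly
        with np.errstate(invalid="ignore"):
            s = np.where((denom == 0) & (ma != mb), np.inf * np.sign(ma - mb), s)
    else:  # Welch t statistic
        na, nb = xa.shape[0], xb.shape[0]
        denom = np.sqrt(sa**2 / max(na, 1) + sb**2 / max(nb, 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(denom > 0, (ma - mb) / denom, 0.0)
        with np.errstate(invalid="ignore"):
            s = np.where((denom == 0) & (ma != mb), np.inf * np.sign(ma - mb), s)
    return s


def rank_genes(
    m: ExpressionMatrix,
    labels: Mapping[str, str],
    ranking: Literal["signal_to_noise", "t_statistic"] = "signal_to_noise",
) -> list[tuple[str, float]]:
    """Rank transcripts by |score| descending; ties broken by transcript ID.

    The default score is the Golub-style signal-to-noise ratio
    s = (mean_A - mean_B) / (sd_A + sd_B).
    """
    classes = sorted(set(labels.values()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    a_ids = [s for s in m.sample_ids if labels.get(s) == classes[0]]
    b_ids = [s for s in m.sample_ids if labels.get(s) == classes[1]]
    if not a_ids or not b_ids:
        raise ValueError("both classes must be non-empty")
    xa = m.subset(samples=a_ids).values
    xb = m.subset(samples=b_ids).values
    s = _score_genes(xa, xb, ranking)
    order = sorted(range(len(s)), key=lambda j: (-abs(s[j]), m.transcript_ids[j]))
    return [(m.transcript_ids[j], float(s[j])) for j in order]


def train_knn(
    m: ExpressionMatrix,
    labels: Mapping[str, str],
    genes: Sequence[str],
    config: KnnConfig | None = None,
) -> ClassifierModel:
    """Fit (store) a KNN model on the given classifier genes."""
    config = config or KnnConfig()
    classes = tuple(sorted(set(labels.values())))
    if len(classes) != 2:
        raise ValueError("two-class models only")
    if not genes:
        raise ValueError("classifier gene set is empty")
    ids = [s for s in m.sample_ids if s in labels]
    sub = m.subset(samples=ids, transcripts=list(genes))
    x = sub.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant genes contribute nothing
    return ClassifierModel(
        classifier_genes=tuple(genes),
        classes=classes,
        config=config,
        training_ids=tuple(ids),
        training_labels=tuple(labels[s] for s in ids),
        _z=(x - mean) / sd,
        _mean=mean,
        _sd=sd,
    )


def knn_predict(
    model: ClassifierModel, sample: Mapping[str, float] | pd.Series
) -> tuple[str, dict[str, int], float]:
    """Predict one sample: (label or NOT_CLASSIFIED, neighbour votes, p-ratio).

    Per class the vote is scored with the hypergeometric upper-tail
    probability of drawing at least that many class members in k neighbours
    from the training pool; the best (smallest-p) class is called only when
    p_best / p_second <= p_ratio_cutoff.
    """
    missing = [g for g in model.classifier_genes if g not in sample]
    if missing:
        raise ValueError(f"sample missing classifier genes: {missing[:5]}")
    v = np.array([float(sample[g]) for g in model.classifier_genes])
    z = (v - model._mean) / model._sd
    if model.config.distance == "euclidean":
        d = np.sqrt(((model._z - z) ** 2).sum(axis=1))
    else:
        zc = model._z - model._z.mean(axis=1, keepdims=True)
        vc = z - z.mean()
        num = zc @ vc
        den = np.sqrt((zc**2).sum(axis=1) * (vc**2).sum())
        with np.errstate(invalid="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        d = 1.0 - r
    # distance ties broken by training sample ID for determinism
    order = sorted(range(len(d)), key=lambda i: (d[i], model.training_ids[i]))
    k = min(model.config.k, len(order))
    neighbours = order[:k]
    labels = np.array(model.training_labels)
    votes = {c: int(np.sum(labels[np.array(neighbours)] == c)) for c in model.classes}
    n_total = len(model.training_ids)
    p_class = {}
    for c in model.classes:
        n_class = int(np.sum(labels == c))
        p_class[c] = float(stats.hypergeom.sf(votes[c] - 1, n_total, n_class, k))
    ordered = sorted(model.classes, key=lambda c: (p_class[c], c))
    best, second = ordered[0], ordered[1]
    ratio = p_class[best] / p_class[second] if p_class[second] > 0 else np.inf
    label = best if ratio <= model.config.p_ratio_cutoff else NOT_CLASSIFIED
    return label, votes, float(ratio)


def loocv_accuracy(
    m: ExpressionMatrix,
    labels: Mapping[str, str],
    genes: Sequence[str],
    config: KnnConfig | None = None,
) -> float:
    """Leave-one-out accuracy with the gene set held fixed; abstentions count
    as errors."""
    config = config or KnnConfig()
    ids = [s for s in m.sample_ids if s in labels]
    correct = 0
    for sid in ids:
        rest = {s: labels[s] for s in ids if s != sid}
        model = train_knn(m.subset(samples=[s for s in ids if s != sid]), rest, genes, config)
        row = m.data.loc[sid, list(genes)]
        pred, _, _ = knn_predict(model, row)
        if pred == labels[sid]:
            correct += 1
    return correct / len(ids)


def select_classifier_genes(
    m: ExpressionMatrix,
    labels: Mapping[str, str],
    config: KnnConfig | None = None,
    max_genes: int = 30,
) -> ClassifierModel:
    """Choose the smallest top-N prefix of the ranked gene list maximizing
    LOOCV accuracy, and return the model trained on it."""
    import warnings as _warnings

    config = config or KnnConfig()
    ranked = rank_genes(m, labels, config.ranking)
    if max_genes > len(ranked):
        _warnings.warn(
            f"max_genes={max_genes} exceeds {len(ranked)} transcripts; capped"
        )
        max_genes = len(ranked)
    best_n, best_acc = 1, -1.0
    for n in range(1, max_genes + 1):
        genes = [g for g, _ in ranked[:n]]
        acc = loocv_accuracy(m, labels, genes, config)
        if acc > best_acc:
            best_n, best_acc = n, acc
    genes = [g for g, _ in ranked[:best_n]]
    ids = [s for s in m.sample_ids if s in labels]
    return train_knn(m.subset(samples=ids), {s: labels[s] for s in ids}, genes, config)


def loocv_confusion(
    m: ExpressionMatrix,
    labels: Mapping[str, str],
    genes: Sequence[str] | None,
    config: KnnConfig | None = None,
    n_genes: int | None = None,
) -> ConfusionCounts:
    """Per-class correct / incorrect / not-classified tallies under LOOCV.

    With an explicit ``genes`` list the gene set is held fixed across folds
    (the published evaluation protocol).  With ``genes=None`` the top
    ``n_genes`` are re-ranked inside each fold — a fully nested evaluation
    free of selection optimism, appropriate for permutation calibration.
    """
    config = config or KnnConfig()
    if genes is None and n_genes is None:
        raise ValueError("provide either a fixed gene list or n_genes")
    ids = [s for s in m.sample_ids if s in labels]
    classes = sorted(set(labels.values()))
    for c in classes:
        if sum(1 for s in ids if labels[s] == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    tally = {c: [0, 0, 0] for c in classes}
    for sid in ids:
        rest_ids = [s for s in ids if s != sid]
        rest_labels = {s: labels[s] for s in rest_ids}
        rest_m = m.subset(samples=rest_ids)
        fold_genes = (
            list(genes)
            if genes is not None
            else [g for g, _ in rank_genes(rest_m, rest_labels, config.ranking)[:n_genes]]
        )
        model = train_knn(rest_m, rest_labels, fold_genes, config)
        pred, _, _ = knn_predict(model, m.data.loc[sid, fold_genes])
        truth = labels[sid]
        if pred == truth:
            tally[truth][0] += 1
        elif pred == NOT_CLASSIFIED:
            tally[truth][2] += 1
        else:
            tally[truth][1] += 1
    return ConfusionCounts(
        per_class={c: ClassCounts(*tally[c]) for c in classes}
    )


def predict_set(
    model: ClassifierModel, m: ExpressionMatrix, labels: Mapping[str, str]
) -> ConfusionCounts:
    """Apply a trained model to an independent labelled set."""
    classes = sorted(set(labels.values()))
    tally = {c: [0, 0, 0] for c in classes}
    for sid in m.sample_ids:
        if sid not in labels:
            continue
        pred, _, _ = knn_predict(model, m.data.loc[sid, list(model.classifier_genes)])
        truth = labels[sid]
        if pred == truth:
            tally[truth][0] += 1
        elif pred == NOT_CLASSIFIED:
            tally[truth][2] += 1
        else:
            tally[truth][1] += 1
    return ConfusionCounts(per_class={c: ClassCounts(*tally[c]) for c in classes})


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval, in percent (0-100 scale)."""
    if not (0 <= x <= n) or n < 1:
        raise ValueError(f"invalid successes/trials: {x}/{n}")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return 100.0 * lo, 100.0 * hi


def performance_metrics(
    counts: ConfusionCounts, positive_class: str, level: float = 0.95
) -> PerformanceReport:
    """Sensitivity/specificity/accuracy with exact binomial CIs.

    Abstained samples count against both sensitivity and specificity (an
    unclassified patient is an undetected patient).
    """
    if positive_class not in counts.per_class:
        raise ValueError(f"unknown positive class {positive_class!r}")
    pos = counts.per_class[positive_class]
    neg_classes = [c for c in counts.per_class if c != positive_class]
    if not neg_classes:
        raise ValueError("need a negative class")
    neg_correct = sum(counts.per_class[c].correct for c in neg_classes)
    neg_total = sum(counts.per_class[c].total for c in neg_classes)
    if pos.total == 0 or neg_total == 0:
        raise ValueError("empty class: metric undefined")
    sens = pos.correct / pos.total
    spec = neg_correct / neg_total
    acc = counts.accuracy()
    ci_sens = clopper_pearson(pos.correct, pos.total, level)
    ci_spec = clopper_pearson(neg_correct, neg_total, level)
    return PerformanceReport(
        sensitivity=round(100.0 * sens),
        specificity=round(100.0 * spec),
        accuracy=round(100.0 * acc),
        ci_sensitivity=(round(ci_sens[0], 1), round(ci_sens[1], 1)),
        ci_specificity=(round(ci_spec[0], 1), round(ci_spec[1], 1)),
    )
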