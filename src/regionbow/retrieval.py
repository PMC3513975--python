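"""Ranking and retrieval evaluation (precision, recall, AP, mAP, CV).

A query ranks the dataset by nondecreasing learned distance (ties broken
by dataset index).  With relevance flags ``R_j`` (1 iff the j-th ranked
item shares the query's class):

    Precision@K = (sum_{j<=K} R_j) / K
    Recall@K    = (sum_{j<=K} R_j) / (sum_j R_j)
    AP          = (sum over relevant ranks j of Precision@j) / (sum_j R_j)
    mAP         = mean of AP over queries

All measures are ratios of integer counts; they are accumulated as exact
rationals and converted to float once, so results match enumeration
oracles bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .metric import MetricModel, pairwise_distances

__all__ = [
    "RankedList",
    "EvalResult",
    "rank",
    "precision_recall",
    "precision_at_k",
    "average_precision",
    "mean_average_precision",
    "crossval",
]


@dataclass
class RankedList:
    """Dataset ordering for one query, with distances and relevance flags."""

    query_id: str
    order: np.ndarray  # dataset indices, best first
    distances: np.ndarray  # nondecreasing
    relevance: np.ndarray  # 0/1 ints aligned with `order`


def rank(
    query: np.ndarray,
    dataset: np.ndarray,
    model: MetricModel,
    query_label,
    dataset_labels: Sequence,
    query_id: str = "",
) -> RankedList:
    """Rank every dataset row by squared Mahalanobis distance to the query.

    The caller is responsible for excluding the query itself from
    ``dataset`` (queries probe a disjoint training set).
    """
    dataset = np.asarray(dataset, dtype=np.float64)
    if len(dataset) == 0:
        raise ValueError("cannot rank an empty dataset")
    dist = pairwise_distances(model, np.asarray(query, dtype=np.float64), dataset)
    order = np.argsort(dist, kind="stable")  # stable = index tie-break
    labels = np.asarray(dataset_labels)
    return RankedList(
        query_id=query_id,
        order=order,
        distances=dist[order],
        relevance=(labels[order] == query_label).astype(np.int64),
    )


def precision_recall(ranked: RankedList, k: int) -> tuple[float, float]:
    """(precision, recall) over the top ``k`` ranked items."""
    n = len(ranked.relevance)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    n_rel = int(ranked.relevance.sum())
    if n_rel == 0:
        raise ValueError("no relevant item in the dataset for this query")
    hits = int(ranked.relevance[:k].sum())
    return float(Fraction(hits, k)), float(Fraction(hits, n_rel))


def precision_at_k(ranked: RankedList, k: int) -> float:
    """Precision among the top ``k`` results (Prec@K)."""
    return precision_recall(ranked, k)[0]


def average_precision(ranked: RankedList) -> float:
    """Mean of Prec@j over the ranks j of the relevant items.

    Accumulated in exact rational arithmetic, then rounded once to float.
    """
    rel = np.asarray(ranked.relevance)
    n_rel = int(rel.sum())
    if n_rel == 0:
        raise ValueError("no relevant item in the dataset for this query")
    cum = 0
    total = Fraction(0)
    for j, r in enumerate(rel, start=1):
        cum += int(r)
        if r:
            total += Fraction(cum, j)
    return float(total / n_rel)


def mean_average_precision(aps: Sequence[float]) -> float:
    """Arithmetic mean of per-query APs (exact rational accumulation)."""
    aps = list(aps)
    if not aps:
        raise ValueError("need at least one AP value")
    return float(sum(Fraction(a) for a in aps) / len(aps))


@dataclass
class EvalResult:
    """Cross-validation retrieval outcome.

    ``per_query`` rows: (repeat, fold, query id, label, AP, Prec@K...).
    ``map_per_repeat`` averages AP over every query of one repeat; the
    headline numbers are the mean and standard deviation across repeats.
    ``pr_curve`` holds mean precision/recall at each cutoff K (averaged
    over queries, up to the smallest training-set size seen).
    """

    per_query: list[dict] = field(default_factory=list)
    map_per_repeat: list[float] = field(default_factory=list)
    map_mean: float = float("nan")
    map_sd: float = float("nan")
    per_class_map: dict = field(default_factory=dict)
    pr_curve: list[tuple[float, float]] = field(default_factory=list)
    prec_at: dict[int, float] = field(default_factory=dict)
    seed: int = 0
    n_folds: int = 0
    n_repeats: int = 0


def crossval(
    images,
    config=None,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    prec_ks: Sequence[int] = (10, 20),
) -> EvalResult:
    """Repeated stratified k-fold retrieval evaluation of the full pipeline.

    Per fold, every model (standardization, whitening, vocabularies,
    CFML) is fitted on the training images only; each held-out image then
    queries the training set.  Per repeat, mAP averages AP over all its
    queries; the result reports mean and sd of mAP across repeats.
    """
    from sklearn.model_selection import StratifiedKFold

    from .pipeline import PipelineConfig, extract_representations, fit_feature_models, fit_metric

    if config is None:
        config = PipelineConfig()
    labels = np.array([img.label for img in images])
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has {counts.min()} samples, fewer than "
            f"n_folds={n_folds}: stratified folding impossible"
        )

    result = EvalResult(seed=seed, n_folds=n_folds, n_repeats=n_repeats)
    class_aps: dict = {int(c): [] for c in classes}
    pr_sums: dict[int, list] = {}
    for rep in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=(seed + rep) % (2**31)
        )
        rep_aps: list[float] = []
        for fold, (train_idx, test_idx) in enumerate(skf.split(labels, labels)):
            train = [images[i] for i in train_idx]
            test = [images[i] for i in test_idx]
            models = fit_feature_models(train, config)
            x_train = extract_representations(train, models, config)
            x_test = extract_representations(test, models, config)
            metric_model = fit_metric(x_train, labels[train_idx], config)
            for qi, img in zip(x_test, test):
                ranked = rank(
                    qi,
                    x_train,
                    metric_model,
                    img.label,
                    labels[train_idx],
                    query_id=img.image_id,
                )
                ap = average_precision(ranked)
                rep_aps.append(ap)
                class_aps[int(img.label)].append(ap)
                row = {
                    "repeat": rep,
                    "fold": fold,
                    "query": img.image_id,
                    "label": img.label,
                    "ap": ap,
                }
                for k in prec_ks:
                    if k <= len(ranked.relevance):
                        row[f"prec_at_{k}"] = precision_at_k(ranked, k)
                result.per_query.append(row)
                for k in range(1, len(ranked.relevance) + 1):
                    p, r = precision_recall(ranked, k)
                    pr_sums.setdefault(k, [0.0, 0.0, 0])
                    pr_sums[k][0] += p
                    pr_sums[k][1] += r
                    pr_sums[k][2] += 1
        result.map_per_repeat.append(mean_average_precision(rep_aps))

    result.map_mean = float(np.mean(result.map_per_repeat))
    result.map_sd = float(np.std(result.map_per_repeat))
    result.per_class_map = {
        c: float(np.mean(v)) for c, v in class_aps.items() if v
    }
    n_queries = max(v[2] for v in pr_sums.values())
    result.pr_curve = [
        (pr_sums[k][0] / pr_sums[k][2], pr_sums[k][1] / pr_sums[k][2])
        for k in sorted(pr_sums)
        if pr_sums[k][2] == n_queries  # cutoffs seen by every query
    ]
    for k in prec_ks:
        vals = [row[f"prec_at_{k}"] for row in result.per_query if f"prec_at_{k}" in row]
        if vals:
            result.prec_at[k] = float(np.mean(vals))
    return result
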