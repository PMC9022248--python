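"""Splice-site prediction metrics and tissue-specific usage evaluation.

``top_k_accuracy`` implements the top-1 / top-0.5 metric: with N labeled
splice sites, the fraction of the top ``floor(k_frac * N)`` scored
positions that are true sites.  ``auprc`` is the area under the
precision-recall curve computed by step integration (the average-precision
estimator), with tied scores collapsed to a single threshold.  Both are
rank statistics, invariant to strictly monotone transforms of the scores;
score ties are broken by position for reproducibility.

``tissue_specificity_eval`` mirrors the differential-usage evaluation:
after filtering to sites whose usage deviates from the cross-tissue mean by
more than 0.2 in at least one tissue (and optional per-sample coverage and
stability filters), it rank-correlates observed and predicted deviations
from each site's mean usage, per tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InsufficientDataError
from .junctions import TISSUES


@dataclass
class MetricResult:
    name: str
    per_tissue: dict
    pooled: float | None = None
    n_sites: int | None = None
    n_scored: int | None = None


def _ranked(scores: np.ndarray) -> np.ndarray:
    """Indices ordered by descending score, ties broken by position."""
    scores = np.asarray(scores, dtype=float)
    return np.lexsort((np.arange(len(scores)), -scores))


def top_k_accuracy(scores, labels, k_frac: float = 1.0) -> float:
    """Fraction of true sites among the top floor(k_frac * N) predictions."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise DataError("scores and labels must be aligned")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise DataError("top-k accuracy undefined without positive labels")
    k = int(np.floor(k_frac * n_pos))
    if k == 0:
        raise DataError(f"k_frac={k_frac} with N={n_pos} selects no predictions")
    top = _ranked(scores)[:k]
    return float(labels[top].sum() / k)


def per_gene_top_k(gene_scores: Mapping[str, np.ndarray],
                   gene_labels: Mapping[str, np.ndarray],
                   k_frac: float = 1.0) -> float:
    """Average top-k accuracy over genes that contain labeled sites."""
    accs = []
    for gid, scores in gene_scores.items():
        labels = np.asarray(gene_labels[gid]).astype(int)
        if labels.sum() == 0 or int(np.floor(k_frac * labels.sum())) == 0:
            continue
        accs.append(top_k_accuracy(scores, labels, k_frac))
    if not accs:
        raise InsufficientDataError("no gene has labeled splice sites")
    return float(np.mean(accs))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by step integration.

    AP = sum_i (R_i - R_{i-1}) * P_i over descending distinct score
    thresholds, which equals the mean of the precisions at the ranks of the
    positives when scores are untied.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise DataError("scores and labels must be aligned")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise DataError("AUPRC requires both classes")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    # keep only the last index of each tied-score run (threshold boundaries)
    boundary = np.r_[s[1:] != s[:-1], True]
    tp_b, rank_b = tp[boundary], ranks[boundary]
    precision = tp_b / rank_b
    recall = tp_b / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def spearman(a, b) -> float:
    r = stats.spearmanr(a, b).statistic
    if np.isnan(r):
        raise InsufficientDataError("rank correlation undefined (constant input)")
    return float(r)


def deviation_filter(observed: np.ndarray, min_deviation: float = 0.2) -> np.ndarray:
    """Sites whose usage in >=1 tissue deviates from their mean by > threshold."""
    observed = np.asarray(observed, dtype=float)
    dev = observed - observed.mean(axis=1, keepdims=True)
    return np.abs(dev).max(axis=1) > min_deviation


def tissue_specificity_eval(predicted: np.ndarray, observed: np.ndarray,
                            min_deviation: float = 0.2,
                            sample_reads: np.ndarray | None = None,
                            sample_usage_sd: np.ndarray | None = None,
                            min_reads: int = 10, min_read_samples: int = 3,
                            max_sd: float = 0.1,
                            tissues: Sequence[str] = TISSUES) -> MetricResult:
    """Per-tissue rank correlation of usage deviations from the site mean.

    ``predicted``/``observed`` are (sites x tissues) usage matrices.
    Optional quality filters: ``sample_reads`` (sites x samples) requires at
    least ``min_reads`` reads in ``min_read_samples`` samples, and
    ``sample_usage_sd`` (sites,) requires an across-sample usage standard
    deviation below ``max_sd``.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise DataError("prediction/observation matrices must align")
    keep = deviation_filter(observed, min_deviation)
    if sample_reads is not None:
        keep &= (np.asarray(sample_reads) >= min_reads).sum(axis=1) >= min_read_samples
    if sample_usage_sd is not None:
        keep &= np.asarray(sample_usage_sd) < max_sd
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} sites pass the tissue-specificity filters")
    obs_dev = observed[keep] - observed[keep].mean(axis=1, keepdims=True)
    pred_dev = predicted[keep] - predicted[keep].mean(axis=1, keepdims=True)
    per_tissue = {t: spearman(obs_dev[:, i], pred_dev[:, i])
                  for i, t in enumerate(tissues)}
    return MetricResult("tissue_specificity", per_tissue,
                        pooled=spearman(obs_dev.ravel(), pred_dev.ravel()),
                        n_sites=int(keep.sum()))
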