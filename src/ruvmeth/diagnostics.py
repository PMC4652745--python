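"""Quality-control summaries and ranking-performance evaluation.

The diagnostics operate on the same data structures the pipeline produces
and return plain arrays/frames; plotting is an optional thin layer on top.

* RLE (relative log expression, here on M-values): per-array distribution of
  deviations from each probe's across-array median; boxes that drift off
  zero or vary wildly in spread flag array-level artifacts and batches.
* MDS on the most variable probes: the dominant directions of sample-sample
  variation — when dimension 1 separates batches instead of the biology,
  unwanted variation dominates.
* p-value histograms: a well-calibrated analysis is near-uniform with a
  spike at zero.
* ROC/AUC and cumulative true-positive rank curves against a user-supplied
  truth set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .core import MethylationMatrix, RuvFit

logger = logging.getLogger(__name__)

__all__ = [
    "RleSummary",
    "MdsCoordinates",
    "TruthSet",
    "RocResult",
    "rle_summary",
    "mds_coordinates",
    "pvalue_histogram",
    "roc_auc",
    "cumulative_tp_curve",
]


@dataclass(frozen=True)
class RleSummary:
    """Five-number summary of median-centred deviations, one row per sample."""

    sample_ids: tuple[str, ...]
    summary: pd.DataFrame  # columns: min, q1, median, q3, max
    deviations: np.ndarray  # n_samples x n_features


@dataclass(frozen=True)
class MdsCoordinates:
    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # n_samples x n_dims
    eigenvalue_share: np.ndarray


@dataclass(frozen=True)
class TruthSet:
    """User-supplied 'true' positive and negative feature sets for evaluation."""

    positives: frozenset
    negatives: frozenset

    def __post_init__(self):
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))
        if self.positives & self.negatives:
            raise ValueError("positive and negative truth sets overlap")

    @classmethod
    def from_tsv(cls, path) -> "TruthSet":
        df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "label"])
        labels = set(df["label"])
        if not labels <= {"positive", "negative"}:
            raise ValueError(f"truth labels must be positive/negative, got {sorted(labels)}")
        return cls(
            positives=frozenset(df.loc[df.label == "positive", "feature_id"]),
            negatives=frozenset(df.loc[df.label == "negative", "feature_id"]),
        )

    def to_tsv(self, path) -> None:
        rows = [(f, "positive") for f in sorted(self.positives)]
        rows += [(f, "negative") for f in sorted(self.negatives)]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def rle_summary(Y: MethylationMatrix) -> RleSummary:
    """Deviation of every M-value from its probe's across-sample median,
    summarized per sample by (min, Q1, median, Q3, max)."""
    if Y.n_samples < 2:
        raise ValueError("need at least 2 samples")
    dev = Y.values - np.median(Y.values, axis=0, keepdims=True)
    qs = np.quantile(dev, [0.0, 0.25, 0.5, 0.75, 1.0], axis=1).T
    summary = pd.DataFrame(
        qs, columns=["min", "q1", "median", "q3", "max"], index=list(Y.sample_ids)
    )
    return RleSummary(sample_ids=Y.sample_ids, summary=summary, deviations=dev)


def mds_coordinates(Y: MethylationMatrix, top_n: int = 1000) -> MdsCoordinates:
    """Classical (Torgerson) multidimensional scaling of sample-sample
    Euclidean distances computed on the ``top_n`` probes with the largest
    across-sample standard deviation (ties broken by feature order)."""
    if Y.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if top_n < 2:
        raise ValueError("top_n must be at least 2")
    top_n = min(top_n, Y.n_features)
    sd = Y.values.std(axis=0, ddof=1)
    order = np.argsort(-sd, kind="stable")[:top_n]
    sub = Y.values[:, np.sort(order)]

    diff = sub[:, None, :] - sub[None, :, :]
    d2 = np.sum(diff**2, axis=-1)
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ d2 @ J
    w, V = np.linalg.eigh(Bmat)
    w, V = w[::-1], V[:, ::-1]
    tol = max(w.max(), 0) * 1e-10
    keep = w > tol
    if not keep.any():
        logger.warning("all samples identical on the selected probes; zero coordinates")
        return MdsCoordinates(
            sample_ids=Y.sample_ids,
            coordinates=np.zeros((n, 1)),
            eigenvalue_share=np.array([0.0]),
        )
    coords = V[:, keep] * np.sqrt(w[keep])
    share = w[keep] / w[keep].sum()
    return MdsCoordinates(sample_ids=Y.sample_ids, coordinates=coords, eigenvalue_share=share)


def pvalue_histogram(p: np.ndarray, bins: int = 20) -> np.ndarray:
    """Counts on equal-width bins over [0, 1] (last bin right-closed)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    counts, _ = np.histogram(p, bins=bins, range=(0.0, 1.0))
    return counts


def roc_auc(fit: RuvFit, truth: TruthSet) -> RocResult:
    """ROC curve and AUC of the fit's p-value ranking against a truth set.

    Features outside the truth sets are ignored; score is -p so that small
    p-values rank first; tied scores share one ROC vertex, making the AUC
    equal the tie-corrected Mann-Whitney probability.
    """
    if not truth.positives or not truth.negatives:
        raise ValueError("both truth sets must be nonempty")
    universe = set(fit.feature_ids)
    if not (truth.positives <= universe and truth.negatives <= universe):
        missing = (truth.positives | truth.negatives) - universe
        raise ValueError(f"truth features outside the fit's universe: {sorted(missing)[:5]}")
    labels, scores = [], []
    for f, p in zip(fit.feature_ids, fit.p_value):
        if f in truth.positives:
            labels.append(1)
            scores.append(-p)
        elif f in truth.negatives:
            labels.append(0)
            scores.append(-p)
    labels = np.array(labels)
    scores = np.array(scores)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return RocResult(fpr=fpr, tpr=tpr, auc=auc)


def cumulative_tp_curve(fit: RuvFit, positives, top_k: int = 1000) -> np.ndarray:
    """Entry k (1-based) = number of truth positives among the k best-ranked
    features."""
    positives = set(positives)
    if top_k > fit.n_features:
        raise ValueError("top_k exceeds the number of tested features")
    order = np.argsort(fit.rank)
    ids = np.array(fit.feature_ids)[order][:top_k]
    hits = np.fromiter((f in positives for f in ids), dtype=int, count=len(ids))
    return np.cumsum(hits)
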