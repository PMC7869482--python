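"""Supervised BM25-tf-rf weighting of the mutation-count matrix.

Each patient is a document and each gene a term. The weight of gene g in
sample i is the product of two components:

* BM25 term frequency — a saturating, document-length-normalized transform of
  the raw count:  bm25_tf = (k1+1)·tf / (k1·(1 − b + b·dl/avgdl) + tf)

* relevance frequency (rf) — a supervised, per-gene factor computed one-vs-rest
  for a target class from presence document frequencies:
  rf = log2(2 + a / max(1, c)), with a (resp. c) the number of positive-
  (resp. negative-) class samples in which the gene is mutated at least once.

rf is inherently binary, so multiclass weighting produces one weighted matrix
per target class (one-vs-rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .vcf_gene_counts import MutationCountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightingParams:
    """BM25 parameters: k1 controls count saturation (> 0), b the strength of
    document-length normalization (0 = none, 1 = full)."""

    k1: float = 1.2
    b: float = 0.75

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError(f"k1 must be > 0, got {self.k1}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"b must be in [0, 1], got {self.b}")


@dataclass(frozen=True)
class ClassTermStats:
    """Presence document frequencies of one gene: a in the positive class,
    c in the negative (rest) class."""

    gene_id: str
    a: int
    c: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.c < 0:
            raise ValueError("document frequencies must be nonnegative")


@dataclass
class WeightedMutationMatrix:
    """BM25-tf-rf-weighted mutation matrix for one target class."""

    sample_ids: list[str]
    gene_ids: list[str]
    weights: np.ndarray
    target_class: str
    params: WeightingParams
    rf: np.ndarray  # per-gene relevance frequency used for this class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.sample_ids, columns=self.gene_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def bm25_tf(
    tf: float | np.ndarray,
    dl: float | np.ndarray,
    avgdl: float,
    params: WeightingParams = WeightingParams(),
) -> float | np.ndarray:
    """BM25 term-frequency weight; 0 iff tf = 0, bounded above by k1 + 1."""
    if avgdl <= 0:
        raise ValueError(f"avgdl must be positive, got {avgdl}")
    tf = np.asarray(tf, dtype=float)
    dl = np.asarray(dl, dtype=float)
    norm = params.k1 * (1.0 - params.b + params.b * dl / avgdl)
    out = (params.k1 + 1.0) * tf / (norm + tf)
    return float(out) if out.ndim == 0 else out


def relevance_frequency(stats: ClassTermStats | None = None, a: int | None = None,
                        c: int | None = None) -> float:
    """rf = log2(2 + a / max(1, c)); >= 1, equal to 1 iff a = 0."""
    if stats is not None:
        a, c = stats.a, stats.c
    if a is None or c is None:
        raise TypeError("provide either stats or both a and c")
    return float(np.log2(2.0 + a / max(1, c)))


def class_term_stats(
    counts: MutationCountMatrix, labels: dict[str, str], target_class: str
) -> list[ClassTermStats]:
    """Per-gene one-vs-rest presence document frequencies for target_class."""
    pos_mask = _positive_mask(counts, labels, target_class)
    present = counts.counts > 0
    a = present[pos_mask].sum(axis=0)
    c = present[~pos_mask].sum(axis=0)
    return [
        ClassTermStats(gene_id=g, a=int(a[j]), c=int(c[j]))
        for j, g in enumerate(counts.gene_ids)
    ]


def _positive_mask(
    counts: MutationCountMatrix, labels: dict[str, str], target_class: str
) -> np.ndarray:
    unlabeled = [s for s in counts.sample_ids if s not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled samples: {', '.join(unlabeled)}")
    if target_class not in set(labels[s] for s in counts.sample_ids):
        raise ValueError(f"target class {target_class!r} not present among labels")
    return np.array([labels[s] == target_class for s in counts.sample_ids])


def weight_matrix(
    counts: MutationCountMatrix,
    labels: dict[str, str],
    target_class: str,
    params: WeightingParams = WeightingParams(),
) -> WeightedMutationMatrix:
    """Weight every cell as bm25_tf(count, dl, avgdl) x rf(gene, target class)."""
    pos_mask = _positive_mask(counts, labels, target_class)
    present = counts.counts > 0
    a = present[pos_mask].sum(axis=0).astype(float)
    c = present[~pos_mask].sum(axis=0).astype(float)
    rf = np.log2(2.0 + a / np.maximum(1.0, c))

    if counts.avg_doc_length <= 0:  # all-zero matrix: weights are all zero
        weights = np.zeros_like(counts.counts, dtype=float)
    else:
        tf_part = bm25_tf(
            counts.counts, counts.doc_lengths[:, None], counts.avg_doc_length, params
        )
        weights = tf_part * rf[None, :]
    logger.debug(
        "weight_matrix: class=%s k1=%s b=%s", target_class, params.k1, params.b
    )
    return WeightedMutationMatrix(
        sample_ids=list(counts.sample_ids),
        gene_ids=list(counts.gene_ids),
        weights=weights,
        target_class=target_class,
        params=params,
        rf=rf,
    )
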