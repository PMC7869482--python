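"""Classical feature selectors used as comparison baselines: mutual-information
ranking, greedy mRMR, and multiclass ReliefF.

All three are deterministic given fixed settings; ties are broken
lexicographically by gene_id throughout. Mutual information is, by default,
the plug-in estimate on equal-frequency-discretized features (a k-NN estimator
is available for the MI ranking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class FeatureRanking:
    """Genes ordered by selector score (descending for mi_topk / relieff,
    greedy selection order for mrmr)."""

    entries: list[tuple[str, float]]
    selector: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not np.isfinite(s) for _, s in self.entries):
            raise ValueError("non-finite selector score")

    def top_genes(self, k: int) -> list[str]:
        return [g for g, _ in self.entries[:k]]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tgene_id\tscore\tselector\tparams\n")
            for rank, (g, s) in enumerate(self.entries, start=1):
                fh.write(f"{rank}\t{g}\t{s:.10g}\t{self.selector}\t{self.params}\n")


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------


def equal_frequency_discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency (quantile) discretization; a constant feature maps to a
    single level. Duplicate quantile edges merge bins."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    edges = np.quantile(x, np.linspace(0.0, 1.0, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def plugin_mi(u: np.ndarray, v: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete code vectors."""
    u_codes, u_inv = np.unique(u, return_inverse=True)
    v_codes, v_inv = np.unique(v, return_inverse=True)
    joint = np.zeros((len(u_codes), len(v_codes)))
    np.add.at(joint, (u_inv, v_inv), 1.0)
    joint /= joint.sum()
    pu = joint.sum(axis=1, keepdims=True)
    pv = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pu @ pv)[nz])).sum())


def _encode_labels(y: list[str] | np.ndarray) -> np.ndarray:
    _, codes = np.unique(np.asarray(y), return_inverse=True)
    return codes


def mutual_info_rank(
    X: np.ndarray,
    y: list[str] | np.ndarray,
    gene_ids: list[str],
    estimator: str = "discretize",
    bins: int = 5,
    n_neighbors: int = 3,
    seed: int = 0,
) -> FeatureRanking:
    """Rank genes by estimated MI(feature; class label), descending."""
    X = np.asarray(X, dtype=float)
    y_codes = _encode_labels(y)
    if len(np.unique(y_codes)) < 2:
        raise ValueError("mutual_info_rank needs >= 2 classes")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")

    if estimator == "discretize":
        scores = np.array(
            [
                plugin_mi(equal_frequency_discretize(X[:, j], bins), y_codes)
                for j in range(X.shape[1])
            ]
        )
        params: dict[str, Any] = {"estimator": estimator, "bins": bins}
    elif estimator == "knn":
        from sklearn.feature_selection import mutual_info_classif

        scores = mutual_info_classif(
            X, y_codes, n_neighbors=n_neighbors, random_state=seed
        )
        params = {"estimator": estimator, "n_neighbors": n_neighbors, "seed": seed}
    else:
        raise ValueError(f"unknown MI estimator: {estimator}")

    entries = sorted(zip(gene_ids, map(float, scores)), key=lambda e: (-e[1], e[0]))
    return FeatureRanking(entries=entries, selector="mi_topk", params=params)


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------


def mrmr_select(
    X: np.ndarray,
    y: list[str] | np.ndarray,
    gene_ids: list[str],
    k: int,
    scheme: str = "MID",
    bins: int = 3,
) -> FeatureRanking:
    """Greedy minimum-redundancy maximum-relevance selection.

    Features are equal-frequency discretized before any MI computation. The
    first pick maximizes relevance MI(f; y); each later pick maximizes
    relevance − mean redundancy (MID) or relevance / mean redundancy (MIQ),
    where redundancy is the mean MI with already-selected features.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    if k > n_features:
        raise ValueError(f"k={k} exceeds the {n_features} available features")
    if scheme not in {"MID", "MIQ"}:
        raise ValueError(f"unknown mRMR scheme: {scheme}")
    y_codes = _encode_labels(y)
    disc = np.column_stack(
        [equal_frequency_discretize(X[:, j], bins) for j in range(n_features)]
    )
    relevance = np.array([plugin_mi(disc[:, j], y_codes) for j in range(n_features)])

    selected: list[int] = []
    entries: list[tuple[str, float]] = []
    # redundancy_sum[j] accumulates MI(f_j; f_s) over selected s
    redundancy_sum = np.zeros(n_features)
    remaining = set(range(n_features))
    eps = 1e-12
    for _ in range(k):
        if selected:
            mean_red = redundancy_sum / len(selected)
            if scheme == "MID":
                crit = relevance - mean_red
            else:
                crit = relevance / (mean_red + eps)
        else:
            crit = relevance
        # near-ties (within 1e-9) resolve lexicographically, so FP summation
        # order cannot decide the selection path
        cmax = max(crit[j] for j in remaining)
        best = min(
            (j for j in remaining if crit[j] >= cmax - 1e-9),
            key=lambda j: gene_ids[j],
        )
        selected.append(best)
        remaining.discard(best)
        entries.append((gene_ids[best], float(crit[best])))
        for j in remaining:
            redundancy_sum[j] += plugin_mi(disc[:, j], disc[:, best])

    return FeatureRanking(
        entries=entries, selector="mrmr", params={"scheme": scheme, "bins": bins, "k": k}
    )


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------


def relieff_weights(
    X: np.ndarray,
    y: list[str] | np.ndarray,
    gene_ids: list[str],
    n_neighbors: int = 10,
    n_sampled: int | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Multiclass ReliefF feature weights.

    Features are min-max scaled to [0, 1] internally (so weights are invariant
    to feature-wise affine rescaling); neighbors are found under Manhattan
    distance on the scaled features. For each sampled instance the weight of a
    feature decreases by its mean difference to the nearest same-class hits and
    increases by the prior-weighted mean difference to the nearest misses of
    each other class; totals are normalized by n_sampled x n_neighbors.
    Deterministic when all instances are used (the default).
    """
    X = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    n, p = X.shape
    classes, y_codes = np.unique(y_arr, return_inverse=True)
    class_counts = np.bincount(y_codes)
    too_small = [str(classes[c]) for c in range(len(classes))
                 if class_counts[c] < n_neighbors + 1]
    if too_small:
        raise ValueError(
            f"classes {', '.join(too_small)} have fewer than n_neighbors+1="
            f"{n_neighbors + 1} members; use a smaller n_neighbors"
        )

    span = X.max(axis=0) - X.min(axis=0)
    safe = np.where(span > 0, span, 1.0)
    Xs = (X - X.min(axis=0)) / safe  # constant features -> all zeros
    dist = cdist(Xs, Xs, metric="cityblock")
    priors = class_counts / n

    if n_sampled is None:
        sampled = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sampled = rng.choice(n, size=min(n_sampled, n), replace=False)
    m = len(sampled)

    W = np.zeros(p)
    for i in sampled:
        order = np.argsort(dist[i], kind="stable")
        order = order[order != i]
        ci = y_codes[i]
        hits = [j for j in order if y_codes[j] == ci][:n_neighbors]
        W -= np.abs(Xs[hits] - Xs[i]).sum(axis=0) / (m * n_neighbors)
        for c in range(len(classes)):
            if c == ci:
                continue
            misses = [j for j in order if y_codes[j] == c][:n_neighbors]
            w_c = priors[c] / (1.0 - priors[ci])
            W += w_c * np.abs(Xs[misses] - Xs[i]).sum(axis=0) / (m * n_neighbors)

    entries = sorted(zip(gene_ids, map(float, W)), key=lambda e: (-e[1], e[0]))
    return FeatureRanking(
        entries=entries,
        selector="relieff",
        params={"n_neighbors": n_neighbors, "n_sampled": n_sampled, "seed": seed},
    )
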