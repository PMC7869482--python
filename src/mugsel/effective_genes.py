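"""Per-class effective-gene ranking and top-k union selection.

The proposed selector: rank genes by how strongly they mark a class in the
BM25-tf-rf-weighted mutation matrix, take each class's k highest-ranked
("most effective") genes, and use the union across classes as the gene list
for expression-based classification.

Two scoring rules are provided:

* ``coef`` (default) — absolute coefficient of a one-vs-rest L2-regularized
  logistic regression fit on the weighted matrix; matches the classification
  framing under which the gene lists were originally derived.
* ``rf_mass`` — rf_g x mean positive-class bm25_tf_g, i.e. the mean weighted
  value over the target class's samples; classifier-free and solver-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ir_weighting import WeightedMutationMatrix

COEF = "coef"
RF_MASS = "rf_mass"


@dataclass
class EffectivenessTable:
    """Genes of one class ordered by effectiveness score (descending; ties
    broken lexicographically by gene_id)."""

    class_label: str
    entries: list[tuple[str, float]]
    method: str

    def __post_init__(self) -> None:
        if any(not np.isfinite(s) for _, s in self.entries):
            raise ValueError("non-finite effectiveness score")
        self.entries = sorted(self.entries, key=lambda e: (-e[1], e[0]))

    def top_genes(self, k: int) -> list[str]:
        return [g for g, _ in self.entries[:k]]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tgene_id\tscore\n")
            for rank, (g, s) in enumerate(self.entries, start=1):
                fh.write(f"{rank}\t{g}\t{s:.10g}\n")


@dataclass
class SelectedGeneSet:
    """Union of per-class top-k gene lists, with per-gene provenance."""

    gene_ids: set[str]
    per_class_k: int | None = None
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        out: list[str] = []
        for contributors in self.provenance.values():
            for c in contributors:
                if c not in out:
                    out.append(c)
        return out

    def write_gene_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.gene_ids):
                fh.write(g + "\n")


def read_gene_list(path: str | Path) -> SelectedGeneSet:
    genes = [ln.strip() for ln in open(path) if ln.strip()]
    return SelectedGeneSet(gene_ids=set(genes))


def score_effectiveness(
    weighted: WeightedMutationMatrix,
    labels: dict[str, str],
    method: str = COEF,
    *,
    C: float = 1.0,
    seed: int = 0,
) -> EffectivenessTable:
    """Score genes for ``weighted.target_class`` on the weighted matrix."""
    if method not in {COEF, RF_MASS}:
        raise ValueError(f"unknown effectiveness method: {method}")
    unlabeled = [s for s in weighted.sample_ids if s not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled samples: {', '.join(unlabeled)}")
    y = np.array(
        [labels[s] == weighted.target_class for s in weighted.sample_ids]
    )
    if len(set(labels[s] for s in weighted.sample_ids)) < 2:
        raise ValueError("effectiveness scoring needs >= 2 classes of samples")

    if method == COEF:
        if y.sum() < 2 or (~y).sum() < 2:
            raise ValueError(
                f"class {weighted.target_class!r} (or its complement) has < 2 "
                "samples; coef scoring needs >= 2 per side"
            )
        from sklearn.linear_model import LogisticRegression

        model = LogisticRegression(C=C, max_iter=5000, random_state=seed)  # L2 default
        model.fit(weighted.weights, y.astype(int))
        scores = np.abs(model.coef_[0])
    else:  # rf_mass: rf_g x mean positive-class bm25_tf_g == mean pos weight
        scores = weighted.weights[y].mean(axis=0) if y.any() else np.zeros(
            len(weighted.gene_ids)
        )

    return EffectivenessTable(
        class_label=weighted.target_class,
        entries=list(zip(weighted.gene_ids, map(float, scores))),
        method=method,
    )


def top_k_union(tables: list[EffectivenessTable], k: int) -> SelectedGeneSet:
    """Union of each class's k most effective genes."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    for t in tables:
        if k > len(t.entries):
            raise ValueError(
                f"k={k} exceeds the {len(t.entries)}-gene table of class "
                f"{t.class_label!r}"
            )
    provenance: dict[str, list[str]] = {}
    for t in tables:
        for g in t.top_genes(k):
            provenance.setdefault(g, []).append(t.class_label)
    return SelectedGeneSet(
        gene_ids=set(provenance), per_class_k=k, provenance=provenance
    )
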