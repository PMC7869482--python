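"""Expression-matrix assembly, gene-set (GMT) parsing, and gene filtering.

Expression values are FPKM-style nonnegative reals; gene identifiers are
harmonized by stripping Ensembl version suffixes on ingest. No normalization
is applied here — an optional log2(1+x) transform is available at the
classifier stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .effective_genes import SelectedGeneSet
from .vcf_gene_counts import strip_gene_version

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Sample x gene nonnegative real expression values."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[strip_gene_version(str(g)) for g in df.columns],
        values=df.to_numpy(dtype=float),
    )


def assemble_matrix(per_sample_files: list[str | Path]) -> ExpressionMatrix:
    """Assemble one matrix from two-column (gene_id, value) per-sample TSVs.

    Sample IDs come from file name stems; genes absent from a file are filled
    with 0 (FPKM semantics: unobserved ~ unexpressed) and logged. Gene order is
    first-encounter order across files.
    """
    gene_order: list[str] = []
    gene_index: dict[str, int] = {}
    per_sample: list[dict[str, float]] = []
    sample_ids: list[str] = []
    for f in per_sample_files:
        f = Path(f)
        df = pd.read_csv(f, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{f.name}: expected two columns (gene_id, value)")
        vals = df.iloc[:, 1].to_numpy(dtype=float)
        neg = np.flatnonzero(vals < 0)
        if neg.size:
            raise ValueError(
                f"{f.name}: negative expression value at line {int(neg[0]) + 1}"
            )
        record: dict[str, float] = {}
        for gid, v in zip(df.iloc[:, 0].astype(str), vals):
            gid = strip_gene_version(gid)
            record[gid] = float(v)
            if gid not in gene_index:
                gene_index[gid] = len(gene_order)
                gene_order.append(gid)
        per_sample.append(record)
        stem = f.name
        for ext in (".gz", ".tsv", ".txt"):
            if stem.endswith(ext):
                stem = stem[: -len(ext)]
        sample_ids.append(stem)

    values = np.zeros((len(per_sample), len(gene_order)))
    n_filled = 0
    for i, record in enumerate(per_sample):
        for gid, v in record.items():
            values[i, gene_index[gid]] = v
        n_filled += len(gene_order) - len(record)
    if n_filled:
        logger.warning(
            "assemble_matrix: %d sample/gene cells missing from input files, "
            "filled with 0",
            n_filled,
        )
    return ExpressionMatrix(sample_ids=sample_ids, gene_ids=gene_order, values=values)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line — name, description, then members."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            members, seen = [], set()
            dups = 0
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    dups += 1
                    continue
                seen.add(m)
                members.append(m)
            if not members:
                raise ValueError(f"{path.name}:{lineno}: set {name!r} is empty")
            if dups:
                logger.info(
                    "read_gmt: %d duplicate members removed from set %s", dups, name
                )
            sets[name] = members
    return GeneSetCollection(sets=sets, source=str(path))


def union_sets(
    collection: GeneSetCollection, id_map: dict[str, str] | None = None
) -> SelectedGeneSet:
    """Deduplicated union of all sets, optionally translated through id_map
    (symbol -> gene_id); unmapped members are dropped and logged."""
    provenance: dict[str, list[str]] = {}
    n_dropped = 0
    for name, members in collection.sets.items():
        for m in members:
            if id_map is not None:
                if m not in id_map:
                    n_dropped += 1
                    continue
                m = id_map[m]
            provenance.setdefault(m, []).append(name)
    if n_dropped:
        logger.warning("union_sets: %d members had no ID mapping, dropped", n_dropped)
    if not provenance:
        logger.warning("union_sets: the resulting union is empty")
    return SelectedGeneSet(gene_ids=set(provenance), provenance=provenance)


def filter_matrix(
    X: ExpressionMatrix, genes: SelectedGeneSet | set[str]
) -> ExpressionMatrix:
    """Restrict the matrix to the given genes, preserving column order."""
    wanted = genes.gene_ids if isinstance(genes, SelectedGeneSet) else set(genes)
    keep = [j for j, g in enumerate(X.gene_ids) if g in wanted]
    if not keep:
        raise ValueError("no requested genes present in the expression matrix")
    absent = len(wanted) - len(keep)
    if absent:
        logger.info("filter_matrix: %d requested genes absent from the matrix", absent)
    return ExpressionMatrix(
        sample_ids=list(X.sample_ids),
        gene_ids=[X.gene_ids[j] for j in keep],
        values=X.values[:, keep],
    )
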